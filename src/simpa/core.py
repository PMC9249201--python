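"""The imputation engine: one classifier per candidate bin per single cell.

Given the target-specific reference matrix ``RS`` and the sparse bin set
``SC`` of one single cell, the training features ``TF`` are the ``RS``
columns restricted to ``SC``.  Every reference bin absent from ``SC`` is a
candidate ``c_g``; its ``RS`` column is the class vector of a dedicated
random forest trained on ``TF``.  The imputed probability ``rho_g`` is the
forest's class-1 probability for the all-ones probe vector — the predicted
presence of the candidate given that every observed bin is present.  The
result ranks candidates by ``rho`` and can be truncated to an output
profile whose total size defaults to the average number of bins per bulk
reference experiment.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .forest import fit_forest
from .genome_bins import BinKey, BinSet
from .reference import ReferenceMatrix, average_bin_count

__all__ = [
    "TrainingMatrix",
    "CandidateSet",
    "ImputationResult",
    "make_training",
    "candidate_seed",
    "impute_bin",
    "impute_cell",
    "select_output",
    "write_simpa_table",
    "average_interaction",
]

logger = logging.getLogger(__name__)

#: sentinel probability written for original single-cell bins
INPUT_SENTINEL = -1.0


@dataclass(frozen=True)
class TrainingMatrix:
    """``TF``: the reference columns for bins observed in the single cell.

    ``unmatched`` lists single-cell bins absent from the reference; they
    carry no reference signal and are excluded from the features but kept
    verbatim in output profiles.
    """

    columns: Tuple[BinKey, ...]
    values: np.ndarray  # n x s uint8
    bin_size: int
    unmatched: Tuple[BinKey, ...] = ()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def s(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CandidateSet:
    """Candidate bins (reference columns not observed in the cell)."""

    keys: Tuple[BinKey, ...]
    class_vectors: np.ndarray  # n x P uint8
    frequencies: np.ndarray  # P floats

    def __len__(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class ImputationResult:
    """Ranked imputation output for one single cell.

    ``input_bins`` are the original single-cell bins (in genome order) with
    their reference frequency (0.0 for bins outside the reference);
    ``imputed_bins`` are ``(bin, rho, frequency)`` records sorted by the
    total order rho desc, frequency desc, genome position asc.
    """

    bin_size: int
    assembly: str
    input_bins: Tuple[Tuple[BinKey, float], ...]
    imputed_bins: Tuple[Tuple[BinKey, float, float], ...]
    trees: int
    seed: int

    @property
    def input_binset(self) -> BinSet:
        return BinSet([k for k, _ in self.input_bins], self.bin_size, self.assembly)

    def top_candidates(self, k: int) -> List[BinKey]:
        return [key for key, _, _ in self.imputed_bins[:k]]


def make_training(
    rs: ReferenceMatrix, sc: BinSet
) -> Tuple[TrainingMatrix, CandidateSet]:
    """Partition the reference columns into training features and candidates."""
    if len(sc) == 0:
        raise ValueError("single-cell profile is empty")
    if sc.bin_size != rs.bin_size:
        raise ValueError(
            f"bin-size mismatch: cell {sc.bin_size} vs reference {rs.bin_size}"
        )
    sc_keys = sc.keys
    tf_idx = [j for j, key in enumerate(rs.columns) if key in sc_keys]
    if not tf_idx:
        raise ValueError(
            "no usable features: the cell shares no bin with the reference"
        )
    unmatched = tuple(sorted(k for k in sc_keys if k not in rs))
    if unmatched:
        logger.info(
            "%d single-cell bins are outside the reference and ignored for training",
            len(unmatched),
        )
    cand_idx = [j for j, key in enumerate(rs.columns) if key not in sc_keys]
    if not cand_idx:
        warnings.warn("the cell covers every reference bin; nothing to impute")
    tf = TrainingMatrix(
        columns=tuple(rs.columns[j] for j in tf_idx),
        values=np.ascontiguousarray(rs.values[:, tf_idx]),
        bin_size=rs.bin_size,
        unmatched=unmatched,
    )
    cand_values = np.ascontiguousarray(rs.values[:, cand_idx])
    candidates = CandidateSet(
        keys=tuple(rs.columns[j] for j in cand_idx),
        class_vectors=cand_values,
        frequencies=cand_values.mean(axis=0) if cand_idx else np.zeros(0),
    )
    return tf, candidates


def candidate_seed(master_seed: int, class_vector: np.ndarray) -> int:
    """Stable per-candidate seed derived from the master seed and class vector.

    Depending only on the model inputs, it makes results independent of the
    candidate evaluation order and lets identical class vectors share one
    model.
    """
    payload = np.ascontiguousarray(class_vector, dtype=np.uint8).tobytes()
    return zlib.crc32(payload, int(master_seed) & 0xFFFFFFFF) & 0x7FFFFFFF


def impute_bin(
    tf: Union[TrainingMatrix, np.ndarray],
    class_vector: np.ndarray,
    seed: int,
    trees: int = 100,
) -> float:
    """Imputed probability of one candidate bin.

    Trains the candidate's forest on the training features and evaluates it
    on the all-ones probe vector.  A constant class vector short-circuits to
    its constant value without training.
    """
    X = tf.values if isinstance(tf, TrainingMatrix) else np.asarray(tf)
    y = np.ascontiguousarray(class_vector, dtype=np.uint8)
    if y.shape != (X.shape[0],):
        raise ValueError(
            f"class vector length {y.shape} does not match {X.shape[0]} experiments"
        )
    if X.shape[1] < 1:
        raise ValueError("training matrix has no features")
    total = int(y.sum())
    if total == 0:
        return 0.0
    if total == len(y):
        return 1.0
    forest = fit_forest(X, y, n_trees=trees, seed=seed)
    return forest.predict_ones()


def _rank_key(record: Tuple[BinKey, float, float]):
    key, rho, freq = record
    return (-rho, -freq, key)


def impute_cell(
    rs: ReferenceMatrix,
    sc: BinSet,
    seed: int,
    trees: int = 100,
) -> ImputationResult:
    """Impute every candidate bin for one single cell.

    One forest per candidate, seeded per candidate from the master seed, so
    any evaluation order (or parallel split) gives identical results.
    Candidates with identical class vectors share one trained model.
    """
    tf, candidates = make_training(rs, sc)
    cache: Dict[bytes, float] = {}
    records: List[Tuple[BinKey, float, float]] = []
    for g, key in enumerate(candidates.keys):
        cv = candidates.class_vectors[:, g]
        token = cv.tobytes()
        rho = cache.get(token)
        if rho is None:
            rho = impute_bin(tf, cv, candidate_seed(seed, cv), trees=trees)
            cache[token] = rho
        records.append((key, rho, float(candidates.frequencies[g])))
    records.sort(key=_rank_key)
    input_bins = []
    for key in sorted(sc.keys):
        freq = float(rs.column(key).mean()) if key in rs else 0.0
        input_bins.append((key, freq))
    return ImputationResult(
        bin_size=rs.bin_size,
        assembly=rs.assembly,
        input_bins=tuple(input_bins),
        imputed_bins=tuple(records),
        trees=trees,
        seed=int(seed),
    )


def select_output(
    result: ImputationResult,
    total_size: int,
) -> BinSet:
    """Build the output profile: input bins plus top-ranked candidates.

    ``total_size`` is the desired size of the whole output (the package
    default is the reference's average bin count).  Input bins are never
    dropped; if they already meet or exceed ``total_size`` the output is
    the input unchanged (with a warning).
    """
    total_size = int(total_size)
    if total_size <= 0:
        raise ValueError(f"total_size must be >= 1, got {total_size}")
    sc = result.input_binset
    n_extra = total_size - len(sc)
    if n_extra <= 0:
        warnings.warn(
            f"requested total size {total_size} <= input size {len(sc)}; "
            "returning the input profile unchanged"
        )
        return sc
    top = result.top_candidates(n_extra)
    return BinSet(set(sc.keys) | set(top), result.bin_size, result.assembly)


def write_simpa_table(result: ImputationResult, path: Union[str, Path]) -> None:
    """Write the ranked imputation table.

    TSV columns: ``bin_id, chrom, start, end, reference_frequency,
    imputed_probability``.  Input bins come first (probability -1), then
    candidates by rank.
    """
    bs = result.bin_size
    with open(path, "w") as handle:
        handle.write(
            "bin_id\tchrom\tstart\tend\treference_frequency\timputed_probability\n"
        )
        for (chrom, idx), freq in result.input_bins:
            handle.write(
                f"{chrom}:{idx}\t{chrom}\t{idx * bs}\t{(idx + 1) * bs}"
                f"\t{freq:.10g}\t-1\n"
            )
        for (chrom, idx), rho, freq in result.imputed_bins:
            handle.write(
                f"{chrom}:{idx}\t{chrom}\t{idx * bs}\t{(idx + 1) * bs}"
                f"\t{freq:.10g}\t{rho:.10g}\n"
            )


def read_simpa_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a table written by :func:`write_simpa_table`."""
    return pd.read_csv(path, sep="\t")


def average_interaction(rs: ReferenceMatrix) -> Dict[BinKey, float]:
    """Baseline imputation by reference frequency alone (cell-independent).

    Every reference column gets its column mean as probability; used as the
    machine-learning-free comparison point.
    """
    freqs = rs.frequencies()
    return {key: float(freqs[j]) for j, key in enumerate(rs.columns)}
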