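"""Validation machinery: per-bin cross-validation, down-sampling simulations,
single-cell specificity, randomization baselines, and clustering quality.

The central quantities:

* per-candidate-bin stratified k-fold AUROC/AUPRC of the forest against the
  reference column it predicts (random baselines: 0.5 and the class
  balance, respectively);
* leave-out-origin / leave-out-cell-type down-sampling simulations, scoring
  every candidate's imputed probability against membership in the origin
  profile, with the sampled input bins excluded from the evaluation;
* single-cell specificity ``J(imputed, origin) - J(imputed, consensus)``,
  both Jaccard indices computed after removing the input bins from every
  set, where the consensus is the strict-majority profile of the origin's
  same-biosample, same-target peers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import TrainingMatrix, candidate_seed, impute_cell, make_training
from .forest import fit_forest
from .genome_bins import BinKey, BinSet
from .reference import (
    ReferenceExperiment,
    ReferenceMatrix,
    average_bin_count,
    drop_rows,
)

__all__ = [
    "CVRecord",
    "SpecificityRecord",
    "jaccard",
    "crossvalidate_bin",
    "downsample_profile",
    "run_simulation",
    "consensus_profile",
    "specificity",
    "randomized_input",
    "davies_bouldin",
    "recall_of_removed_bins",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVRecord:
    """Cross-validation summary for one candidate bin."""

    bin: Optional[BinKey]
    class_balance: float
    auroc: float
    auprc: float
    folds: int


@dataclass(frozen=True)
class SpecificityRecord:
    """Origin-vs-consensus comparison of one imputed profile.

    All Jaccard values are computed after removing the input bins from
    every set; ``specificity`` > 0 means the imputation is closer to its
    origin than to the same-type consensus.
    """

    j_origin: float
    j_consensus: float
    specificity: float
    origin_consensus_similarity: float
    input_size: int


def jaccard(a: BinSet, b: BinSet) -> float:
    """Jaccard index |a & b| / |a | b|; 1.0 when both sets are empty."""
    if a.bin_size != b.bin_size:
        raise ValueError(f"bin-size mismatch: {a.bin_size} vs {b.bin_size}")
    union = len(a.keys | b.keys)
    if union == 0:
        return 1.0
    return len(a.keys & b.keys) / union


def crossvalidate_bin(
    tf: Union[TrainingMatrix, np.ndarray],
    class_vector: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    trees: int = 100,
) -> Optional[CVRecord]:
    """Stratified k-fold AUROC/AUPRC of one candidate bin's forest.

    Folds are reduced to the minority-class count when necessary; bins with
    fewer than two minority samples (or a constant class vector) are not
    evaluable and return ``None``.

    Both areas are computed on the pooled out-of-fold predictions rather
    than averaged per fold: with a few dozen reference experiments a fold
    holds only 2-3 rows, where per-fold curves are degenerate and the
    average-precision baseline of a signal-free classifier is far above the
    class balance.  Pooling keeps the random baselines at 0.5 (AUROC) and
    near the class balance (AUPRC) at any reference size.
    """
    X = tf.values if isinstance(tf, TrainingMatrix) else np.asarray(tf, dtype=np.uint8)
    y = np.ascontiguousarray(class_vector, dtype=np.uint8)
    if y.shape != (X.shape[0],):
        raise ValueError("class vector length does not match the training matrix")
    minority = int(min(y.sum(), len(y) - y.sum()))
    if minority < 2:
        logger.info("bin skipped in CV: minority class count %d < 2", minority)
        return None
    folds = int(min(folds, minority))
    splitter = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(seed) % (2**32)
    )
    pooled = np.zeros(len(y), dtype=float)
    for k, (train, test) in enumerate(splitter.split(X, y)):
        forest = fit_forest(
            X[train], y[train], n_trees=trees,
            seed=(candidate_seed(seed, y) + k) & 0x7FFFFFFF,
        )
        pooled[test] = forest.predict_proba1(X[test])
    return CVRecord(
        bin=None,
        class_balance=float(y.mean()),
        auroc=float(roc_auc_score(y, pooled)),
        auprc=float(average_precision_score(y, pooled)),
        folds=folds,
    )


def downsample_profile(origin: BinSet, size: int, seed: int) -> BinSet:
    """Uniform random subset of ``size`` bins, simulating a sparse cell."""
    size = int(size)
    if size > len(origin):
        raise ValueError(f"cannot sample {size} bins from a profile of {len(origin)}")
    ordered = sorted(origin.keys)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ordered), size=size, replace=False)
    return BinSet([ordered[i] for i in picked], origin.bin_size, origin.assembly)


def _score_candidates(
    rs: ReferenceMatrix, sc: BinSet, seed: int, trees: int
) -> Tuple[List[BinKey], np.ndarray]:
    """Imputed probability for every candidate bin (unranked)."""
    result = impute_cell(rs, sc, seed, trees=trees)
    keys = [key for key, _, _ in result.imputed_bins]
    rho = np.array([r for _, r, _ in result.imputed_bins])
    return keys, rho


def run_simulation(
    rs: ReferenceMatrix,
    origin: Union[str, ReferenceExperiment],
    sizes: Sequence[int],
    mode: str,
    seed: int,
    trees: int = 100,
) -> pd.DataFrame:
    """Down-sampling simulation for one origin experiment.

    For each input size the origin profile is down-sampled to a sparse
    cell, the origin (LOO) or its whole biosample (LOCT) is removed from
    the training reference, every remaining candidate is scored, and
    AUROC/AUPRC of the scores against origin membership are computed on
    bins not used as input.
    """
    i0 = rs.row_index(origin)
    origin_exp = rs.experiments[i0]
    origin_bins = rs.row_binset(i0)
    rs_train = drop_rows(rs, mode, origin_exp)
    rows = []
    for k, size in enumerate(sizes):
        sc = downsample_profile(origin_bins, size, np.random.default_rng((seed, k)).integers(2**31))
        keys, rho = _score_candidates(rs_train, sc, seed, trees)
        y = np.array([key in origin_bins for key in keys], dtype=np.int8)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("degenerate evaluation set: all candidates one class")
        rows.append(
            {
                "origin": origin_exp.accession,
                "mode": mode,
                "size": int(size),
                "n_candidates": len(keys),
                "class_balance": float(y.mean()),
                "auroc": float(roc_auc_score(y, rho)),
                "auprc": float(average_precision_score(y, rho)),
            }
        )
    return pd.DataFrame(rows)


def consensus_profile(
    rs: ReferenceMatrix, origin: Union[str, ReferenceExperiment]
) -> BinSet:
    """Strict-majority profile of the origin's same-biosample, same-target peers."""
    i0 = rs.row_index(origin)
    origin_exp = rs.experiments[i0]
    peers = [
        i
        for i, e in enumerate(rs.experiments)
        if i != i0 and e.biosample == origin_exp.biosample and e.target == origin_exp.target
    ]
    if not peers:
        raise ValueError(
            f"no peer experiment shares biosample {origin_exp.biosample!r} "
            f"and target {origin_exp.target!r}"
        )
    counts = rs.values[peers].sum(axis=0)
    keys = [rs.columns[j] for j in np.flatnonzero(counts > len(peers) / 2)]
    return BinSet(keys, rs.bin_size, rs.assembly)


def specificity(
    imputed: BinSet,
    origin: BinSet,
    consensus: BinSet,
    input_bins: BinSet,
) -> SpecificityRecord:
    """Single-cell specificity of one imputed profile.

    The input bins are removed from the imputed, origin, and consensus sets
    before any comparison, since they are known before imputation.
    """
    imp = imputed - input_bins
    org = origin - input_bins
    con = consensus - input_bins
    j_origin = jaccard(imp, org)
    j_consensus = jaccard(imp, con)
    return SpecificityRecord(
        j_origin=j_origin,
        j_consensus=j_consensus,
        specificity=j_origin - j_consensus,
        origin_consensus_similarity=jaccard(org, con),
        input_size=len(input_bins),
    )


def randomized_input(rs: ReferenceMatrix, s: int, seed: int) -> BinSet:
    """Randomization baseline: ``s`` bins sampled uniformly from the reference columns."""
    s = int(s)
    if s > rs.m:
        raise ValueError(f"cannot sample {s} bins from {rs.m} reference columns")
    rng = np.random.default_rng(seed)
    picked = rng.choice(rs.m, size=s, replace=False)
    return BinSet([rs.columns[j] for j in picked], rs.bin_size, rs.assembly)


def davies_bouldin(points: np.ndarray, labels: Sequence) -> float:
    """Davies-Bouldin index of a labelled embedding (lower is better).

    Mean over clusters of the worst ratio (intra_i + intra_j) / d(centroid_i,
    centroid_j); coincident centroids with any spread make the score +inf.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or len(labels) != len(points):
        raise ValueError("points must be 2-D with one label per row")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    intra = np.array(
        [
            np.linalg.norm(points[labels == u] - centroids[k], axis=1).mean()
            for k, u in enumerate(uniq)
        ]
    )
    k = len(uniq)
    worst = np.zeros(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            dist = np.linalg.norm(centroids[i] - centroids[j])
            if dist == 0.0:
                ratios.append(np.inf)  # coincident centroids: maximally confusable
            else:
                ratios.append((intra[i] + intra[j]) / dist)
        worst[i] = max(ratios)
    return float(np.mean(worst))


def recall_of_removed_bins(
    rs: ReferenceMatrix,
    cell: BinSet,
    removal_fraction: float,
    seed: int,
    trees: int = 100,
) -> float:
    """Fraction of deliberately removed bins recovered in the top ranks.

    A random ``removal_fraction`` of the cell's reference-covered bins is
    removed, the depleted cell is imputed, and the recall is the share of
    removed bins ranked within the top-(number removed) candidates.
    """
    if not (0.0 <= removal_fraction < 1.0):
        raise ValueError("removal_fraction must be in [0, 1)")
    covered = sorted(k for k in cell.keys if k in rs)
    n_remove = int(round(removal_fraction * len(covered)))
    if n_remove == 0:
        return 1.0
    if len(cell) - n_remove < 1:
        raise ValueError("removal would leave an empty cell")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(covered), size=n_remove, replace=False)
    removed = {covered[i] for i in picked}
    sc = BinSet(cell.keys - removed, cell.bin_size, cell.assembly)
    result = impute_cell(rs, sc, seed, trees=trees)
    top = set(result.top_candidates(n_remove))
    return len(removed & top) / n_remove
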