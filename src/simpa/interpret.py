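"""Interpretable single-locus imputation.

Instead of scoring every candidate, one model is trained for a single
genomic position of interest.  Beyond the imputed probability, the model's
feature importances rank the cell's observed bins by their relevance for
the prediction; each can be annotated with its nearest gene, and the
importance profile can be validated against an external gene-gene
co-expression table (promoter-promoter relationships of co-expressed genes
are expected to score high for activating marks).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import TrainingMatrix, candidate_seed, make_training
from .forest import fit_forest
from .genome_bins import BinKey, BinSet, normalize_chrom
from .reference import ReferenceMatrix

__all__ = [
    "GeneAnnotation",
    "CoexpressionTable",
    "InterpretationResult",
    "FeatureRecord",
    "interpret_position",
    "annotate_nearest_gene",
    "correlate_importance_coexpression",
    "promoter_scan",
]

logger = logging.getLogger(__name__)


class GeneAnnotation:
    """Gene symbol -> TSS lookup with nearest-gene queries.

    Rows: ``symbol, chrom, tss, strand``; symbols must be unique.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"symbol", "chrom", "tss", "strand"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns {sorted(missing)}")
        table = table.copy()
        table["symbol"] = table["symbol"].astype(str)
        table["chrom"] = table["chrom"].map(normalize_chrom)
        table["tss"] = table["tss"].astype(int)
        if table["symbol"].duplicated().any():
            dupes = table.loc[table["symbol"].duplicated(), "symbol"].tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if (table["tss"] < 0).any():
            raise ValueError("negative TSS position")
        if not table["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.table = table.reset_index(drop=True)
        self._by_chrom: Dict[str, pd.DataFrame] = {
            str(chrom): sub.sort_values(["tss", "symbol"]).reset_index(drop=True)
            for chrom, sub in self.table.groupby("chrom")
        }

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.table["symbol"])

    def gene(self, symbol: str) -> pd.Series:
        rows = self.table[self.table["symbol"] == symbol]
        if rows.empty:
            raise ValueError(f"gene {symbol!r} not in annotation")
        return rows.iloc[0]

    def nearest(self, chrom: str, position: int) -> Optional[Tuple[str, int]]:
        """Nearest gene to a position: ``(symbol, signed distance)`` or None.

        Distance is signed along the gene's strand: negative when the
        position lies upstream of the TSS.  Equidistant genes are resolved
        by lexicographic symbol order.
        """
        chrom = normalize_chrom(chrom)
        sub = self._by_chrom.get(chrom)
        if sub is None:
            return None
        tss = sub["tss"].to_numpy()
        dist = np.abs(tss - int(position))
        best = dist.min()
        hits = sub[dist == best].sort_values("symbol").iloc[0]
        signed = int(position) - int(hits["tss"])
        if hits["strand"] == "-":
            signed = -signed
        return str(hits["symbol"]), int(signed)

    def tss_positions(self, chrom: str) -> np.ndarray:
        sub = self._by_chrom.get(normalize_chrom(chrom))
        if sub is None:
            return np.zeros(0, dtype=int)
        return sub["tss"].to_numpy()


class CoexpressionTable:
    """Symmetric gene-pair -> co-expression score lookup (missing pair = 0)."""

    def __init__(self, pairs: Iterable[Tuple[str, str, float]]):
        self._scores: Dict[frozenset, float] = {}
        for a, b, score in pairs:
            score = float(score)
            if score < 0:
                raise ValueError(f"negative co-expression score for ({a}, {b})")
            self._scores[frozenset((str(a), str(b)))] = score

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CoexpressionTable":
        table = pd.read_csv(path, sep="\t")
        cols = list(table.columns[:3])
        return cls(
            (row[0], row[1], row[2]) for row in table[cols].itertuples(index=False)
        )

    def score(self, a: str, b: str) -> float:
        return self._scores.get(frozenset((str(a), str(b))), 0.0)


@dataclass(frozen=True)
class FeatureRecord:
    """One input bin of the single-locus model, with its importance."""

    bin: BinKey
    importance: float
    gene: Optional[str] = None
    tss_distance: Optional[int] = None


@dataclass(frozen=True)
class InterpretationResult:
    """Single-locus model output: probability plus ranked input bins."""

    query_bin: BinKey
    bin_size: int
    probability: float
    features: Tuple[FeatureRecord, ...]
    already_observed: bool = False

    def importance_series(self) -> pd.Series:
        return pd.Series(
            {f"{f.bin[0]}:{f.bin[1]}": f.importance for f in self.features}
        )


def _parse_position(position: Union[str, Tuple[str, int]]) -> Tuple[str, int]:
    if isinstance(position, str):
        chrom, _, pos = position.partition(":")
        if not pos:
            raise ValueError(f"position {position!r} must look like 'chr2:203867786'")
        return normalize_chrom(chrom), int(pos.replace(",", ""))
    chrom, pos = position
    return normalize_chrom(chrom), int(pos)


def _permutation_importance(
    forest, X: np.ndarray, y: np.ndarray, seed: int, n_repeats: int = 5
) -> np.ndarray:
    """Mean drop in training accuracy when one feature column is shuffled."""
    rng = np.random.default_rng(seed)
    base = np.mean((forest.predict_proba1(X) >= 0.5) == (y == 1))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            acc = np.mean((forest.predict_proba1(Xp) >= 0.5) == (y == 1))
            drops[j] += max(0.0, base - acc)
    drops /= n_repeats
    total = drops.sum()
    return drops / total if total > 0 else drops


def interpret_position(
    rs: ReferenceMatrix,
    sc: BinSet,
    position: Union[str, Tuple[str, int]],
    seed: int,
    trees: int = 100,
    max_tss_distance: Optional[int] = None,
    annotation: Optional[GeneAnnotation] = None,
    importance: str = "gini",
) -> InterpretationResult:
    """Train the single-locus model for a genomic position of interest.

    The query position is mapped to its bin; the model is trained exactly
    as the per-candidate imputation model (same features, class vector,
    seeding), and the feature importances are normalized Gini importances
    (or permutation importances on request).  With ``max_tss_distance``,
    the features are restricted before training to input bins whose
    midpoint lies within that distance of an annotated TSS.
    """
    chrom, pos = _parse_position(position)
    key = (chrom, pos // rs.bin_size)
    if key in sc:
        return InterpretationResult(
            query_bin=key,
            bin_size=rs.bin_size,
            probability=1.0,
            features=(),
            already_observed=True,
        )
    if key not in rs:
        raise ValueError(
            f"bin {key[0]}:{key[1]} is outside the reference universe: it is "
            "absent from every reference experiment, so its class vector "
            "would be all-zero"
        )
    tf, _ = make_training(rs, sc)
    columns = list(tf.columns)
    values = tf.values
    if max_tss_distance is not None:
        if annotation is None:
            raise ValueError("max_tss_distance requires a gene annotation")
        keep = []
        for j, (c, i) in enumerate(columns):
            midpoint = i * rs.bin_size + rs.bin_size // 2
            tss = annotation.tss_positions(c)
            if tss.size and np.abs(tss - midpoint).min() <= max_tss_distance:
                keep.append(j)
        if not keep:
            raise ValueError(
                f"no input bin lies within {max_tss_distance} bp of an annotated TSS"
            )
        columns = [columns[j] for j in keep]
        values = np.ascontiguousarray(values[:, keep])
    y = rs.column(key)
    total = int(y.sum())
    if total in (0, len(y)):
        rho = float(total > 0)
        importances = np.zeros(len(columns))
    else:
        forest = fit_forest(values, y, n_trees=trees, seed=candidate_seed(seed, y))
        rho = forest.predict_ones()
        if importance == "gini":
            importances = forest.feature_importances()
        elif importance == "permutation":
            importances = _permutation_importance(
                forest, values, y, candidate_seed(seed + 1, y)
            )
        else:
            raise ValueError(f"unknown importance measure {importance!r}")
    records = []
    for j, (c, i) in enumerate(columns):
        gene = dist = None
        if annotation is not None:
            midpoint = i * rs.bin_size + rs.bin_size // 2
            hit = annotation.nearest(c, midpoint)
            if hit is not None:
                gene, dist = hit
        records.append(FeatureRecord((c, i), float(importances[j]), gene, dist))
    records.sort(key=lambda f: (-f.importance, f.bin))
    return InterpretationResult(
        query_bin=key,
        bin_size=rs.bin_size,
        probability=float(rho),
        features=tuple(records),
    )


def annotate_nearest_gene(
    bins: BinSet, annotation: GeneAnnotation
) -> Dict[BinKey, Tuple[Optional[str], Optional[int]]]:
    """Nearest gene (by |bin midpoint - TSS|) and signed distance per bin.

    Bins on chromosomes without any annotated gene map to ``(None, None)``.
    """
    out: Dict[BinKey, Tuple[Optional[str], Optional[int]]] = {}
    for chrom, idx in sorted(bins.keys):
        midpoint = idx * bins.bin_size + bins.bin_size // 2
        hit = annotation.nearest(chrom, midpoint)
        out[(chrom, idx)] = hit if hit is not None else (None, None)
    return out


def correlate_importance_coexpression(
    result: InterpretationResult,
    query_gene: str,
    coexpression: CoexpressionTable,
) -> Optional[float]:
    """Pearson r between feature importances and co-expression with the query gene.

    Features sharing a nearest gene are aggregated by summed importance
    first.  Returns ``None`` when fewer than 3 annotated genes remain or
    either vector has zero variance.
    """
    by_gene: Dict[str, float] = {}
    for feature in result.features:
        if feature.gene is None:
            continue
        by_gene[feature.gene] = by_gene.get(feature.gene, 0.0) + feature.importance
    if len(by_gene) < 3:
        raise ValueError(
            f"need >= 3 features with annotated genes, got {len(by_gene)}"
        )
    genes = sorted(by_gene)
    imp = np.array([by_gene[g] for g in genes])
    coex = np.array([coexpression.score(g, query_gene) for g in genes])
    if imp.std() == 0.0 or coex.std() == 0.0:
        return None
    return float(np.corrcoef(imp, coex)[0, 1])


def promoter_scan(
    rs: ReferenceMatrix,
    cells: Sequence[BinSet],
    gene_list: Sequence[str],
    annotation: GeneAnnotation,
    seed: int,
    trees: int = 100,
    max_reference_frequency: Optional[float] = None,
) -> pd.DataFrame:
    """Promoter coverage and imputed probability per gene across cells.

    The promoter is the single bin containing the TSS.  ``coverage`` is the
    fraction of cells observing that bin; the imputed probability is 1.0
    for cells that already observe it and the single-locus model output
    otherwise.  ``max_reference_frequency`` keeps only genes whose promoter
    bin is rare in the reference (the low-frequency selection used to focus
    on cell-type-specific promoters).
    """
    rows = []
    for gene in gene_list:
        if gene not in annotation:
            warnings.warn(f"gene {gene!r} absent from annotation; skipped")
            continue
        info = annotation.gene(gene)
        key = (str(info["chrom"]), int(info["tss"]) // rs.bin_size)
        freq = float(rs.column(key).mean()) if key in rs else np.nan
        if max_reference_frequency is not None:
            if not (key in rs and freq < max_reference_frequency):
                continue
        coverage = float(np.mean([key in cell for cell in cells])) if cells else 0.0
        rhos = []
        for cell in cells:
            if key in cell:
                rhos.append(1.0)
            elif key in rs:
                res = interpret_position(
                    rs, cell, (key[0], key[1] * rs.bin_size), seed, trees=trees
                )
                rhos.append(res.probability)
        rows.append(
            {
                "gene": gene,
                "chrom": key[0],
                "promoter_bin": key[1],
                "reference_frequency": freq,
                "coverage": coverage,
                "mean_probability": float(np.mean(rhos)) if rhos else np.nan,
                "sd_probability": float(np.std(rhos, ddof=1)) if len(rhos) > 1 else np.nan,
                "n_cells": len(rhos),
            }
        )
    return pd.DataFrame(rows)
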