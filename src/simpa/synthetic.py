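"""Synthetic reference matrices and single-cell profiles with known truth.

The generator emulates the structure a target-specific bulk reference set
shows in practice: a few cell types, several experiments (replicate
biosamples) per type, cell-type signature bins, shared housekeeping bins
present everywhere, and a floor of background noise.

Real same-biosample experiments are not exchangeable replicates: each one
captures its own subset of the type's regulatory programs, so two
experiments of the same type typically agree at Jaccard ~0.4-0.7 rather
than ~1.  The generator reproduces this by splitting every type's
signature bins into ``modules_per_type`` contiguous modules and assigning
each experiment exactly ``modules_per_experiment`` of them in a balanced
round-robin over the distinct module combinations (with the defaults, the
10 experiments of a type realize the 10 distinct pairs of 5 modules, so
every module is carried by exactly 4 experiments and no module is shared
by a strict majority of any experiment's peers).  A carried module's bins
are present with ``p_signature``; everything else falls back to
``p_background``.  This
within-type heterogeneity is what makes an origin experiment
distinguishable from its same-type consensus, the property the
specificity analysis measures; with exchangeable replicates that analysis
would be vacuous.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

from .genome_bins import BinKey, BinSet, write_bed
from .reference import ReferenceExperiment, ReferenceMatrix, serialize

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticCell",
    "generate_reference",
    "generate_cell",
    "plant_cooccurrence",
    "default_benchmark",
    "BenchmarkBundle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic reference generator.

    Defaults are the package's standard benchmark: 3 cell types x 10
    experiments over 1600 bins of 5 kb on one synthetic chromosome.
    """

    n_cell_types: int = 3
    experiments_per_type: int = 10
    signature_bins: int = 300  # per cell type
    shared_bins: int = 200
    background_bins: int = 500
    p_signature: float = 0.9
    p_background: float = 0.05
    modules_per_type: int = 5
    modules_per_experiment: int = 2
    bin_size: int = 5000
    chrom: str = "chrS"
    assembly: str = "synthetic"
    target: str = "SYNTH-MARK"
    seed: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_background < self.p_signature <= 1.0):
            raise ValueError(
                "need 0 <= p_background < p_signature <= 1, got "
                f"{self.p_background} / {self.p_signature}"
            )
        if not (1 <= self.modules_per_experiment <= self.modules_per_type):
            raise ValueError(
                "modules_per_experiment must be in [1, modules_per_type], got "
                f"{self.modules_per_experiment} / {self.modules_per_type}"
            )
        for name in (
            "n_cell_types", "experiments_per_type", "signature_bins",
            "shared_bins", "background_bins", "modules_per_type", "bin_size",
        ):
            if getattr(self, name) < 0 or (
                name in ("n_cell_types", "experiments_per_type", "modules_per_type",
                         "bin_size")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.modules_per_type > max(1, self.signature_bins):
            raise ValueError("more modules than signature bins")

    @property
    def total_bins(self) -> int:
        return (
            self.n_cell_types * self.signature_bins
            + self.shared_bins
            + self.background_bins
        )

    @property
    def n_experiments(self) -> int:
        return self.n_cell_types * self.experiments_per_type


@dataclass
class SyntheticTruth:
    """Planted structure of a generated reference.

    ``roles`` maps every retained reference column to ``"signature:<type>"``,
    ``"shared"`` or ``"background"``; ``bin_module`` gives the module id of
    signature bins; ``module_carriage`` lists, per experiment accession, the
    modules of its own type it carries.
    """

    spec: SyntheticSpec
    roles: Dict[BinKey, str]
    experiment_types: Dict[str, int]
    bin_module: Dict[BinKey, int]
    module_carriage: Dict[str, Tuple[int, ...]]
    n_dropped_columns: int

    def accessions_of_type(self, cell_type: int) -> List[str]:
        return sorted(
            acc for acc, t in self.experiment_types.items() if t == int(cell_type)
        )

    def keys_with_role(self, role: str) -> List[BinKey]:
        return sorted(k for k, r in self.roles.items() if r == role)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "spec": asdict(self.spec),
            "roles": [[c, i, r] for (c, i), r in sorted(self.roles.items())],
            "experiment_types": dict(sorted(self.experiment_types.items())),
            "bin_module": [[c, i, m] for (c, i), m in sorted(self.bin_module.items())],
            "module_carriage": {
                acc: list(mods) for acc, mods in sorted(self.module_carriage.items())
            },
            "n_dropped_columns": self.n_dropped_columns,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            spec=SyntheticSpec(**payload["spec"]),
            roles={(c, int(i)): r for c, i, r in payload["roles"]},
            experiment_types={
                acc: int(t) for acc, t in payload["experiment_types"].items()
            },
            bin_module={(c, int(i)): int(m) for c, i, m in payload["bin_module"]},
            module_carriage={
                acc: tuple(int(m) for m in mods)
                for acc, mods in payload["module_carriage"].items()
            },
            n_dropped_columns=int(payload["n_dropped_columns"]),
        )


def _accession(t: int, e: int) -> str:
    return f"SYN-T{t}-E{e:02d}"


def generate_reference(spec: SyntheticSpec) -> Tuple[ReferenceMatrix, SyntheticTruth]:
    """Sample a reference matrix with planted structure.

    Bin layout on ``spec.chrom``: per-type signature blocks first, then the
    shared block, then background bins, at contiguous bin indices.  Columns
    that come out all-zero are dropped (recorded in the truth) to satisfy
    the reference column invariant.
    """
    n = spec.n_experiments
    m = spec.total_bins
    if n < 2 or m < 1:
        raise ValueError("spec yields an empty or degenerate matrix")
    rng = np.random.default_rng(spec.seed)

    roles: List[str] = []
    module_of = np.full(m, -1, dtype=np.int64)
    for t in range(spec.n_cell_types):
        base = t * spec.signature_bins
        for l in range(spec.signature_bins):
            roles.append(f"signature:{t}")
            module_of[base + l] = l * spec.modules_per_type // spec.signature_bins
    roles.extend(["shared"] * spec.shared_bins)
    roles.extend(["background"] * spec.background_bins)

    combos = list(
        itertools.combinations(range(spec.modules_per_type), spec.modules_per_experiment)
    )
    carriage = np.zeros(
        (spec.n_cell_types, spec.experiments_per_type, spec.modules_per_type),
        dtype=bool,
    )
    for t in range(spec.n_cell_types):
        for e in range(spec.experiments_per_type):
            carriage[t, e, list(combos[e % len(combos)])] = True

    prob = np.full((n, m), spec.p_background)
    shared_lo = spec.n_cell_types * spec.signature_bins
    prob[:, shared_lo : shared_lo + spec.shared_bins] = spec.p_signature
    for t in range(spec.n_cell_types):
        cols = np.arange(t * spec.signature_bins, (t + 1) * spec.signature_bins)
        mods = module_of[cols]
        for e in range(spec.experiments_per_type):
            row = t * spec.experiments_per_type + e
            carried = carriage[t, e, mods]
            prob[row, cols] = np.where(carried, spec.p_signature, spec.p_background)

    values = (rng.random((n, m)) < prob).astype(np.uint8)
    nonzero = np.flatnonzero(values.sum(axis=0) > 0)
    if nonzero.size == 0:
        raise ValueError("generated reference has no present bins; check parameters")
    values = values[:, nonzero]

    experiments = []
    experiment_types: Dict[str, int] = {}
    module_carriage: Dict[str, Tuple[int, ...]] = {}
    for t in range(spec.n_cell_types):
        for e in range(spec.experiments_per_type):
            acc = _accession(t, e)
            experiments.append(
                ReferenceExperiment(acc, spec.target, f"celltype_{t}", spec.assembly)
            )
            experiment_types[acc] = t
            module_carriage[acc] = tuple(np.flatnonzero(carriage[t, e]).tolist())

    columns = [(spec.chrom, int(j)) for j in nonzero]
    rs = ReferenceMatrix(
        spec.target, experiments, columns, values, spec.bin_size, spec.assembly
    )
    truth = SyntheticTruth(
        spec=spec,
        roles={(spec.chrom, int(j)): roles[j] for j in nonzero},
        experiment_types=experiment_types,
        bin_module={
            (spec.chrom, int(j)): int(module_of[j])
            for j in nonzero
            if module_of[j] >= 0
        },
        module_carriage=module_carriage,
        n_dropped_columns=int(m - nonzero.size),
    )
    return rs, truth


class SyntheticCell(NamedTuple):
    """A simulated sparse cell: the input subset, its full origin, and its source row."""

    sc: BinSet
    origin: BinSet
    accession: str


def generate_cell(
    truth: SyntheticTruth,
    rs: ReferenceMatrix,
    cell_type: int,
    s: int,
    seed: int,
    accession: Optional[str] = None,
    origin_mode: str = "row",
) -> SyntheticCell:
    """Simulate a sparse single cell of a given type.

    The origin is one synthetic experiment row (default) or the type's
    ideal signature-plus-shared set (``origin_mode="ideal"``); the sparse
    input is a uniform subset of ``s`` origin bins.
    """
    rng = np.random.default_rng(seed)
    accessions = truth.accessions_of_type(cell_type)
    if not accessions:
        raise ValueError(f"no synthetic experiment of cell type {cell_type}")
    if accession is None:
        accession = accessions[int(rng.integers(len(accessions)))]
    elif accession not in accessions:
        raise ValueError(f"{accession} is not a cell-type-{cell_type} experiment")
    if origin_mode == "row":
        origin = rs.row_binset(accession)
    elif origin_mode == "ideal":
        keys = truth.keys_with_role(f"signature:{cell_type}") + truth.keys_with_role(
            "shared"
        )
        origin = BinSet(keys, rs.bin_size, rs.assembly)
    else:
        raise ValueError(f"unknown origin_mode {origin_mode!r}")
    if s > len(origin):
        raise ValueError(f"requested {s} bins but origin has only {len(origin)}")
    ordered = sorted(origin.keys)
    picked = rng.choice(len(ordered), size=int(s), replace=False)
    sc = BinSet([ordered[i] for i in picked], rs.bin_size, rs.assembly)
    return SyntheticCell(sc=sc, origin=origin, accession=accession)


def plant_cooccurrence(
    rs: ReferenceMatrix,
    query_key: BinKey,
    feature_key: BinKey,
    epsilon: float = 0.0,
    seed: int = 0,
) -> ReferenceMatrix:
    """Copy one column onto another, optionally flipping entries at rate epsilon.

    Gives ground truth for importance-ranking tests: after planting, the
    query bin's class vector co-occurs (exactly, or up to epsilon noise)
    with the designated feature bin.
    """
    if not (0.0 <= epsilon < 0.5):
        raise ValueError("epsilon must be in [0, 0.5)")
    values = rs.values.copy()
    jq = rs.col_index(query_key)
    jf = rs.col_index(feature_key)
    column = values[:, jf].copy()
    if epsilon > 0.0:
        rng = np.random.default_rng(seed)
        flips = rng.random(rs.n) < epsilon
        column = np.where(flips, 1 - column, column)
    if column.sum() == 0:
        column[int(np.argmax(values[:, jf]))] = 1  # keep the column invariant
    values[:, jq] = column
    return ReferenceMatrix(
        rs.target, rs.experiments, rs.columns, values, rs.bin_size, rs.assembly
    )


class BenchmarkBundle(NamedTuple):
    spec: SyntheticSpec
    rs: ReferenceMatrix
    truth: SyntheticTruth


def default_benchmark(out_dir: Optional[Union[str, Path]] = None) -> BenchmarkBundle:
    """The package's standard synthetic benchmark (seed 1), optionally on disk.

    When ``out_dir`` is given, writes one BED per experiment, a metadata
    TSV, the serialized reference, and the truth JSON; regeneration is
    byte-identical.
    """
    spec = SyntheticSpec()
    rs, truth = generate_reference(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["accession\ttarget\tbiosample\tassembly\tbed"]
        for exp in rs.experiments:
            bed_name = f"{exp.accession}.bed"
            write_bed(rs.row_binset(exp.accession), out / bed_name)
            lines.append(
                f"{exp.accession}\t{exp.target}\t{exp.biosample}"
                f"\t{exp.assembly}\t{bed_name}"
            )
        (out / "metadata.tsv").write_text("\n".join(lines) + "\n")
        serialize(rs, out / "reference.simparef")
        truth.to_json(out / "truth.json")
    return BenchmarkBundle(spec=spec, rs=rs, truth=truth)
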