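"""Target-specific binary reference matrix built from bulk ChIP-seq experiments.

The reference set ``RS`` is an ``n x m`` binary matrix: one row per bulk
experiment sharing the single cell's protein target (or a user-supplied
target group), one column per genomic bin observed in at least one of those
experiments.  Entry ``a[i, j] = 1`` iff bin ``j`` is present in experiment
``i``.  Every column has at least one 1 by construction, and this invariant
is restored after row removal by pruning all-zero columns.
"""

from __future__ import annotations

import io
import logging
import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome_bins import BinKey, BinSet, GenomicBin, read_bed

__all__ = [
    "ReferenceExperiment",
    "ReferenceMatrix",
    "build_reference",
    "average_bin_count",
    "bin_frequency",
    "shuffle_reference",
    "drop_rows",
    "serialize",
    "deserialize",
    "load_metadata_table",
]

logger = logging.getLogger(__name__)

_MAGIC = b"SIMPAREF"
_VERSION = 1


@dataclass(frozen=True)
class ReferenceExperiment:
    """Metadata (and optionally the bin set) of one bulk reference experiment."""

    accession: str
    target: str
    biosample: str
    assembly: str
    bins: Optional[BinSet] = None


class ReferenceMatrix:
    """Binary experiments x bins matrix for one protein target (group)."""

    def __init__(
        self,
        target: str,
        experiments: Sequence[ReferenceExperiment],
        columns: Sequence[BinKey],
        values: np.ndarray,
        bin_size: int,
        assembly: str,
    ):
        values = np.asarray(values, dtype=np.uint8)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(experiments), len(columns)):
            raise ValueError(
                f"shape mismatch: values {values.shape}, "
                f"{len(experiments)} experiments x {len(columns)} columns"
            )
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("reference entries must be binary")
        if values.shape[1] and (values.sum(axis=0) == 0).any():
            raise ValueError("every reference column must contain at least one 1")
        accs = [e.accession for e in experiments]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate experiment accessions in reference")
        self.target = str(target)
        self.experiments = list(experiments)
        self.columns: Tuple[BinKey, ...] = tuple((str(c), int(i)) for c, i in columns)
        self.values = values
        self.bin_size = int(bin_size)
        self.assembly = str(assembly)
        self._col_index: Dict[BinKey, int] = {k: j for j, k in enumerate(self.columns)}

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def col_index(self, key: BinKey) -> int:
        key = (str(key[0]), int(key[1]))
        if key not in self._col_index:
            raise ValueError(f"bin {key} is not a reference column")
        return self._col_index[key]

    def __contains__(self, key: BinKey) -> bool:
        return (str(key[0]), int(key[1])) in self._col_index

    def column(self, key: BinKey) -> np.ndarray:
        return self.values[:, self.col_index(key)]

    def frequencies(self) -> np.ndarray:
        """Per-column presence frequency across experiments."""
        return self.values.mean(axis=0)

    def row_binset(self, row: Union[int, str]) -> BinSet:
        """The BinSet of one experiment row (by index or accession)."""
        i = self.row_index(row)
        keys = [self.columns[j] for j in np.flatnonzero(self.values[i])]
        return BinSet(keys, self.bin_size, self.assembly)

    def row_index(self, row: Union[int, str, ReferenceExperiment]) -> int:
        if isinstance(row, ReferenceExperiment):
            row = row.accession
        if isinstance(row, str):
            for i, exp in enumerate(self.experiments):
                if exp.accession == row:
                    return i
            raise ValueError(f"accession {row!r} is not a reference row")
        i = int(row)
        if not 0 <= i < self.n:
            raise ValueError(f"row index {i} out of range")
        return i

    def column_binset(self) -> BinSet:
        return BinSet(self.columns, self.bin_size, self.assembly)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceMatrix):
            return NotImplemented
        return (
            self.target == other.target
            and self.bin_size == other.bin_size
            and self.assembly == other.assembly
            and self.columns == other.columns
            and [(e.accession, e.target, e.biosample) for e in self.experiments]
            == [(e.accession, e.target, e.biosample) for e in other.experiments]
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ReferenceMatrix(target={self.target!r}, n={self.n}, m={self.m}, "
            f"bin_size={self.bin_size}, assembly={self.assembly!r})"
        )


def build_reference(
    experiments: Iterable[ReferenceExperiment],
    target: Union[str, Iterable[str]],
) -> ReferenceMatrix:
    """Assemble the reference matrix for one target or a target group.

    Rows are the experiments whose target is in the group, sorted by
    accession; columns are the union of their bins in genome order.  At
    least two matching experiments are required.
    """
    targets = {target} if isinstance(target, str) else set(target)
    if not targets:
        raise ValueError("no target given")
    matching = sorted(
        (e for e in experiments if e.target in targets), key=lambda e: e.accession
    )
    if not matching:
        raise ValueError(f"no reference experiment matches target(s) {sorted(targets)}")
    if len(matching) < 2:
        raise ValueError(
            f"need >= 2 reference experiments for target(s) {sorted(targets)}, "
            f"got {len(matching)}"
        )
    for exp in matching:
        if exp.bins is None:
            raise ValueError(f"experiment {exp.accession} has no bins loaded")
    bin_sizes = {e.bins.bin_size for e in matching}
    if len(bin_sizes) != 1:
        raise ValueError(f"mixed bin sizes in reference experiments: {sorted(bin_sizes)}")
    assemblies = {e.assembly for e in matching}
    if len(assemblies) != 1:
        raise ValueError(f"mixed assemblies in reference experiments: {sorted(assemblies)}")
    bin_size = bin_sizes.pop()
    assembly = assemblies.pop()
    columns = sorted(set().union(*(e.bins.keys for e in matching)))
    col_index = {k: j for j, k in enumerate(columns)}
    values = np.zeros((len(matching), len(columns)), dtype=np.uint8)
    for i, exp in enumerate(matching):
        for key in exp.bins.keys:
            values[i, col_index[key]] = 1
    label = "+".join(sorted(targets))
    meta = [replace(e, bins=None) for e in matching]
    return ReferenceMatrix(label, meta, columns, values, bin_size, assembly)


def average_bin_count(rs: ReferenceMatrix) -> int:
    """Round-half-up mean number of present bins per reference experiment.

    This is the default total size of the imputed output profile.
    """
    if rs.n < 1:
        raise ValueError("reference has no experiments")
    mean = float(rs.values.sum(axis=1).mean())
    return int(math.floor(mean + 0.5))


def bin_frequency(rs: ReferenceMatrix, key: BinKey) -> float:
    """Fraction of reference experiments in which the bin is present."""
    return float(rs.column(key).mean())


def shuffle_reference(rs: ReferenceMatrix, seed: int) -> ReferenceMatrix:
    """Randomization baseline: permute each column independently across rows.

    Per-bin frequencies (column sums) are preserved exactly while every
    joint, cross-experiment pattern is destroyed.
    """
    rng = np.random.default_rng(seed)
    values = rs.values.copy()
    for j in range(rs.m):
        values[:, j] = values[rng.permutation(rs.n), j]
    return ReferenceMatrix(
        rs.target, rs.experiments, rs.columns, values, rs.bin_size, rs.assembly
    )


def drop_rows(
    rs: ReferenceMatrix,
    mode: str,
    origin: Union[str, ReferenceExperiment],
) -> ReferenceMatrix:
    """Ablate the reference for simulation: leave-out-origin or leave-out-cell-type.

    ``leave_out_origin`` (LOO) removes exactly the origin experiment's row;
    ``leave_out_cell_type`` (LOCT) removes every row sharing the origin's
    biosample.  Columns left with no 1 are pruned to restore the column
    invariant (logged, since kept-vs-pruned is a package choice).
    """
    aliases = {
        "loo": "leave_out_origin",
        "loct": "leave_out_cell_type",
        "leave_out_origin": "leave_out_origin",
        "leave_out_cell_type": "leave_out_cell_type",
    }
    if mode not in aliases:
        raise ValueError(f"unknown mode {mode!r}")
    mode = aliases[mode]
    i0 = rs.row_index(origin)
    origin_exp = rs.experiments[i0]
    if mode == "leave_out_origin":
        keep = [i for i in range(rs.n) if i != i0]
    else:
        keep = [
            i for i, e in enumerate(rs.experiments) if e.biosample != origin_exp.biosample
        ]
    if len(keep) < 2:
        raise ValueError(
            f"{mode} removal of {origin_exp.accession} leaves {len(keep)} rows (< 2)"
        )
    values = rs.values[keep]
    nonzero = np.flatnonzero(values.sum(axis=0) > 0)
    if len(nonzero) < rs.m:
        logger.info(
            "drop_rows(%s): pruned %d all-zero columns", mode, rs.m - len(nonzero)
        )
    columns = [rs.columns[j] for j in nonzero]
    return ReferenceMatrix(
        rs.target,
        [rs.experiments[i] for i in keep],
        columns,
        values[:, nonzero],
        rs.bin_size,
        rs.assembly,
    )


# -- serialization ---------------------------------------------------------
#
# Binary container layout (little-endian):
#   8s   magic "SIMPAREF"
#   H    version (1)
#   I    bin_size
#   str  assembly          (H length + utf-8 bytes)
#   str  target
#   I    n (experiments)
#   I    m (columns)
#   H    n_chrom_names; then n_chrom_names strings
#   m*H  per-column chromosome id
#   m*I  per-column bin index
#   n*3  per-experiment strings: accession, target, biosample
#   n*ceil(m/8) row bitsets (numpy packbits, big-endian bit order)


def _write_str(buf: io.BufferedIOBase, s: str) -> None:
    data = s.encode("utf-8")
    if len(data) > 0xFFFF:
        raise ValueError("string too long for serialization")
    buf.write(struct.pack("<H", len(data)))
    buf.write(data)


def _read_str(buf: io.BufferedIOBase) -> str:
    (length,) = struct.unpack("<H", _read_exact(buf, 2))
    return _read_exact(buf, length).decode("utf-8")


def _read_exact(buf: io.BufferedIOBase, size: int) -> bytes:
    data = buf.read(size)
    if len(data) != size:
        raise ValueError("truncated reference file")
    return data


def serialize(rs: ReferenceMatrix, path: Union[str, Path]) -> None:
    """Write the reference matrix to a compact binary container."""
    with open(path, "wb") as handle:
        handle.write(_MAGIC)
        handle.write(struct.pack("<HI", _VERSION, rs.bin_size))
        _write_str(handle, rs.assembly)
        _write_str(handle, rs.target)
        handle.write(struct.pack("<II", rs.n, rs.m))
        chroms = sorted({c for c, _ in rs.columns})
        chrom_id = {c: k for k, c in enumerate(chroms)}
        handle.write(struct.pack("<H", len(chroms)))
        for c in chroms:
            _write_str(handle, c)
        cids = np.array([chrom_id[c] for c, _ in rs.columns], dtype="<u2")
        idxs = np.array([i for _, i in rs.columns], dtype="<u4")
        handle.write(cids.tobytes())
        handle.write(idxs.tobytes())
        for exp in rs.experiments:
            _write_str(handle, exp.accession)
            _write_str(handle, exp.target)
            _write_str(handle, exp.biosample)
        for i in range(rs.n):
            handle.write(np.packbits(rs.values[i]).tobytes())


def deserialize(path: Union[str, Path]) -> ReferenceMatrix:
    """Read a reference matrix written by :func:`serialize`."""
    with open(path, "rb") as handle:
        magic = handle.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a SIMPA reference file (bad magic)")
        version, bin_size = struct.unpack("<HI", _read_exact(handle, 6))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported reference version {version}")
        assembly = _read_str(handle)
        target = _read_str(handle)
        n, m = struct.unpack("<II", _read_exact(handle, 8))
        (n_chroms,) = struct.unpack("<H", _read_exact(handle, 2))
        chroms = [_read_str(handle) for _ in range(n_chroms)]
        cids = np.frombuffer(_read_exact(handle, 2 * m), dtype="<u2")
        idxs = np.frombuffer(_read_exact(handle, 4 * m), dtype="<u4")
        columns = [(chroms[c], int(i)) for c, i in zip(cids, idxs)]
        experiments = []
        for _ in range(n):
            acc = _read_str(handle)
            tgt = _read_str(handle)
            bios = _read_str(handle)
            experiments.append(ReferenceExperiment(acc, tgt, bios, assembly))
        row_bytes = (m + 7) // 8
        values = np.zeros((n, m), dtype=np.uint8)
        for i in range(n):
            packed = np.frombuffer(_read_exact(handle, row_bytes), dtype=np.uint8)
            values[i] = np.unpackbits(packed)[:m]
    return ReferenceMatrix(target, experiments, columns, values, bin_size, assembly)


def load_metadata_table(
    path: Union[str, Path],
    bin_size: int,
    base_dir: Optional[Union[str, Path]] = None,
) -> List[ReferenceExperiment]:
    """Load reference experiments from a metadata TSV.

    Expected columns: ``accession``, ``target``, ``biosample``, ``assembly``,
    ``bed`` (path to the experiment's peak/bin BED, relative to ``base_dir``
    or to the table's directory).
    """
    table = pd.read_csv(path, sep="\t")
    required = {"accession", "target", "biosample", "assembly", "bed"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    experiments = []
    for row in table.itertuples(index=False):
        bed_path = Path(row.bed)
        if not bed_path.is_absolute():
            bed_path = base / bed_path
        bins = read_bed(bed_path, bin_size, assembly=str(row.assembly))
        experiments.append(
            ReferenceExperiment(
                str(row.accession), str(row.target), str(row.biosample),
                str(row.assembly), bins,
            )
        )
    return experiments
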