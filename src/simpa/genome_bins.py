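"""Genomic bin model, BED I/O, and peak-to-bin conversion.

The whole package works on fixed-size, non-overlapping genomic windows
("bins").  Bin ``k`` of a chromosome covers the half-open interval
``[k * bin_size, (k + 1) * bin_size)`` in 0-based BED coordinates.  A bin is
"present" in a profile if at least one peak or region overlaps it by at
least one base pair.  Profiles — a peak file, a single cell, an imputed
result — are all represented by :class:`BinSet`.
"""

from __future__ import annotations

import math
import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence, Set, Tuple, Union

import pandas as pd

__all__ = [
    "GenomicBin",
    "BinSet",
    "ChromSizes",
    "normalize_chrom",
    "load_chrom_sizes",
    "peaks_to_bins",
    "count_genome_bins",
    "read_bed",
    "write_bed",
    "matrix_to_cell_beds",
    "DEFAULT_EXCLUDE_CHROMS",
]

#: chromosomes excluded by default from single-cell profiles (sex chromosomes
#: and the mitochondrial genome).
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX", "chrY", "chrM"})

#: mapping chromosome name -> length in bp
ChromSizes = Mapping[str, int]

BinKey = Tuple[str, int]


class GenomicBin(NamedTuple):
    """One fixed-size genomic window in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    bin_index: int


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed dialect.

    Accepts ``1``/``chr1``, ``MT``/``M``/``chrM`` and returns the UCSC-style
    name; public BED files mix both dialects.
    """
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name in ("MT", "M"):
        return "chrM"
    if name == "chrMT":
        return "chrM"
    if name.startswith("chr"):
        return name
    return "chr" + name


class BinSet:
    """A sorted, duplicate-free set of bins at a fixed bin size.

    Parameters
    ----------
    keys:
        Iterable of ``(chrom, bin_index)`` pairs.
    bin_size:
        Bin width in bp (> 0).
    assembly:
        Genome assembly label; purely a tag, but set operations require it
        to match so that profiles from different genomes are never mixed.
    """

    __slots__ = ("bin_size", "assembly", "_keys")

    def __init__(self, keys: Iterable[BinKey], bin_size: int, assembly: str = "unknown"):
        bin_size = int(bin_size)
        if bin_size <= 0:
            raise ValueError(f"bin_size must be > 0, got {bin_size}")
        self.bin_size = bin_size
        self.assembly = str(assembly)
        norm = set()
        for chrom, idx in keys:
            idx = int(idx)
            if idx < 0:
                raise ValueError(f"negative bin index {idx} on {chrom}")
            norm.add((str(chrom), idx))
        self._keys: frozenset = frozenset(norm)

    # -- container protocol ------------------------------------------------
    @property
    def keys(self) -> frozenset:
        return self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __contains__(self, key: BinKey) -> bool:
        return (str(key[0]), int(key[1])) in self._keys

    def __iter__(self) -> Iterator[BinKey]:
        return iter(sorted(self._keys))

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinSet):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and self.assembly == other.assembly
            and self._keys == other._keys
        )

    def __hash__(self):
        return hash((self.bin_size, self.assembly, self._keys))

    def __repr__(self) -> str:
        return f"BinSet(n={len(self)}, bin_size={self.bin_size}, assembly={self.assembly!r})"

    @property
    def bins(self) -> Tuple[GenomicBin, ...]:
        bs = self.bin_size
        return tuple(
            GenomicBin(c, i * bs, (i + 1) * bs, i) for c, i in sorted(self._keys)
        )

    # -- set algebra -------------------------------------------------------
    def _check(self, other: "BinSet") -> None:
        if self.bin_size != other.bin_size:
            raise ValueError(
                f"bin-size mismatch: {self.bin_size} vs {other.bin_size}"
            )

    def _make(self, keys) -> "BinSet":
        return BinSet(keys, self.bin_size, self.assembly)

    def union(self, other: "BinSet") -> "BinSet":
        self._check(other)
        return self._make(self._keys | other._keys)

    def intersection(self, other: "BinSet") -> "BinSet":
        self._check(other)
        return self._make(self._keys & other._keys)

    def difference(self, other: "BinSet") -> "BinSet":
        self._check(other)
        return self._make(self._keys - other._keys)

    __or__ = union
    __and__ = intersection
    __sub__ = difference


def load_chrom_sizes(source: Union[str, Path]) -> Dict[str, int]:
    """Load a two-column chromosome-sizes table.

    ``source`` is either a bundled assembly name (``hg38``, ``mm10``) or a
    path to a plain-text file with ``name<TAB>length`` lines.
    """
    if str(source) in ("hg38", "mm10"):
        text = (resources.files("simpa.data") / f"{source}.chrom.sizes").read_text()
    else:
        text = Path(source).read_text()
    sizes: Dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"chrom sizes line {lineno}: expected 2 columns")
        name = normalize_chrom(fields[0])
        length = int(fields[1])
        if length <= 0:
            raise ValueError(f"chrom sizes line {lineno}: non-positive length")
        if name in sizes:
            raise ValueError(f"chrom sizes line {lineno}: duplicate chromosome {name}")
        sizes[name] = length
    if not sizes:
        raise ValueError("empty chromosome sizes table")
    return sizes


def peaks_to_bins(
    peaks: Iterable[Tuple[str, int, int]],
    bin_size: int,
    chrom_filter: Optional[Set[str]] = None,
    chrom_sizes: Optional[ChromSizes] = None,
    assembly: str = "unknown",
) -> BinSet:
    """Convert peak intervals to the set of bins they overlap.

    A bin is included iff at least one peak overlaps it by >= 1 bp (no
    minimum-overlap fraction).  Intervals are 0-based half-open.  Chromosomes
    outside ``chrom_filter`` are dropped silently; chromosomes unknown to
    ``chrom_sizes`` (when given) are dropped with a warning.
    """
    bin_size = int(bin_size)
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    if chrom_filter is not None:
        chrom_filter = {normalize_chrom(c) for c in chrom_filter}
    keys = set()
    for chrom, start, end in peaks:
        chrom = normalize_chrom(chrom)
        start, end = int(start), int(end)
        if start < 0 or end <= start:
            raise ValueError(
                f"invalid interval {chrom}:[{start},{end}): need 0 <= start < end"
            )
        if chrom_filter is not None and chrom not in chrom_filter:
            continue
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                warnings.warn(f"dropping interval on unknown chromosome {chrom}")
                continue
            end = min(end, chrom_sizes[chrom])
            if end <= start:
                continue
        first = start // bin_size
        last = (end - 1) // bin_size
        for idx in range(first, last + 1):
            keys.add((chrom, idx))
    return BinSet(keys, bin_size, assembly)


def count_genome_bins(chrom_sizes: ChromSizes, bin_size: int) -> int:
    """Number of bins tiling a genome: sum over chromosomes of ceil(len / bin_size)."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    if not chrom_sizes:
        raise ValueError("empty chromosome sizes")
    return sum(math.ceil(length / bin_size) for length in chrom_sizes.values())


_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(
    path: Union[str, Path],
    bin_size: int,
    assembly: str = "unknown",
    chrom_filter: Optional[Set[str]] = None,
    chrom_sizes: Optional[ChromSizes] = None,
) -> BinSet:
    """Read a BED3+ file and bin its regions.

    Regions spanning several bins mark all of them present.  Malformed lines
    raise a ``ValueError`` carrying the line number.
    """
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start},{end})"
                )
            intervals.append((fields[0], start, end))
    return peaks_to_bins(
        intervals, bin_size, chrom_filter=chrom_filter, chrom_sizes=chrom_sizes,
        assembly=assembly,
    )


def write_bed(binset: BinSet, path: Union[str, Path]) -> None:
    """Write a BinSet as sorted BED3 (one line per bin)."""
    with open(path, "w") as handle:
        for b in binset.bins:
            handle.write(f"{b.chrom}\t{b.start}\t{b.end}\n")


_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+?)[:_](?P<start>\d+)[-_](?P<end>\d+)$")


def _parse_region_label(label: str) -> Tuple[str, int, int]:
    match = _REGION_RE.match(str(label).strip())
    if match is None:
        raise ValueError(f"unparseable region label {label!r}")
    return (
        normalize_chrom(match.group("chrom")),
        int(match.group("start")),
        int(match.group("end")),
    )


def matrix_to_cell_beds(
    matrix: Union[pd.DataFrame, str, Path],
    bin_size: int,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE_CHROMS,
    assembly: str = "unknown",
) -> Dict[str, BinSet]:
    """Split a regions x cells count matrix into one BinSet per cell.

    Rows are labeled ``chrom:start-end`` or ``chrom_start_end``; a bin is
    present in a cell iff the region overlapping it has count > 0.  Rows on
    excluded chromosomes (sex chromosomes and chrM by default) are dropped
    for every cell.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.read_csv(matrix, sep=None, engine="python", index_col=0)
    exclude = {normalize_chrom(c) for c in exclude_chroms}
    regions = [_parse_region_label(label) for label in matrix.index]
    cells: Dict[str, BinSet] = {}
    values = matrix.to_numpy()
    for j, cell in enumerate(matrix.columns):
        intervals = [
            region
            for region, count in zip(regions, values[:, j])
            if count > 0 and region[0] not in exclude
        ]
        cells[str(cell)] = peaks_to_bins(intervals, bin_size, assembly=assembly)
    return cells
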