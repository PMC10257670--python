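"""Genomic interval model and BED/bedGraph/chrom-sizes/stranded-read I/O.

All coordinates are 0-based, half-open (BED convention). Intervals within an
annotation track are merged before any bp-length arithmetic so overlapping
features never double-count bases.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "GenomicInterval",
    "ChromSizes",
    "StrandedReadSet",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "read_stranded_reads",
    "overlap_length",
    "merged_length",
    "merge_intervals",
    "bin_counts",
]

VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph/chrom-sizes lines, naming the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic interval, 0-based half-open, with optional BED6 fields."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(Mapping[str, int]):
    """Mapping chromosome name -> length in bp; total_length is the genome size L_g."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        self._sizes = dict(items)

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"ChromSizes({self._sizes!r})"


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) TSV."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length") from exc
            pairs.append((fields[0], length))
    return ChromSizes(pairs)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def _parse_bed_line(
    fields: Sequence[str], path: str | Path, lineno: int
) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    name = fields[3] if len(fields) >= 4 else None
    score: float | None = None
    if len(fields) >= 5 and fields[4] not in ("", "."):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
    strand = fields[5] if len(fields) >= 6 else "."
    if strand not in VALID_STRANDS:
        raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
    try:
        return GenomicInterval(fields[0], start, end, strand, name, score)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(
    path: str | Path, n_columns_expected: int | None = None
) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (strand from column 6 when present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if n_columns_expected is not None and len(fields) != n_columns_expected:
                raise BedParseError(
                    f"{path}:{lineno}: expected {n_columns_expected} columns, "
                    f"got {len(fields)}"
                )
            out.append(_parse_bed_line(fields, path, lineno))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED3 when no interval carries name/score/strand, else BED6.

    Round-trips with :func:`read_bed` field-for-field.
    """
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                score = "." if iv.score is None else f"{iv.score:g}"
                name = "." if iv.name is None else iv.name
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(
    intervals: Iterable[GenomicInterval] | Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Sort and merge overlapping/adjacent-overlapping intervals per chromosome.

    Returns chrom -> (n, 2) int64 array of disjoint [start, end) rows. Already
    merged dicts pass through unchanged.
    """
    if isinstance(intervals, Mapping):
        return dict(intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged: list[list[int]] = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def merged_length(intervals: Iterable[GenomicInterval] | Mapping[str, np.ndarray]) -> int:
    """Total bp covered by the union of the intervals."""
    merged = merge_intervals(intervals)
    return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in merged.values()))


def overlap_length(
    set_a: Iterable[GenomicInterval] | Mapping[str, np.ndarray],
    set_b: Iterable[GenomicInterval] | Mapping[str, np.ndarray],
) -> int:
    """Total bp of intersection between the unions of two interval sets."""
    ma, mb = merge_intervals(set_a), merge_intervals(set_b)
    total = 0
    for chrom in ma.keys() & mb.keys():
        a, b = ma[chrom], mb[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
    return total


# ---------------------------------------------------------------------------
# stranded reads


class StrandedReadSet:
    """Strand-labeled read placements, stored as sorted per-chromosome 5'-end arrays.

    Each read is reduced to (chrom, pos5, strand) where pos5 is the 5'-most
    aligned base (0-based): the start of a Watson (+) read, the last base
    (end - 1) of a Crick (-) read.
    """

    def __init__(self, records: Iterable[tuple[str, int, str]] = ()):
        buckets: dict[str, dict[str, list[int]]] = defaultdict(
            lambda: {"W": [], "C": []}
        )
        n = 0
        for chrom, pos5, strand in records:
            if strand not in ("W", "C"):
                raise ValueError(f"strand must be 'W' or 'C', got {strand!r}")
            if pos5 < 0:
                raise ValueError(f"negative pos5 {pos5} on {chrom}")
            buckets[chrom][strand].append(pos5)
            n += 1
        self._pos: dict[str, dict[str, np.ndarray]] = {
            chrom: {s: np.sort(np.asarray(v, dtype=np.int64)) for s, v in d.items()}
            for chrom, d in buckets.items()
        }
        self._total = n

    @property
    def total_count(self) -> int:
        return self._total

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        """Sorted pos5 array for one chromosome and strand ('W' or 'C')."""
        if strand not in ("W", "C"):
            raise ValueError("strand must be 'W' or 'C'")
        return self._pos.get(chrom, {}).get(strand, np.empty(0, dtype=np.int64))

    def iter_records(self) -> Iterator[tuple[str, int, str]]:
        for chrom in self.chroms:
            for strand in ("W", "C"):
                for pos in self._pos[chrom][strand]:
                    yield chrom, int(pos), strand

    def swap_strands(self) -> "StrandedReadSet":
        """Relabel every W read as C and vice versa (bias antisymmetry checks)."""
        out = StrandedReadSet()
        out._pos = {
            chrom: {"W": d["C"].copy(), "C": d["W"].copy()}
            for chrom, d in self._pos.items()
        }
        out._total = self._total
        return out

    def validate(self, chrom_sizes: ChromSizes) -> None:
        for chrom, d in self._pos.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"reads on unknown chromosome {chrom!r}")
            for arr in d.values():
                if arr.size and arr[-1] >= chrom_sizes[chrom]:
                    raise ValueError(
                        f"read pos5 {int(arr[-1])} beyond end of {chrom}"
                    )

    def count_in(self, chrom: str, start: int, end: int, strand: str | None = None) -> int:
        """Number of reads with pos5 in [start, end); both strands if strand None."""
        strands = ("W", "C") if strand is None else (strand,)
        n = 0
        for s in strands:
            pos = self.positions(chrom, s)
            n += int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        return n

    def to_bed6(self, path: str | Path, read_length: int = 50) -> None:
        """Write reads as BED6 (W on '+', C on '-'); inverse of from_bed6."""
        with open(path, "w") as fh:
            for i, (chrom, pos5, strand) in enumerate(self.iter_records()):
                if strand == "W":
                    start, end, bs = pos5, pos5 + read_length, "+"
                else:
                    start, end, bs = max(0, pos5 - read_length + 1), pos5 + 1, "-"
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{bs}\n")

    @classmethod
    def from_bed6(cls, path: str | Path) -> "StrandedReadSet":
        def gen() -> Iterator[tuple[str, int, str]]:
            with open(path) as fh:
                for lineno, raw in enumerate(fh, 1):
                    line = raw.rstrip("\n")
                    if not line.strip() or line.startswith(("track", "browser", "#")):
                        continue
                    fields = line.split("\t")
                    if len(fields) < 6:
                        raise BedParseError(
                            f"{path}:{lineno}: BED6 required (strand column missing)"
                        )
                    iv = _parse_bed_line(fields, path, lineno)
                    if iv.strand == ".":
                        raise BedParseError(
                            f"{path}:{lineno}: read without strand"
                        )
                    if iv.strand == "+":
                        yield iv.chrom, iv.start, "W"
                    else:
                        yield iv.chrom, iv.end - 1, "C"

        return cls(gen())

    @classmethod
    def from_sam(cls, path: str | Path) -> "StrandedReadSet":
        """Read mapped alignments from SAM/BAM via pysam.

        Paired-end strand is taken from the first mate only; secondary,
        supplementary and unmapped records are skipped.
        """
        import pysam

        records: list[tuple[str, int, str]] = []
        n_seen = 0
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for aln in sam.fetch(until_eof=True):
                n_seen += 1
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.is_paired and not aln.is_read1:
                    continue
                if aln.is_reverse:
                    records.append(
                        (aln.reference_name, aln.reference_end - 1, "C")
                    )
                else:
                    records.append((aln.reference_name, aln.reference_start, "W"))
        if n_seen and not records:
            warnings.warn(f"{path}: no usable mapped reads", stacklevel=2)
        return cls(records)


def read_stranded_reads(path: str | Path, format: str = "bed6") -> StrandedReadSet:
    """Load stranded reads from 'bed6' (canonical) or 'sam' input."""
    if format == "bed6":
        return StrandedReadSet.from_bed6(path)
    if format == "sam":
        return StrandedReadSet.from_sam(path)
    raise ValueError(f"unknown format {format!r} (expected 'bed6' or 'sam')")


def bin_counts(
    reads: StrandedReadSet,
    bins: Sequence[GenomicInterval],
    strand_filter: str | None = None,
) -> np.ndarray:
    """Count reads (by pos5) per bin; bins must be sorted and non-overlapping.

    strand_filter 'W' or 'C' restricts to one strand; None counts both.
    """
    prev: dict[str, int] = {}
    for i, b in enumerate(bins):
        if b.chrom in prev and bins[prev[b.chrom]].end > b.start:
            raise ValueError(f"bins unsorted or overlapping at index {i}")
        prev[b.chrom] = i
    counts = np.zeros(len(bins), dtype=np.int64)
    for i, b in enumerate(bins):
        counts[i] = reads.count_in(b.chrom, b.start, b.end, strand_filter)
    return counts


# ---------------------------------------------------------------------------
# signal tracks (bedGraph semantics)


@dataclass
class SignalTrack:
    """Sorted, disjoint intervals carrying float values (bedGraph semantics)."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in self.intervals:
            if iv.score is None or not np.isfinite(iv.score):
                raise ValueError(f"non-finite value on {iv.chrom}:{iv.start}")
            by_chrom[iv.chrom].append(iv)
        for chrom, ivs in by_chrom.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"unsorted/overlapping track on {chrom}")

    def value_at(self, chrom: str, pos: int) -> float:
        for iv in self.intervals:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return float(iv.score)  # type: ignore[arg-type]
        return 0.0

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), score=float(fields[3])
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return SignalTrack(intervals)
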