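"""Genomic interval primitives and BED-format I/O.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases, and two intervals that merely
abut (``a.end == b.start``) do not overlap. Chromosome names are compared as
exact strings; no "chr" aliasing is performed.

Overlap requires at least one shared base; no reciprocal-fraction requirement
is imposed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "TSSAnnotation",
    "TSSEntry",
    "IntervalIndex",
    "BedParseError",
    "overlaps",
    "merge_overlapping",
    "read_bed",
    "write_bed",
    "read_tss_bed",
    "site_id",
    "parse_region",
]

_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED / bedGraph lines; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome.

    Ordering (and therefore sorting of :class:`PeakSet`) is by
    ``(chrom, start, end)``; ``name``, ``score`` and ``strand`` are carried
    metadata and do not participate in comparisons.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, rounded down on a half-base tie."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (same chromosome)."""
    return a.overlaps(b)


def site_id(interval: GenomicInterval) -> str:
    """Stable identifier for a site: its name if set, else ``chrom:start-end``."""
    if interval.name:
        return interval.name
    return f"{interval.chrom}:{interval.start}-{interval.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string back into an interval."""
    try:
        chrom, rest = text.rsplit(":", 1)
        start_s, end_s = rest.split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except ValueError as exc:
        raise ValueError(f"cannot parse region string {text!r}") from exc


@dataclass
class PeakSet:
    """An ordered collection of intervals from one replicate / condition."""

    intervals: list[GenomicInterval]
    condition: str | None = None
    replicate_id: str | None = None
    is_sorted: bool = False

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "PeakSet":
        """Return a copy sorted by (chrom, start, end)."""
        return replace(self, intervals=sorted(self.intervals), is_sorted=True)

    def merged(self) -> "PeakSet":
        return merge_overlapping(self)

    def total_bases(self) -> int:
        """Bases covered counting every interval (use ``merged()`` first for a union)."""
        return sum(iv.width for iv in self.intervals)


def merge_overlapping(peaks: PeakSet) -> PeakSet:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Half-open abutting intervals (``a.end == b.start``) are *not* merged:
    they share no base.
    """
    ivs = sorted(peaks.intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(
        merged,
        condition=peaks.condition,
        replicate_id=peaks.replicate_id,
        is_sorted=True,
    )


class IntervalIndex:
    """Per-chromosome sorted index answering any-overlap queries in O(log n).

    Built from the merged union of the input peaks, so it answers "does any
    interval of the set overlap this query", which is all the consensus and
    category logic needs.
    """

    def __init__(self, peaks: PeakSet) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merge_overlapping(peaks):
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps_any(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if starts is None:
            return False
        ends = self._ends[query.chrom]
        # last merged interval starting before query.end
        i = int(np.searchsorted(starts, query.end, side="left")) - 1
        return bool(i >= 0 and ends[i] > query.start)


# ---------------------------------------------------------------------------
# BED I/O


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


def read_bed(
    path: str | Path,
    condition: str | None = None,
    replicate_id: str | None = None,
) -> PeakSet:
    """Read BED3/BED6 into a :class:`PeakSet`.

    Track/browser/comment lines are skipped. Optional name (col 4), score
    (col 5, "." allowed) and strand (col 6) are preserved. Malformed lines
    raise :class:`BedParseError` naming the 1-based line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(intervals, condition=condition, replicate_id=replicate_id)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED; emits as many optional columns as the richest record needs."""
    n_cols = 3
    for iv in peaks:
        if iv.strand != ".":
            n_cols = max(n_cols, 6)
        elif iv.score is not None:
            n_cols = max(n_cols, 5)
        elif iv.name is not None:
            n_cols = max(n_cols, 4)
    with Path(path).open("w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols >= 5:
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
            if n_cols >= 6:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSS annotation


@dataclass(frozen=True)
class TSSEntry:
    gene: str
    chrom: str
    position: int  # 0-based TSS base
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative TSS position for {self.gene}")


@dataclass
class TSSAnnotation:
    """Transcription start sites; gene names need not be unique."""

    entries: list[TSSEntry]

    def __post_init__(self) -> None:
        self.entries = list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TSSEntry]:
        return iter(self.entries)

    def by_chrom(self) -> dict[str, list[TSSEntry]]:
        out: dict[str, list[TSSEntry]] = {}
        for e in self.entries:
            out.setdefault(e.chrom, []).append(e)
        for lst in out.values():
            lst.sort(key=lambda e: (e.position, e.gene))
        return out


def read_tss_bed(path: str | Path) -> TSSAnnotation:
    """Read a BED6 gene table; the TSS is the strand-aware 5' end.

    For ``+`` (or unstranded) records the TSS is ``start``; for ``-`` records
    it is ``end - 1`` (the last covered base).
    """
    peaks = read_bed(path)
    entries = []
    for iv in peaks:
        pos = iv.start if iv.strand != "-" else iv.end - 1
        entries.append(TSSEntry(iv.name or site_id(iv), iv.chrom, pos, iv.strand))
    return TSSAnnotation(entries)
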