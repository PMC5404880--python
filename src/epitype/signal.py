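"""Coverage tracks, reference-point signal matrices and metagene profiles.

Read 5' positions are turned into coverage in two ways used by the assays:

* ChIP-style: each read is extended by the library's average fragment length
  in its 3' direction and contributes one unit of coverage per covered base
  (:func:`extend_and_pileup`).
* ATAC-style: read 5' ends are first shifted +4 bp (plus strand) / -5 bp
  (minus strand) so they sit on the Tn5 insertion centre
  (:func:`tn5_correct`), compensating for the 9 bp duplication the
  transposase introduces.

Tracks are normalised to reads-per-million and sampled around site centres
into sites x position-bins matrices (default window 1500 bp each side);
column means of such a matrix are the metagene profile, and
:func:`bimodality_index` quantifies the flanking-nucleosome ("bimodal")
signature typical of active enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import BedParseError, GenomicInterval, PeakSet, site_id

__all__ = [
    "ReadRecord",
    "SignalTrack",
    "SiteSignalMatrix",
    "tn5_correct",
    "extend_and_pileup",
    "normalize_per_million",
    "signal_matrix",
    "metagene_profile",
    "bimodality_index",
    "read_bedgraph",
    "write_bedgraph",
]

DEFAULT_WINDOW = 1500
DEFAULT_BIN_SIZE = 50
#: chromosome names dropped before any ATAC analysis (mitochondrial reads)
DEFAULT_EXCLUDED_CHROMS = ("chrM",)


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced read reduced to its 5' position and strand."""

    chrom: str
    five_prime: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError("read 5' position must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")


def tn5_correct(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Shift ATAC read 5' ends onto the Tn5 insertion centre: +4 / -5 bp.

    Plus-strand 5' ends move +4 bp, minus-strand 5' ends move -5 bp; positions
    are clipped at 0 rather than dropping reads, so read count and strand
    composition are preserved exactly.
    """
    out = []
    for r in reads:
        shift = 4 if r.strand == "+" else -5
        out.append(ReadRecord(r.chrom, max(0, r.five_prime + shift), r.strand))
    return out


def exclude_chroms(
    reads: Sequence[ReadRecord], chroms: Sequence[str] = DEFAULT_EXCLUDED_CHROMS
) -> list[ReadRecord]:
    """Drop reads on the given chromosomes (default: mitochondrial)."""
    drop = set(chroms)
    return [r for r in reads if r.chrom not in drop]


@dataclass
class SignalTrack:
    """Binned non-negative coverage per chromosome plus normalisation metadata.

    ``values[chrom][i]`` is the mean per-base coverage of bin ``i`` (bases
    ``[i*bin_size, (i+1)*bin_size)``). ``clipped_mass`` accounts for coverage
    lost to chromosome-end clipping during pileup.
    """

    values: dict[str, np.ndarray]
    bin_size: int = 1
    total_reads: int = 0
    normalized: bool = False
    fragment_length: int | None = None
    clipped_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, v in self.values.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"negative signal values on {chrom}")

    def chroms(self) -> list[str]:
        return sorted(self.values)

    def covered_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)``; out-of-range bases are 0."""
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        v = self.values[chrom]
        pos = np.arange(start, end, dtype=np.int64)
        out = np.zeros(end - start, dtype=float)
        idx = pos // self.bin_size
        ok = (pos >= 0) & (idx < len(v))
        out[ok] = v[idx[ok]]
        return out

    def total_signal(self) -> float:
        """Sum over all bins weighted by bin width (total per-base mass)."""
        return float(sum(v.sum() * self.bin_size for v in self.values.values()))


def extend_and_pileup(
    reads: Sequence[ReadRecord],
    fragment_length: int,
    bin_size: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> SignalTrack:
    """Extend each read 3' to ``fragment_length`` and pile up coverage.

    A plus-strand read covers ``[p, p+L)``; a minus-strand read covers
    ``[p-L+1, p+1)`` so that its 5' base is included and every read covers
    exactly L bases (mass conservation, before chromosome-end clipping).
    Coverage is aggregated into bins by mean per-base value.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    spans: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        if r.strand == "+":
            s, e = r.five_prime, r.five_prime + fragment_length
        else:
            s, e = r.five_prime - fragment_length + 1, r.five_prime + 1
        spans.setdefault(r.chrom, []).append((s, e))

    values: dict[str, np.ndarray] = {}
    clipped = 0.0
    lengths = dict(chrom_lengths or {})
    for chrom, pairs in spans.items():
        length = lengths.get(chrom)
        if length is None:
            length = max(e for _, e in pairs)
            lengths[chrom] = length
        diff = np.zeros(length + 1, dtype=float)
        for s, e in pairs:
            cs, ce = max(0, s), min(length, e)
            clipped += (e - s) - max(0, ce - cs)
            if ce > cs:
                diff[cs] += 1.0
                diff[ce] -= 1.0
        cov = np.cumsum(diff[:-1])
        if bin_size > 1:
            pad = (-len(cov)) % bin_size
            if pad:
                cov = np.concatenate([cov, np.zeros(pad)])
            cov = cov.reshape(-1, bin_size).mean(axis=1)
        values[chrom] = cov
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            if chrom not in values:
                n = -(-length // bin_size)
                values[chrom] = np.zeros(n)
    return SignalTrack(
        values,
        bin_size=bin_size,
        total_reads=len(reads),
        normalized=False,
        fragment_length=fragment_length,
        clipped_mass=clipped,
    )


def normalize_per_million(track: SignalTrack) -> SignalTrack:
    """Scale every value by 1e6 / total_reads (reads-per-million units)."""
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.total_reads <= 0:
        raise ValueError("cannot normalize a track with total_reads == 0")
    factor = 1e6 / track.total_reads
    return replace(
        track,
        values={c: v * factor for c, v in track.values.items()},
        normalized=True,
    )


@dataclass
class SiteSignalMatrix:
    """Sites x position-bins signal values for one assay/timepoint."""

    site_ids: list[str]
    assay: str
    window: int
    bin_size: int
    values: np.ndarray  # shape (n_sites, 2*window//bin_size)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ncol = 2 * self.window // self.bin_size
        if self.values.ndim != 2 or self.values.shape != (len(self.site_ids), ncol):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {ncol} bins"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the site centre (bp)."""
        return np.arange(-self.window, self.window, self.bin_size)

    def to_tsv(self, path: str | Path) -> None:
        offs = "\t".join(str(o) for o in self.bin_offsets())
        with Path(path).open("w") as fh:
            fh.write(f"site\t{offs}\n")
            for sid, row in zip(self.site_ids, self.values):
                fh.write(sid + "\t" + "\t".join(format(x, ".6g") for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, assay: str = "") -> "SiteSignalMatrix":
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            offsets = [int(x) for x in header[1:]]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(offsets) < 2:
            raise BedParseError(f"{path}: matrix header has fewer than two bins")
        bin_size = offsets[1] - offsets[0]
        window = -offsets[0]
        return cls(ids, assay, window, bin_size, np.array(rows, dtype=float))


def signal_matrix(
    track: SignalTrack,
    sites: PeakSet,
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    assay: str = "",
) -> SiteSignalMatrix:
    """Sample the track in bins of ``[center - window, center + window)`` per site.

    Each matrix entry is the mean per-base value within its bin; bins (or bin
    parts) beyond chromosome ends contribute zeros. Sites on chromosomes the
    track does not cover are an error.
    """
    if window % bin_size != 0:
        raise ValueError(f"window {window} not divisible by bin_size {bin_size}")
    missing = [site_id(iv) for iv in sites if iv.chrom not in track.values]
    if missing:
        raise KeyError(f"sites on chromosomes absent from track: {missing}")
    ncol = 2 * window // bin_size
    out = np.empty((len(sites), ncol), dtype=float)
    ids = []
    for i, iv in enumerate(sites):
        c = iv.center
        per_base = track.per_base(iv.chrom, c - window, c + window)
        out[i] = per_base.reshape(ncol, bin_size).mean(axis=1)
        ids.append(site_id(iv))
    return SiteSignalMatrix(ids, assay, window, bin_size, out)


def metagene_profile(matrix: SiteSignalMatrix) -> np.ndarray:
    """Column-wise mean signal across sites (the average profile)."""
    if matrix.n_sites == 0:
        raise ValueError("metagene profile of an empty matrix is undefined")
    return matrix.values.mean(axis=0)


def bimodality_index(
    profile: np.ndarray,
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    flank: tuple[int, int] = (200, 1000),
    center_halfwidth: int = 200,
    eps: float = 1e-9,
) -> float:
    """Flank-to-centre signal ratio of a metagene profile.

    Mean over the flank bins spanning ``[-1000, -200)`` and ``[200, 1000)``
    divided by the mean over the centre bins ``[-200, 200)`` (plus a small
    epsilon). Values > 1 indicate flanking enrichment — the bimodal
    nucleosome configuration of active enhancers; values < 1 indicate a
    centre-peaked profile.
    """
    if window < flank[1]:
        raise ValueError(
            f"window {window} bp too small for flank extent {flank[1]} bp"
        )
    profile = np.asarray(profile, dtype=float)
    if len(profile) != 2 * window // bin_size:
        raise ValueError("profile length inconsistent with window/bin_size")
    left = np.arange(-window, window, bin_size)
    right = left + bin_size
    inner, outer = flank
    flank_mask = ((left >= -outer) & (right <= -inner)) | (
        (left >= inner) & (right <= outer)
    )
    center_mask = (left >= -center_halfwidth) & (right <= center_halfwidth)
    if not flank_mask.any() or not center_mask.any():
        raise ValueError("no complete bins fall inside the flank/centre windows")
    return float(profile[flank_mask].mean() / (eps + profile[center_mask].mean()))


# ---------------------------------------------------------------------------
# bedGraph I/O


def read_bedgraph(path: str | Path, bin_size: int = 1) -> SignalTrack:
    """Read a bedGraph (chrom, start, end, value) into a track at ``bin_size``.

    Every record's span must be aligned to the requested bin grid.
    """
    values: dict[str, list[tuple[int, int, float]]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split("\t")
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end, val = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: malformed record") from None
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{lineno}: bad span {start}-{end}")
            if start % bin_size or end % bin_size:
                raise BedParseError(
                    f"{path}:{lineno}: span not aligned to bin_size {bin_size}"
                )
            values.setdefault(parts[0], []).append((start, end, val))
    arrays: dict[str, np.ndarray] = {}
    for chrom, recs in values.items():
        length = max(e for _, e, _ in recs) // bin_size
        arr = np.zeros(length, dtype=float)
        for s, e, v in recs:
            arr[s // bin_size : e // bin_size] = v
        arrays[chrom] = arr
    return SignalTrack(arrays, bin_size=bin_size)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length-merging equal adjacent bins."""
    with Path(path).open("w") as fh:
        for chrom in track.chroms():
            v = track.values[chrom]
            if len(v) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0.0:
                    fh.write(
                        f"{chrom}\t{s * track.bin_size}\t{e * track.bin_size}"
                        f"\t{format(v[s], '.6g')}\n"
                    )
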