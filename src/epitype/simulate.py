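"""Ground-truthed synthetic data with the structure the analysis assumes.

The generator emulates a factor-withdrawal study: an inducibly expressed
transcription factor binds a set of genomic sites; replicate peak calls in
the induced (treatment) and uninduced (control) conditions carry
per-replicate sensitivity and false-positive noise; accessibility tracks
over the withdrawal time course lose signal at Type 1 sites by the first
post-withdrawal timepoint while Type 2 sites persist; enhancer marks
(H3K4me1 / H3K27ac) form bimodal flanking profiles at bound sites, H3K4me3
is promoter-restricted, and repressive H3K27me3 blocks are kept disjoint
from all bound sites; a co-binding factor (MyoD-like) sits at small centre
offsets near Type 2 sites only; and an expression table carries a planted
up/down fold-change signature.

Everything is deterministic for a fixed :class:`SimulationConfig` seed; the
per-stage random streams are derived as ``default_rng([seed, stage_id])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    PeakSet,
    TSSAnnotation,
    TSSEntry,
)
from .signal import SignalTrack

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_truth",
    "simulate_peak_replicates",
    "simulate_tracks",
    "simulate_expression",
    "simulate_accessibility_panel",
    "reference_site_standin",
    "TIMEPOINTS",
]

TIMEPOINTS = ("+Dox", "-Dox_12h", "-Dox_24h", "-Dox_3d")

# per-stage random stream identifiers (combined with the config seed)
_STAGE_TRUTH = 1
_STAGE_PEAKS = 2
_STAGE_TRACKS = 3
_STAGE_EXPRESSION = 4
_STAGE_PANEL = 5


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults encode the simulated experiment every test and the acceptance
    run share: 500 sites on a 3 x 2 Mb genome, 60% Type 1 collapsing to 10%
    of baseline accessibility at the first withdrawal timepoint, 40% Type 2
    persisting at 90%, three treatment and two control replicates called at
    90% per-replicate sensitivity, and 200 expected reads per site per track.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    n_sites: int = 500
    type1_fraction: float = 0.6
    site_width: int = 300
    timepoints: tuple[str, ...] = TIMEPOINTS
    type1_decays: tuple[float, ...] = (1.0, 0.1, 0.05, 0.02)
    type2_decays: tuple[float, ...] = (1.0, 0.9, 0.88, 0.85)
    # replicate peak calling
    n_treatment_reps: int = 3
    n_control_reps: int = 2
    sensitivity: float = 0.9
    false_peaks_per_mb: float = 5.0
    peak_jitter: int = 10
    # tracks
    reads_per_site: float = 200.0
    mark_reads_per_site: float = 200.0
    promoter_reads: float = 200.0
    background_rate: float = 0.01  # expected reads per base outside features
    atac_sigma: float = 100.0
    flank_offset: int = 500
    flank_sigma: float = 150.0
    repressive_rate: float = 0.2
    n_repressive_blocks: int = 30
    repressive_width: int = 20_000
    # mark-peak retention after withdrawal (drives enhancer loss, Fig-4C-like)
    mark_retention: dict[str, float] = field(
        default_factory=lambda: {"Type1": 0.2, "Type2": 0.9}
    )
    # annotation
    n_tss_extra: int = 200
    promoter_site_fraction: float = 0.12
    # co-binding factor near Type 2 sites; folded-normal offsets with
    # median sigma*0.6745 ~ 240 bp
    cofactor_offset_sigma: float = 356.0
    cofactor_peak_width: int = 200
    # expression table
    n_genes: int = 100
    fold_grid: tuple[float, ...] = (4.0, 2.5, 2.0, 1.0, 0.5, 0.4, 0.25)
    satellite_expressed_prob: float = 0.8
    expression_noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        for name, p in (
            ("type1_fraction", self.type1_fraction),
            ("sensitivity", self.sensitivity),
            ("satellite_expressed_prob", self.satellite_expressed_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if len(self.type1_decays) != len(self.timepoints):
            raise ValueError("type1_decays must match timepoints")
        if len(self.type2_decays) != len(self.timepoints):
            raise ValueError("type2_decays must match timepoints")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator; the oracle for every stage."""

    config: SimulationConfig
    sites: PeakSet  # named site0000.., sorted
    types: list[str]  # Type1 / Type2 per site
    decays: np.ndarray  # (n_sites, n_timepoints)
    mark_k4me1: np.ndarray  # bool per site, at baseline
    mark_k27ac: np.ndarray
    mark_retained: np.ndarray  # bool: marks survive withdrawal
    cofactor_offset: list[int | None]  # signed bp from centre; Type 2 only
    tss: TSSAnnotation
    repressive_blocks: PeakSet
    expression: pd.DataFrame  # gene-indexed: satellite/treatment/withdrawal (+fold)
    down_genes: list[str]
    up_genes: list[str]

    @property
    def site_ids(self) -> list[str]:
        return [iv.name or "" for iv in self.sites]

    def type_of(self) -> dict[str, str]:
        return dict(zip(self.site_ids, self.types))

    def sites_of_type(self, label: str) -> PeakSet:
        return PeakSet(
            [iv for iv, t in zip(self.sites, self.types) if t == label],
            is_sorted=True,
        )

    def cofactor_peaks(self) -> PeakSet:
        """Peaks of the co-binding factor, offset from Type 2 site centres."""
        w = self.config.cofactor_peak_width
        out = []
        for iv, off in zip(self.sites, self.cofactor_offset):
            if off is None:
                continue
            c = iv.center + off
            out.append(GenomicInterval(iv.chrom, max(0, c - w // 2), c + w // 2))
        return PeakSet(sorted(out), is_sorted=True)

    def mark_peaks(self, after_withdrawal: bool = False) -> tuple[PeakSet, PeakSet]:
        """Called H3K4me1 / H3K27ac peak sets before or after withdrawal.

        A marked site carries a +/-1 kb mark region; after withdrawal only
        sites whose ``mark_retained`` flag is set keep their regions.
        """
        k4, k27 = [], []
        for iv, m1, m2, kept in zip(
            self.sites, self.mark_k4me1, self.mark_k27ac, self.mark_retained
        ):
            if after_withdrawal and not kept:
                continue
            region = GenomicInterval(
                iv.chrom, max(0, iv.center - 1000), iv.center + 1000
            )
            if m1:
                k4.append(region)
            if m2:
                k27.append(region)
        return PeakSet(k4, is_sorted=True), PeakSet(k27, is_sorted=True)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, iv in enumerate(self.sites):
            rows.append(
                {
                    "site": iv.name,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "type": self.types[i],
                    "k4me1": bool(self.mark_k4me1[i]),
                    "k27ac": bool(self.mark_k27ac[i]),
                    "mark_retained": bool(self.mark_retained[i]),
                    "cofactor_offset": (
                        "" if self.cofactor_offset[i] is None else self.cofactor_offset[i]
                    ),
                    **{
                        f"decay_{tp}": self.decays[i, t]
                        for t, tp in enumerate(self.config.timepoints)
                    },
                }
            )
        return pd.DataFrame(rows)


def _allocate_per_chrom(cfg: SimulationConfig) -> list[tuple[str, int]]:
    """Largest-remainder allocation of site counts to chromosomes."""
    chroms = sorted(cfg.chrom_lengths)
    total = sum(cfg.chrom_lengths.values())
    raw = {c: cfg.n_sites * cfg.chrom_lengths[c] / total for c in chroms}
    counts = {c: int(raw[c]) for c in chroms}
    leftover = cfg.n_sites - sum(counts.values())
    for c in sorted(chroms, key=lambda c: raw[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1
    return [(c, counts[c]) for c in chroms]


def simulate_truth(cfg: SimulationConfig) -> SyntheticTruth:
    """Draw the ground truth: site placement, types, marks, TSSs, expression.

    Sites are placed one per equal-width slot (with a margin wide enough for
    flanking-mark profiles), guaranteeing disjoint sites; the Type 1 count is
    exactly ``round(n_sites * type1_fraction)``.
    """
    rng = cfg.rng(_STAGE_TRUTH)
    margin = int(cfg.flank_offset + 4 * cfg.flank_sigma + cfg.site_width)
    intervals: list[GenomicInterval] = []
    for chrom, n_c in _allocate_per_chrom(cfg):
        if n_c == 0:
            continue
        slot = cfg.chrom_lengths[chrom] // n_c
        if slot < 2 * margin + cfg.site_width:
            raise ValueError(
                f"{n_c} sites do not fit disjointly on {chrom} "
                f"({cfg.chrom_lengths[chrom]} bp; need slots >= {2 * margin + cfg.site_width} bp)"
            )
        for i in range(n_c):
            lo = i * slot + margin
            hi = (i + 1) * slot - margin - cfg.site_width
            start = int(rng.integers(lo, hi + 1))
            intervals.append(
                GenomicInterval(chrom, start, start + cfg.site_width)
            )
    intervals.sort()
    intervals = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"site{i:04d}")
        for i, iv in enumerate(intervals)
    ]
    n = len(intervals)

    n_type1 = round(cfg.n_sites * cfg.type1_fraction)
    labels = np.array(["Type1"] * n_type1 + ["Type2"] * (n - n_type1))
    rng.shuffle(labels)
    types = labels.tolist()

    decays = np.array(
        [
            cfg.type1_decays if t == "Type1" else cfg.type2_decays
            for t in types
        ],
        dtype=float,
    )

    mark_k4me1 = np.ones(n, dtype=bool)
    mark_k27ac = np.ones(n, dtype=bool)
    retention_p = np.array([cfg.mark_retention[t] for t in types])
    mark_retained = rng.random(n) < retention_p

    cofactor: list[int | None] = []
    for t in types:
        if t == "Type2":
            off = abs(rng.normal(0.0, cfg.cofactor_offset_sigma))
            sign = 1 if rng.random() < 0.5 else -1
            cofactor.append(sign * int(round(off)))
        else:
            cofactor.append(None)

    # TSSs: a promoter TSS within 1 kb for a fraction of sites, plus extras
    n_prom = round(n * cfg.promoter_site_fraction)
    prom_idx = rng.choice(n, size=n_prom, replace=False)
    entries: list[TSSEntry] = []
    for j, i in enumerate(sorted(prom_idx)):
        iv = intervals[i]
        offset = int(rng.integers(-900, 901))
        pos = max(0, iv.center + offset)
        entries.append(TSSEntry(f"pgene{j:04d}", iv.chrom, pos, "+"))
    chroms = sorted(cfg.chrom_lengths)
    for j in range(cfg.n_tss_extra):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, cfg.chrom_lengths[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        entries.append(TSSEntry(f"gene{j:04d}", chrom, pos, strand))
    tss = TSSAnnotation(entries)

    # repressive blocks disjoint from all sites (asserted)
    site_idx = IntervalIndex(
        PeakSet(
            [GenomicInterval(iv.chrom, max(0, iv.start - 2000), iv.end + 2000)
             for iv in intervals]
        )
    )
    blocks: list[GenomicInterval] = []
    attempts = 0
    while len(blocks) < cfg.n_repressive_blocks and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_lengths[chrom] - cfg.repressive_width))
        cand = GenomicInterval(chrom, start, start + cfg.repressive_width)
        if site_idx.overlaps_any(cand):
            continue
        if any(cand.overlaps(b) for b in blocks):
            continue
        blocks.append(cand)
    repressive = PeakSet(sorted(blocks), is_sorted=True)
    block_check = IntervalIndex(repressive)
    assert not any(block_check.overlaps_any(iv) for iv in intervals), (
        "repressive blocks must stay disjoint from planted sites"
    )

    # expression table expectations with a planted fold-change grid
    genes = [f"xgene{j:04d}" for j in range(cfg.n_genes)]
    folds = np.array(
        [cfg.fold_grid[j % len(cfg.fold_grid)] for j in range(cfg.n_genes)]
    )
    # floor keeps pseudocounted ratios close to the planted folds
    base = 50.0 + rng.lognormal(mean=math.log(100.0), sigma=0.5, size=cfg.n_genes)
    sat_expressed = rng.random(cfg.n_genes) < cfg.satellite_expressed_prob
    satellite = np.where(
        sat_expressed, rng.lognormal(math.log(50.0), 0.5, cfg.n_genes), 0.0
    )
    expression = pd.DataFrame(
        {
            "satellite": satellite,
            "treatment": base * folds,
            "withdrawal": base,
            "planted_fold": folds,
        },
        index=pd.Index(genes, name="gene"),
    )
    down = [g for g, f, s in zip(genes, folds, sat_expressed) if s and f >= 2.0]
    up = [g for g, f, s in zip(genes, folds, sat_expressed) if s and f <= 0.5]

    return SyntheticTruth(
        config=cfg,
        sites=PeakSet(intervals, condition="truth", is_sorted=True),
        types=types,
        decays=decays,
        mark_k4me1=mark_k4me1,
        mark_k27ac=mark_k27ac,
        mark_retained=mark_retained,
        cofactor_offset=cofactor,
        tss=tss,
        repressive_blocks=repressive,
        expression=expression,
        down_genes=down,
        up_genes=up,
    )


def simulate_peak_replicates(
    truth: SyntheticTruth, cfg: SimulationConfig | None = None
) -> tuple[list[PeakSet], list[PeakSet]]:
    """Replicate peak calls: true sites at ``sensitivity`` plus false peaks.

    Each treatment replicate contains each true site independently with
    probability ``cfg.sensitivity`` (edges jittered a few bp), plus Poisson
    false peaks at ``false_peaks_per_mb`` placed away from true sites.
    Control replicates contain only false peaks.
    """
    cfg = cfg or truth.config
    rng = cfg.rng(_STAGE_PEAKS)
    site_idx = IntervalIndex(
        PeakSet(
            [
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - cfg.site_width),
                    iv.end + cfg.site_width,
                )
                for iv in truth.sites
            ]
        )
    )

    def false_peaks() -> list[GenomicInterval]:
        out = []
        for chrom in sorted(cfg.chrom_lengths):
            length = cfg.chrom_lengths[chrom]
            n_false = rng.poisson(cfg.false_peaks_per_mb * length / 1e6)
            made = 0
            while made < n_false:
                start = int(rng.integers(0, length - cfg.site_width))
                cand = GenomicInterval(chrom, start, start + cfg.site_width)
                if site_idx.overlaps_any(cand):
                    continue
                out.append(cand)
                made += 1
        return out

    treatment: list[PeakSet] = []
    for r in range(cfg.n_treatment_reps):
        ivs: list[GenomicInterval] = []
        for iv in truth.sites:
            if rng.random() >= cfg.sensitivity:
                continue
            j1 = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
            j2 = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
            start = max(0, iv.start + j1)
            end = max(start + 1, iv.end + j2)
            ivs.append(GenomicInterval(iv.chrom, start, end))
        ivs.extend(false_peaks())
        treatment.append(
            PeakSet(sorted(ivs), condition="treatment", replicate_id=f"T{r + 1}",
                    is_sorted=True)
        )
    control: list[PeakSet] = []
    for r in range(cfg.n_control_reps):
        control.append(
            PeakSet(sorted(false_peaks()), condition="control",
                    replicate_id=f"C{r + 1}", is_sorted=True)
        )
    return treatment, control


def _add_kernel(
    rate: np.ndarray, center: int, amplitude: float, sigma: float
) -> None:
    """Add ``amplitude`` reads spread as a Gaussian (truncated at 4 sigma)."""
    half = int(4 * sigma)
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    lo, hi = center - half, center + half + 1
    klo = max(0, -lo)
    lo = max(0, lo)
    hi = min(len(rate), hi)
    if hi > lo:
        rate[lo:hi] += amplitude * kernel[klo : klo + (hi - lo)]


def simulate_tracks(
    truth: SyntheticTruth,
    cfg: SimulationConfig | None = None,
    assays: Sequence[str] = ("ATAC", "H3K4me1", "H3K27ac", "H3K4me3", "H3K27me3"),
    timepoints: Sequence[str] | None = None,
) -> dict[str, SignalTrack]:
    """Per-base Poisson count tracks for each assay and timepoint.

    Keys are ``"{assay}:{timepoint}"``. ATAC signal is a centre Gaussian
    (sigma 100 bp) scaled by each site's per-timepoint decay; H3K4me1 and
    H3K27ac are symmetric flank Gaussians at +/-500 bp (sigma 150 bp),
    likewise decaying at Type 1 sites after withdrawal; H3K4me3 is a centre
    Gaussian at planted TSSs only; H3K27me3 is a uniform elevation inside
    its blocks, disjoint from all bound sites.
    """
    cfg = cfg or truth.config
    timepoints = tuple(timepoints or cfg.timepoints)
    rng = cfg.rng(_STAGE_TRACKS)
    chroms = sorted(cfg.chrom_lengths)
    tp_index = {tp: t for t, tp in enumerate(cfg.timepoints)}
    tracks: dict[str, SignalTrack] = {}
    for assay in assays:
        for tp in timepoints:
            t = tp_index[tp]
            values: dict[str, np.ndarray] = {}
            for chrom in chroms:
                rate = np.full(cfg.chrom_lengths[chrom], cfg.background_rate)
                if assay == "ATAC":
                    for i, iv in enumerate(truth.sites):
                        if iv.chrom != chrom:
                            continue
                        _add_kernel(
                            rate, iv.center,
                            cfg.reads_per_site * truth.decays[i, t],
                            cfg.atac_sigma,
                        )
                elif assay in ("H3K4me1", "H3K27ac"):
                    flags = truth.mark_k4me1 if assay == "H3K4me1" else truth.mark_k27ac
                    for i, iv in enumerate(truth.sites):
                        if iv.chrom != chrom or not flags[i]:
                            continue
                        amp = cfg.mark_reads_per_site * truth.decays[i, t] / 2.0
                        _add_kernel(rate, iv.center - cfg.flank_offset, amp,
                                    cfg.flank_sigma)
                        _add_kernel(rate, iv.center + cfg.flank_offset, amp,
                                    cfg.flank_sigma)
                elif assay == "H3K4me3":
                    for e in truth.tss:
                        if e.chrom == chrom:
                            _add_kernel(rate, e.position, cfg.promoter_reads,
                                        cfg.flank_sigma)
                elif assay == "H3K27me3":
                    for b in truth.repressive_blocks:
                        if b.chrom == chrom:
                            rate[b.start : b.end] += cfg.repressive_rate
                else:
                    raise ValueError(f"unknown assay {assay!r}")
                values[chrom] = rng.poisson(rate).astype(float)
            total = int(sum(v.sum() for v in values.values()))
            tracks[f"{assay}:{tp}"] = SignalTrack(
                values, bin_size=1, total_reads=total, normalized=False
            )
    return tracks


def simulate_expression(
    truth: SyntheticTruth,
    cfg: SimulationConfig | None = None,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Observed expression table: planted expectations x log-normal noise."""
    cfg = cfg or truth.config
    sigma = cfg.expression_noise_sigma if noise_sigma is None else noise_sigma
    rng = cfg.rng(_STAGE_EXPRESSION)
    expected = truth.expression[["satellite", "treatment", "withdrawal"]]
    noise = rng.lognormal(0.0, sigma, size=expected.shape) if sigma > 0 else 1.0
    return expected * noise


# sample layout of the accessibility panel: (label, origin, expresses factor, n)
_PANEL_GROUPS = (
    ("iPax7_plusDox", "iPax7", True, 4),
    ("iPax7_minusDox_12h", "iPax7", False, 3),
    ("iPax7_minusDox_24h", "iPax7", False, 3),
    ("iPax7_minusDox_3d", "iPax7", False, 4),
    ("satellite", "satellite", True, 3),
    ("MB_ctrl", "C2C12", False, 3),
    ("MB_Pax7", "C2C12", True, 4),
    ("MT", "C2C12", False, 3),
)


def simulate_accessibility_panel(
    truth: SyntheticTruth,
    cfg: SimulationConfig | None = None,
    n_background_sites: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame, PeakSet]:
    """Sample x site accessibility panel contrasting batch and factor effects.

    Most accessible sites (the background set) carry a strong cell-of-origin
    batch effect shared within each origin; the bound sites carry signal only
    in factor-expressing samples. PCA over all sites therefore groups by
    origin, while PCA restricted to the bound sites separates
    factor-expressing from non-expressing samples.

    Returns (table, sample metadata with ``origin`` and ``factor`` columns,
    bound-site :class:`PeakSet` usable as the PCA restriction).
    """
    cfg = cfg or truth.config
    rng = cfg.rng(_STAGE_PANEL)
    chroms = sorted(cfg.chrom_lengths)
    site_idx = IntervalIndex(truth.sites)
    bg_sites: list[GenomicInterval] = []
    while len(bg_sites) < n_background_sites:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, cfg.chrom_lengths[chrom] - 300))
        cand = GenomicInterval(chrom, start, start + 300)
        if site_idx.overlaps_any(cand):
            continue
        bg_sites.append(cand)

    samples, origins, factor = [], [], []
    for label, origin, has_factor, n_rep in _PANEL_GROUPS:
        for r in range(n_rep):
            samples.append(f"{label}_r{r + 1}")
            origins.append(origin)
            factor.append(has_factor)
    origin_names = sorted(set(origins))

    # strong per-origin batch effect on background sites
    origin_effect = {
        o: rng.normal(0.0, 3.5, size=len(bg_sites)) for o in origin_names
    }
    small_origin_effect = {
        o: rng.normal(0.0, 0.3, size=len(truth.sites)) for o in origin_names
    }
    rows = []
    for s, o, f in zip(samples, origins, factor):
        bg = 5.0 + origin_effect[o] + rng.normal(0.0, 0.3, size=len(bg_sites))
        bound = (
            (5.0 if f else 1.0)
            + small_origin_effect[o]
            + rng.normal(0.0, 0.3, size=len(truth.sites))
        )
        rows.append(np.clip(np.concatenate([bg, bound]), 0.0, None))
    all_sites = bg_sites + list(truth.sites)
    columns = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in all_sites]
    table = pd.DataFrame(rows, index=pd.Index(samples, name="sample"),
                         columns=columns)
    meta = pd.DataFrame(
        {"origin": origins, "factor": factor},
        index=pd.Index(samples, name="sample"),
    )
    return table, meta, PeakSet(sorted(truth.sites.intervals), is_sorted=True)


# mm9-like chromosome sizes (Mb scale) for the synthetic reference stand-in
_MOUSE_CHROMS = {
    **{f"chr{i}": 197_000_000 - i * 6_000_000 for i in range(1, 20)},
    "chrX": 166_000_000,
}


def reference_site_standin(n: int = 2455, seed: int = 20170425) -> PeakSet:
    """Synthetic stand-in for the published binding-site BED supplement.

    The real supplementary table (2455 factor binding sites in BED form) is
    distributed with the article and is not bundled here; this deterministic
    synthetic set reproduces its format and region count so that the BED
    reader's behaviour on a file of that shape is testable. Coordinates are
    arbitrary and carry no biology.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(_MOUSE_CHROMS)
    lengths = np.array([_MOUSE_CHROMS[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    for _ in range(n):
        ci = int(rng.choice(len(chroms), p=probs))
        width = int(rng.integers(150, 1200))
        start = int(rng.integers(3_000_000, _MOUSE_CHROMS[chroms[ci]] - width))
        out.append(GenomicInterval(chroms[ci], start, start + width))
    return PeakSet(sorted(out), condition="reference-standin", is_sorted=True)
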