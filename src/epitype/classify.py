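"""Type 1 / Type 2 site classification, accessibility testing and PCA.

A bound site's accessibility at each timepoint of a factor-withdrawal time
course is summarised as the mean normalised signal over the centre +/- 250 bp
window. Sites are clustered (k-means, default k=2) on their per-timepoint
profiles scaled by the induced-condition baseline, and each *cluster* is
labelled:

* **Type 1** — mean persistence ratio (first-withdrawal / baseline signal)
  below the persistence threshold: accessibility collapses as soon as the
  factor is withdrawn.
* **Type 2** — accessibility persists after withdrawal, consistent with
  maintenance by other factors binding nearby.

A site is called "accessible" when its scalar exceeds a background-calibrated
threshold (see :func:`accessibility_threshold`), and accessibility change
between conditions is tested with an uncorrected Pearson chi-square on the
2x2 accessible/inaccessible x condition table.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .intervals import GenomicInterval, IntervalIndex, PeakSet, parse_region, site_id
from .signal import SignalTrack

__all__ = [
    "AccessibilityProfile",
    "SiteClassification",
    "EnhancerSignature",
    "accessibility_scalars",
    "accessibility_threshold",
    "kmeans_sites",
    "classify_types",
    "chi_square_accessibility",
    "contingency_from_calls",
    "enhancer_categories",
    "enhancer_retention",
    "pca_samples",
]

TYPE1 = "Type1"
TYPE2 = "Type2"
UNASSIGNED = "unassigned"

CATEGORIES = ("H3K4me1 only", "H3K27ac only", "both", "neither")

ACCESS_HALFWIDTH = 250  # bp each side of the site centre


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-site scalar accessibility across an ordered set of timepoints."""

    site_id: str
    timepoints: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.values):
            raise ValueError("timepoint / value length mismatch")
        if len(self.timepoints) < 2:
            raise ValueError("need a baseline plus >=1 withdrawal timepoint")
        if any(v < 0 for v in self.values):
            raise ValueError(f"negative accessibility for {self.site_id}")

    @property
    def baseline(self) -> float:
        return self.values[0]

    @property
    def persistence_ratio(self) -> float:
        """First-withdrawal-timepoint signal over baseline signal."""
        if self.baseline == 0:
            return float("nan")
        return self.values[1] / self.baseline


@dataclass(frozen=True)
class SiteClassification:
    site_id: str
    cluster: int  # -1 for unassigned
    type_label: str  # Type1 / Type2 / unassigned
    persistence_ratio: float


@dataclass(frozen=True)
class EnhancerSignature:
    site_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# accessibility scalars and the open/closed call


def accessibility_scalars(
    track: SignalTrack, sites: PeakSet, halfwidth: int = ACCESS_HALFWIDTH
) -> np.ndarray:
    """Mean per-base signal over each site's centre +/- ``halfwidth`` bp."""
    out = np.empty(len(sites))
    for i, iv in enumerate(sites):
        c = iv.center
        out[i] = track.per_base(iv.chrom, c - halfwidth, c + halfwidth).mean()
    return out


def background_scalars(
    track: SignalTrack,
    n: int,
    seed: int,
    halfwidth: int = ACCESS_HALFWIDTH,
    exclude: PeakSet | None = None,
) -> np.ndarray:
    """Scalars at ``n`` random genomic positions (optionally avoiding a set)."""
    rng = np.random.default_rng(seed)
    chroms = track.chroms()
    lengths = np.array([track.covered_length(c) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    idx = exclude if exclude is None else IntervalIndex(exclude)
    out = []
    while len(out) < n:
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(halfwidth, track.covered_length(chrom) - halfwidth))
        if idx is not None and idx.overlaps_any(
            GenomicInterval(chrom, pos - halfwidth, pos + halfwidth)
        ):
            continue
        out.append(track.per_base(chrom, pos - halfwidth, pos + halfwidth).mean())
    return np.array(out)


def accessibility_threshold(
    track: SignalTrack,
    seed: int,
    n_background: int = 1000,
    halfwidth: int = ACCESS_HALFWIDTH,
    quantile: float = 0.75,
    min_fold: float = 10.0,
    exclude: PeakSet | None = None,
) -> float:
    """Background-calibrated signal threshold for calling a site accessible.

    The threshold is ``max(q-quantile of background scalars,
    min_fold x median background)``. The quantile alone guards against
    background noise; the fold-enrichment floor (default 10x, the order of
    enrichment typical of called open-chromatin regions) keeps weak residual
    signal from counting as open when the genome-wide background is very low.
    """
    bg = background_scalars(track, n_background, seed, halfwidth, exclude)
    return float(max(np.quantile(bg, quantile), min_fold * np.median(bg)))


# ---------------------------------------------------------------------------
# clustering and typing


def kmeans_sites(
    matrix: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, float]:
    """Lloyd's k-means with k-means++ seeding; returns (labels, inertia).

    Deterministic for a fixed seed. Degenerate inputs (fewer distinct rows
    than clusters) are handled by scikit-learn without crashing; duplicated
    centroids simply leave a cluster empty-or-degenerate.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if matrix.ndim != 2 or matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {matrix.shape}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(matrix)
    return labels, float(km.inertia_)


def classify_types(
    profiles: Sequence[AccessibilityProfile],
    k: int = 2,
    seed: int = 0,
    persistence_threshold: float = 0.5,
) -> list[SiteClassification]:
    """Cluster baseline-scaled accessibility profiles and label whole clusters.

    Profiles are scaled by their baseline (+induction) value, clustered with
    k-means, and each cluster is labelled Type 1 if its mean persistence
    ratio falls below ``persistence_threshold``, else Type 2. Sites with a
    zero baseline cannot be scaled; they are excluded from clustering and
    returned as ``unassigned`` (cluster -1).
    """
    tps = profiles[0].timepoints
    for p in profiles:
        if p.timepoints != tps:
            raise ValueError(f"profile {p.site_id} has mismatched timepoints")

    usable = [p for p in profiles if p.baseline > 0]
    skipped = [p for p in profiles if p.baseline == 0]
    if len(usable) < k:
        raise ValueError("fewer usable profiles than clusters")

    scaled = np.array([np.asarray(p.values) / p.baseline for p in usable])
    labels, _ = kmeans_sites(scaled, k=k, seed=seed)
    ratios = np.array([p.persistence_ratio for p in usable])

    cluster_label: dict[int, str] = {}
    for c in range(k):
        members = labels == c
        if not members.any():
            continue
        mean_ratio = float(ratios[members].mean())
        cluster_label[c] = TYPE1 if mean_ratio < persistence_threshold else TYPE2

    out = [
        SiteClassification(
            p.site_id, int(c), cluster_label[int(c)], float(r)
        )
        for p, c, r in zip(usable, labels, ratios)
    ]
    out.extend(
        SiteClassification(p.site_id, -1, UNASSIGNED, float("nan")) for p in skipped
    )
    return out


# ---------------------------------------------------------------------------
# chi-square accessibility test


def chi_square_accessibility(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Rows are conditions, columns accessible / not accessible. A zero row or
    column total leaves the statistic undefined and raises ``ValueError``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column total: statistic undefined")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(stat), float(p)


def contingency_from_calls(
    accessible_a: np.ndarray, accessible_b: np.ndarray
) -> np.ndarray:
    """Build the 2x2 (condition x accessible/not) table from boolean calls."""
    a = np.asarray(accessible_a, dtype=bool)
    b = np.asarray(accessible_b, dtype=bool)
    return np.array(
        [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
    )


# ---------------------------------------------------------------------------
# enhancer-mark categories and retention


def enhancer_categories(
    sites: PeakSet, k4me1: PeakSet, k27ac: PeakSet
) -> tuple[list[EnhancerSignature], dict[str, Fraction]]:
    """Assign each site an H3K4me1/H3K27ac overlap category.

    Returns the per-site signatures plus exact category fractions (as
    :class:`~fractions.Fraction`, so they sum to 1 exactly).
    """
    idx1, idx2 = IntervalIndex(k4me1), IntervalIndex(k27ac)
    sigs = []
    counts = dict.fromkeys(CATEGORIES, 0)
    for iv in sites:
        has1, has2 = idx1.overlaps_any(iv), idx2.overlaps_any(iv)
        if has1 and has2:
            cat = "both"
        elif has1:
            cat = "H3K4me1 only"
        elif has2:
            cat = "H3K27ac only"
        else:
            cat = "neither"
        sigs.append(EnhancerSignature(site_id(iv), cat))
        counts[cat] += 1
    n = len(sites)
    fractions = {c: (Fraction(counts[c], n) if n else Fraction(0)) for c in CATEGORIES}
    return sigs, fractions


def enhancer_retention(
    signature_before: Sequence[EnhancerSignature],
    signature_after: Sequence[EnhancerSignature],
    site_types: Mapping[str, str],
) -> dict[str, float | None]:
    """Per type class, the fraction of full enhancers ("both") that stay "both".

    ``site_types`` maps site id to its Type 1 / Type 2 label. Both signature
    lists must cover the same site universe. Classes with no "both" site
    before withdrawal get ``None``.
    """
    before = {s.site_id: s.category for s in signature_before}
    after = {s.site_id: s.category for s in signature_after}
    if set(before) != set(after):
        raise ValueError("before/after signature lists cover different sites")
    out: dict[str, float | None] = {}
    for label in sorted(set(site_types.values())):
        ids = [
            s
            for s, t in site_types.items()
            if t == label and s in before and before[s] == "both"
        ]
        out[label] = (
            sum(1 for s in ids if after[s] == "both") / len(ids) if ids else None
        )
    return out


# ---------------------------------------------------------------------------
# PCA of sample accessibility


def pca_samples(
    table: pd.DataFrame,
    restrict_to: PeakSet | None = None,
    site_intervals: Sequence[GenomicInterval] | None = None,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (rows) on principal components of site accessibility.

    Features (columns = sites) are mean-centred across samples and decomposed
    by SVD; returned coordinates are the projections and the second value the
    explained-variance fractions (non-increasing). Each component's sign is
    fixed so that its largest-magnitude feature loading is positive, making
    outputs reproducible.

    When ``restrict_to`` is given, only feature columns whose site overlaps
    the peak set are used; sites are taken from ``site_intervals`` (parallel
    to the columns) or parsed from ``chrom:start-end`` column names.
    """
    if table.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    X = table
    if restrict_to is not None:
        if site_intervals is None:
            site_intervals = [parse_region(str(c)) for c in table.columns]
        if len(site_intervals) != table.shape[1]:
            raise ValueError("site_intervals must parallel the table columns")
        idx = IntervalIndex(restrict_to)
        keep = [i for i, iv in enumerate(site_intervals) if idx.overlaps_any(iv)]
        if len(keep) < 2:
            raise ValueError("fewer than two features remain after restriction")
        X = table.iloc[:, keep]
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # sign convention: largest-|loading| of each component positive
    for j in range(len(S)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    coords = U * S
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    if n_components is not None:
        coords = coords[:, :n_components]
        explained = explained[:n_components]
    cols = [f"PC{j + 1}" for j in range(coords.shape[1])]
    return pd.DataFrame(coords, index=X.index, columns=cols), explained
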