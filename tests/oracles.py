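"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (per-base marking, all-pairs loops,
closed-form arithmetic) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist

from epitype.intervals import GenomicInterval


def union_runs(intervals, chrom_len: int) -> list[tuple[int, int]]:
    """Per-base union of intervals on one chromosome, re-extracted as runs."""
    covered = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        covered[iv.start : iv.end] = True
    runs = []
    in_run = False
    for pos in range(chrom_len):
        if covered[pos] and not in_run:
            start, in_run = pos, True
        elif not covered[pos] and in_run:
            runs.append((start, pos))
            in_run = False
    if in_run:
        runs.append((start, chrom_len))
    return runs


def pair_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def naive_merge(intervals) -> list[tuple[int, int]]:
    """Fixed-point pairwise merging of spans sharing >=1 base (one chrom).

    Unlike a per-base union, this honours the half-open convention: spans
    that merely abut stay separate.
    """
    spans = [[iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                if a[0] < b[1] and b[0] < a[1]:
                    spans[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    spans.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in spans)


def bruteforce_consensus(treatment, control, min_support: int, chrom_len: int):
    """Two-rule evaluation per candidate, with candidates from per-base union.

    Assumes a single chromosome named 'chr1' (enough for randomized tests).
    Returns a list of (start, end, support) for kept candidates.
    """
    all_treatment = [iv for rep in treatment for iv in rep]
    kept = []
    for start, end in naive_merge(all_treatment):
        cand = GenomicInterval("chr1", start, end)
        support = sum(
            1 for rep in treatment if any(pair_overlaps(cand, iv) for iv in rep)
        )
        if support < min_support:
            continue
        if any(pair_overlaps(cand, iv) for rep in control for iv in rep):
            continue
        kept.append((start, end, support))
    return kept


def bruteforce_matrix(per_base: dict[str, np.ndarray], sites, window, bin_size):
    """Direct per-base averaging of a per-base track around site centres."""
    ncol = 2 * window // bin_size
    out = np.zeros((len(sites), ncol))
    for i, iv in enumerate(sites):
        arr = per_base[iv.chrom]
        c = (iv.start + iv.end) // 2
        for j in range(ncol):
            total = 0.0
            for off in range(bin_size):
                pos = c - window + j * bin_size + off
                if 0 <= pos < len(arr):
                    total += arr[pos]
            out[i, j] = total / bin_size
    return out


def chi2_closed_form(table) -> tuple[float, float]:
    """Pearson statistic from first principles: sum (O-E)^2 / E, 1 df."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / n
            stat += (t[i, j] - e) ** 2 / e
    return stat, float(chi2_dist.sf(stat, df=1))


def bruteforce_nearest_tss(site, tss_entries):
    """All-pairs nearest TSS with the (|d|, position, gene) tie-break."""
    c = (site.start + site.end) // 2
    best = None
    for e in tss_entries:
        if e.chrom != site.chrom:
            continue
        key = (abs(e.position - c), e.position, e.gene)
        if best is None or key < best:
            best = key
    return best  # (|d|, position, gene) or None


def bruteforce_min_center_distance(a, b_set, max_distance):
    ca = (a.start + a.end) // 2
    dists = [
        abs(((b.start + b.end) // 2) - ca)
        for b in b_set
        if b.chrom == a.chrom
    ]
    dists = [d for d in dists if d <= max_distance]
    return min(dists) if dists else None
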