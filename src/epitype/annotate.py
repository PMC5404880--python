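"""Positional annotation of binding sites and the expression-signature filter.

Distances are measured from the site centre: to the nearest TSS for
promoter / distal classification, and centre-to-centre between two factors'
peak sets for co-binding proximity. The expression filter reproduces the
"transcribed in satellite cells and >=2-fold higher with the inducer"
signature logic on any three-condition expression table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, TSSAnnotation, site_id

__all__ = [
    "TSSDistanceRecord",
    "ProximityRecord",
    "nearest_tss",
    "center_distance_stats",
    "expression_signature",
]

PROMOTER_BP = 1000
DISTAL_BP = 5000

PROMOTER = "promoter"
INTERMEDIATE = "intermediate"
DISTAL = "distal"


@dataclass(frozen=True)
class TSSDistanceRecord:
    site_id: str
    gene: str
    distance: int  # signed, positive when the TSS lies downstream of the centre
    category: str


@dataclass(frozen=True)
class ProximityRecord:
    site_id: str
    distance: int | None  # None when no partner centre within max_distance


def _categorize(abs_distance: int, promoter_bp: int, distal_bp: int) -> str:
    if abs_distance <= promoter_bp:
        return PROMOTER
    if abs_distance <= distal_bp:
        return INTERMEDIATE
    return DISTAL


def nearest_tss(
    sites: PeakSet,
    tss: TSSAnnotation,
    promoter_bp: int = PROMOTER_BP,
    distal_bp: int = DISTAL_BP,
) -> tuple[list[TSSDistanceRecord], dict]:
    """Nearest TSS per site (same chromosome) plus category summary.

    The TSS minimising ``|position - centre|`` wins; ties are broken by the
    smaller TSS coordinate, then lexicographic gene name. The summary reports
    counts per category (promoter <= ``promoter_bp``, intermediate, distal >
    ``distal_bp``) and the median/mean absolute distance.
    """
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    by_chrom = tss.by_chrom()
    pos_arrays = {
        c: np.array([e.position for e in entries])
        for c, entries in by_chrom.items()
    }
    records: list[TSSDistanceRecord] = []
    missing: list[str] = []
    for iv in sites:
        entries = by_chrom.get(iv.chrom)
        if not entries:
            missing.append(site_id(iv))
            continue
        positions = pos_arrays[iv.chrom]
        c = iv.center
        j = int(np.searchsorted(positions, c))
        best: tuple[int, int, str] | None = None  # (|d|, position, gene)
        # candidate neighbours: the nearest position at or after c and before c;
        # duplicates at equal positions are adjacent in the (position, gene) sort.
        cand_idx: set[int] = set()
        if j < len(positions):
            cand_idx.add(j)
        if j > 0:
            cand_idx.add(j - 1)
        best_abs = min(abs(int(positions[k]) - c) for k in cand_idx)
        # gather all entries at exactly best_abs on either side (tie handling)
        for target in (c - best_abs, c + best_abs):
            lo = int(np.searchsorted(positions, target, side="left"))
            hi = int(np.searchsorted(positions, target, side="right"))
            for k in range(lo, hi):
                e = entries[k]
                key = (best_abs, e.position, e.gene)
                if best is None or key < best:
                    best = key
        assert best is not None
        abs_d, position, gene = best
        records.append(
            TSSDistanceRecord(
                site_id(iv),
                gene,
                position - c,
                _categorize(abs_d, promoter_bp, distal_bp),
            )
        )
    if missing:
        raise ValueError(
            f"no TSS on the chromosome of sites: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    abs_d = np.array([abs(r.distance) for r in records])
    summary = {
        "n_sites": len(records),
        "counts": {
            cat: sum(1 for r in records if r.category == cat)
            for cat in (PROMOTER, INTERMEDIATE, DISTAL)
        },
        "median_abs_distance": float(np.median(abs_d)),
        "mean_abs_distance": float(abs_d.mean()),
    }
    return records, summary


def center_distance_stats(
    set_a: PeakSet,
    set_b: PeakSet,
    max_distance: int = 2000,
) -> tuple[list[ProximityRecord], float | None, int]:
    """Nearest centre-to-centre distance from each A peak to the B set.

    Only partners on the same chromosome within ``max_distance`` count as
    matched. Returns (per-A records, median over matched distances or None,
    number of unmatched A peaks).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("both peak sets must be non-empty")
    b_centers: dict[str, np.ndarray] = {}
    for iv in set_b:
        b_centers.setdefault(iv.chrom, []).append(iv.center)  # type: ignore[arg-type]
    b_centers = {c: np.sort(np.array(v)) for c, v in b_centers.items()}

    records: list[ProximityRecord] = []
    matched: list[int] = []
    for iv in set_a:
        centers = b_centers.get(iv.chrom)
        dist: int | None = None
        if centers is not None and len(centers):
            c = iv.center
            j = int(np.searchsorted(centers, c))
            best = min(
                abs(int(centers[k]) - c)
                for k in (j - 1, j)
                if 0 <= k < len(centers)
            )
            if best <= max_distance:
                dist = best
        records.append(ProximityRecord(site_id(iv), dist))
        if dist is not None:
            matched.append(dist)
    median = float(np.median(matched)) if matched else None
    return records, median, len(records) - len(matched)


def expression_signature(
    expr: pd.DataFrame,
    fold_threshold: float = 2.0,
    sc_expressed_min: float = 1.0,
    pseudocount: float = 1.0,
    satellite_col: str = "satellite",
    treatment_col: str = "treatment",
    withdrawal_col: str = "withdrawal",
) -> tuple[list[str], list[str]]:
    """Split genes into (down-regulated, up-regulated) upon factor withdrawal.

    A gene qualifies only if expressed in satellite cells
    (``satellite > sc_expressed_min``). Among those, genes whose
    pseudocounted treatment/withdrawal ratio is >= ``fold_threshold`` are
    down-regulated upon withdrawal; the reciprocal ratio picks the
    up-regulated list. For ``fold_threshold >= 1`` the lists are disjoint.
    The index of ``expr`` holds gene names.
    """
    for col in (satellite_col, treatment_col, withdrawal_col):
        if col not in expr.columns:
            raise ValueError(f"expression table lacks required column {col!r}")
    sat = expr[satellite_col].to_numpy(dtype=float)
    tre = expr[treatment_col].to_numpy(dtype=float) + pseudocount
    wit = expr[withdrawal_col].to_numpy(dtype=float) + pseudocount
    expressed = sat > sc_expressed_min
    down = expr.index[expressed & (tre / wit >= fold_threshold)].tolist()
    up = expr.index[expressed & (wit / tre >= fold_threshold)].tolist()
    return down, up
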