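"""Condition-specific consensus binding sites from replicate peak calls.

The final site list for an inducibly expressed factor is derived from
per-replicate peak calls in the induced (treatment) and uninduced (control)
conditions:

1. candidate regions are the merged union of all treatment-replicate peaks;
2. a candidate is kept if peaks from at least ``min_treatment_support``
   distinct treatment replicates overlap it (default 2);
3. a candidate is removed whole if any control-replicate peak overlaps it.

Candidates keep their merged coordinates; the number of supporting treatment
replicates is recorded in the interval score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, IntervalIndex, PeakSet, merge_overlapping

__all__ = [
    "ConsensusConfig",
    "consensus_sites",
    "overlap_fraction",
    "novel_sites",
]


class ConsensusConfigError(ValueError):
    """Configuration inconsistent with the supplied replicates."""


@dataclass(frozen=True)
class ConsensusConfig:
    """Parameters of the consensus/subtraction rule."""

    min_treatment_support: int = 2
    subtract_any_control: bool = True

    def __post_init__(self) -> None:
        if self.min_treatment_support < 1:
            raise ConsensusConfigError("min_treatment_support must be >= 1")


def consensus_sites(
    treatment_reps: list[PeakSet],
    control_reps: list[PeakSet],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> PeakSet:
    """Apply the two-rule consensus: replicate support then control subtraction.

    Returns a sorted, disjoint :class:`PeakSet`; each interval's ``score`` is
    the number of distinct treatment replicates supporting it.
    """
    if cfg.min_treatment_support > len(treatment_reps):
        raise ConsensusConfigError(
            f"min_treatment_support={cfg.min_treatment_support} exceeds the "
            f"{len(treatment_reps)} treatment replicates supplied"
        )
    all_treatment = PeakSet([iv for rep in treatment_reps for iv in rep])
    candidates = merge_overlapping(all_treatment)

    rep_indexes = [IntervalIndex(rep) for rep in treatment_reps]
    control_indexes = (
        [IntervalIndex(rep) for rep in control_reps] if cfg.subtract_any_control else []
    )

    kept: list[GenomicInterval] = []
    for cand in candidates:
        support = sum(1 for idx in rep_indexes if idx.overlaps_any(cand))
        if support < cfg.min_treatment_support:
            continue
        if any(idx.overlaps_any(cand) for idx in control_indexes):
            continue
        kept.append(
            GenomicInterval(cand.chrom, cand.start, cand.end, score=float(support))
        )
    return PeakSet(kept, condition="consensus", is_sorted=True)


def overlap_fraction(query: PeakSet, reference: PeakSet) -> float:
    """Fraction of query intervals overlapping at least one reference interval."""
    if len(query) == 0:
        raise ValueError("overlap_fraction is undefined for an empty query set")
    idx = IntervalIndex(reference)
    hits = sum(1 for iv in query if idx.overlaps_any(iv))
    return hits / len(query)


def novel_sites(query: PeakSet, reference: PeakSet) -> PeakSet:
    """Query intervals overlapping no reference interval."""
    idx = IntervalIndex(reference)
    return PeakSet(
        [iv for iv in query if not idx.overlaps_any(iv)],
        condition=query.condition,
        replicate_id=query.replicate_id,
    )
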