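"""Second-hit classification at germline variant loci.

Under the two-hit model, a germline variant in a tumor suppressor gene is
expected to be accompanied in the tumor by a somatic event in the same gene:
a copy-number alteration removing or outcompeting the normal allele, or a
second small mutation.  This module turns allele-specific copy-number
segments (consumed from an upstream caller such as FACETS), confirmed
allele-balance shifts, and somatic small-variant calls into a per-variant
verdict.

Event decision table over the locus copy state (total t, minor m):

    t = 0                        -> HZ_DEL        (both alleles lost)
    t >= 6                       -> AMPLIFICATION (clinically meaningful gain)
    t = 2, m = 0, DAB confirmed  -> CN_LOH        (copy-neutral LOH)
    t = 2, m = 0, unconfirmed    -> NONE, flagged cnloh-candidate-unconfirmed
    m = 0, 1 <= t < 6, t != 2    -> LOH           (one parental allele lost)
    otherwise                    -> NONE

CN-LOH is the only class that *requires* the allele-balance confirmation: a
2+0 segment call without a confirmed shift is indistinguishable from a
segmentation artifact, so it is reported only as an unconfirmed candidate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .allele_balance import DabResult

__all__ = [
    "CnSegment",
    "Event",
    "CallDirection",
    "SecondHitCall",
    "locate_segment",
    "classify_cna",
    "call_direction",
    "find_somatic_second_mutation",
    "summarize_cohort",
    "CohortSummary",
    "AMPLIFICATION_MIN_CN",
]

AMPLIFICATION_MIN_CN = 6


class Event(str, Enum):
    LOH = "LOH"
    CN_LOH = "CN_LOH"
    HZ_DEL = "HZ_DEL"
    AMPLIFICATION = "AMPLIFICATION"
    SOMATIC_MUTATION = "SOMATIC_MUTATION"
    NONE = "NONE"


class CallDirection(str, Enum):
    ENRICHED = "ENRICHED"
    DEPLETED = "DEPLETED"
    BALANCED = "BALANCED"
    NA = "NA"


@dataclass(frozen=True)
class CnSegment:
    """Allele-specific copy-number segment on a half-open interval [start, end)."""

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele for total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SecondHitCall:
    variant_id: str
    sample: str
    gene: str
    event: Event
    direction: CallDirection
    dab_confirmed: bool
    evidence: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def is_second_hit(self) -> bool:
        return self.event not in (Event.NONE,)


def locate_segment(chrom: str, pos: int, segments: Iterable[CnSegment]) -> Optional[CnSegment]:
    """The unique segment covering a 1-based position, or None when uncovered.

    Raises on overlapping coverage — overlapping allele-specific segments in
    one sample indicate corrupt upstream output.
    """
    hits = [s for s in segments if s.chrom == chrom and s.contains(pos)]
    if len(hits) > 1:
        raise ValueError(
            f"overlapping segments cover {chrom}:{pos}: "
            + ", ".join(f"[{s.start},{s.end})" for s in hits)
        )
    return hits[0] if hits else None


def classify_cna(segment: CnSegment, dab: Optional[DabResult]) -> tuple[Event, list[str]]:
    """Copy-number event class at a variant locus, plus diagnostic flags.

    A discordance flag is raised when the segment's allele state and the
    allele-balance analysis disagree (imbalanced segment without a confirmed
    shift, or a balanced segment with one) — the cross-check used to vet the
    upstream allele calls.
    """
    flags: list[str] = []
    confirmed = dab is not None and dab.confirmed
    t, m = segment.total_cn, segment.minor_cn

    imbalanced = m != t - m
    if imbalanced and not confirmed and t > 0:
        flags.append("dab-discordant-segment-imbalanced")
    if not imbalanced and confirmed:
        flags.append("dab-discordant-segment-balanced")

    if t == 0:
        return Event.HZ_DEL, flags
    if t >= AMPLIFICATION_MIN_CN:
        return Event.AMPLIFICATION, flags
    if t == 2 and m == 0:
        if confirmed:
            return Event.CN_LOH, flags
        flags.append("cnloh-candidate-unconfirmed")
        return Event.NONE, flags
    if m == 0 and 1 <= t < AMPLIFICATION_MIN_CN:
        return Event.LOH, flags
    return Event.NONE, flags


def call_direction(
    event: Event, dab: Optional[DabResult], segment: Optional[CnSegment] = None
) -> CallDirection:
    """Direction of selection on the germline allele implied by the event.

    Homozygous deletion removes both alleles and is always a depletion.  For
    the other classes the sign of the confirmed allele-balance shift carries
    the direction; an amplification without a confirmed shift is a balanced
    gain of both alleles.
    """
    if event is Event.HZ_DEL:
        return CallDirection.DEPLETED
    confirmed = dab is not None and dab.confirmed
    if confirmed and dab.delta_ab > 0:
        return CallDirection.ENRICHED
    if confirmed and dab.delta_ab < 0:
        return CallDirection.DEPLETED
    if event is Event.AMPLIFICATION:
        return CallDirection.BALANCED
    return CallDirection.NA


def find_somatic_second_mutation(
    gene: str,
    somatic_calls: Iterable,
    germline_direction: CallDirection,
) -> list[dict]:
    """Somatic small variants in the same gene, as candidate second mutations.

    Returns one record per somatic call in ``gene`` with its allele fraction;
    no driver/passenger verdict is made — the allele fraction is reported for
    human review.  When the germline variant is under negative selection
    (direction DEPLETED) a somatic hit in the same gene cannot be a
    cooperating second hit, so the list is empty.
    """
    if germline_direction is CallDirection.DEPLETED:
        return []
    out = []
    for mut in somatic_calls:
        if getattr(mut, "gene", None) == gene:
            out.append(
                {
                    "gene": gene,
                    "chrom": mut.chrom,
                    "pos": mut.pos,
                    "ref": mut.ref,
                    "alt": mut.alt,
                    "allele_fraction": float(mut.allele_fraction),
                }
            )
    return out


@dataclass
class CohortSummary:
    n_variants: int
    n_second_hit: int
    n_cna: int
    n_somatic_mutation: int
    n_enriched: int
    n_depleted: int
    n_balanced: int
    events: dict
    aneuploidy_p_value: Optional[float]
    aneuploidy_note: str = ""


def summarize_cohort(
    calls: Sequence[SecondHitCall],
    aneuploidy_by_sample: Optional[dict[str, float]] = None,
) -> CohortSummary:
    """Cohort-level tallies and the aneuploidy comparison between groups.

    Counts partition exactly: second hits split into CNA events and somatic
    second mutations; CNA events split into enriched/depleted/balanced (plus
    NA for directionless calls).  When per-sample aneuploidy fractions are
    supplied, patients with at least one second hit are compared to those
    without by a two-sided Mann-Whitney rank-sum test.
    """
    cna_events = (Event.LOH, Event.CN_LOH, Event.HZ_DEL, Event.AMPLIFICATION)
    n_cna = sum(1 for c in calls if c.event in cna_events)
    n_mut = sum(1 for c in calls if c.event is Event.SOMATIC_MUTATION)
    n_enr = sum(1 for c in calls if c.event in cna_events and c.direction is CallDirection.ENRICHED)
    n_dep = sum(1 for c in calls if c.event in cna_events and c.direction is CallDirection.DEPLETED)
    n_bal = sum(1 for c in calls if c.event in cna_events and c.direction is CallDirection.BALANCED)
    events = {e.value: sum(1 for c in calls if c.event is e) for e in Event}

    p_value = None
    note = ""
    if aneuploidy_by_sample:
        with_hit = {c.sample for c in calls if c.is_second_hit}
        a = [v for s, v in aneuploidy_by_sample.items() if s in with_hit]
        b = [v for s, v in aneuploidy_by_sample.items() if s not in with_hit]
        if a and b:
            p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            note = "aneuploidy comparison skipped: one group is empty"
    elif not calls:
        note = "no calls: all counts zero, test skipped"

    return CohortSummary(
        n_variants=len(calls),
        n_second_hit=n_cna + n_mut,
        n_cna=n_cna,
        n_somatic_mutation=n_mut,
        n_enriched=n_enr,
        n_depleted=n_dep,
        n_balanced=n_bal,
        events=events,
        aneuploidy_p_value=p_value,
        aneuploidy_note=note,
    )


def calls_table(calls: Sequence[SecondHitCall]) -> pd.DataFrame:
    """Waterfall-ready long-format table: one row per (patient, variant)."""
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "variant_id": [c.variant_id for c in calls],
            "gene": [c.gene for c in calls],
            "event": [c.event.value for c in calls],
            "direction": [c.direction.value for c in calls],
            "dab_confirmed": [c.dab_confirmed for c in calls],
            "flags": [";".join(c.flags) for c in calls],
            "evidence": [c.evidence for c in calls],
        },
        columns=[
            "sample", "variant_id", "gene", "event", "direction",
            "dab_confirmed", "flags", "evidence",
        ],
    )
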