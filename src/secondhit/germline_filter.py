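"""Retention rules for rare germline candidate variants.

A variant survives when it lies in the configured candidate-gene list and
passes three independent rule sets:

* sequencing quality  — mapping quality Phred > 30, at most two haplotypes at
  the position, support outside the 3' read ends, no strand bias;
* population rarity   — allele frequency below 0.015 in a reference database
  (a variant unseen in the database is treated as rare);
* in-silico pathogenicity — called damaging by at least two of eight missense
  predictors, or called splice-altering by at least one of two ensemble
  splice methods.

Variants in well-established breast-cancer predisposition genes are
additionally flagged for external (manual, ACMG-style) curation; a caller may
mark such a variant as curated-retained, which overrides the pathogenicity
rule but never the quality rule.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "QualityFlags",
    "GermlineVariant",
    "GeneTier",
    "ESTABLISHED_BC_GENES",
    "gene_tier",
    "passes_quality",
    "passes_population_frequency",
    "passes_pathogenicity",
    "filter_cohort",
    "FilterSummary",
]

#: Well-established breast-cancer predisposition genes (fixed tier list).
ESTABLISHED_BC_GENES = frozenset(
    {"BRCA1", "BRCA2", "TP53", "PALB2", "ATM", "CHEK2", "CDH1", "PTEN", "STK11"}
)

#: Number of missense predictors whose damaging calls are counted.
N_PREDICTORS = 8
#: Number of ensemble splice-effect methods.
N_SPLICE_METHODS = 2

DEFAULT_MAX_POP_AF = 0.015
DEFAULT_MIN_DAMAGING = 2
DEFAULT_MIN_MAPQ_PHRED = 30.0


class GeneTier(str, Enum):
    ESTABLISHED_BC = "ESTABLISHED_BC"
    CANDIDATE = "CANDIDATE"


@dataclass(frozen=True)
class QualityFlags:
    """Upstream-computed sequencing-quality descriptors for one call."""

    mapping_phred: float
    n_haplotypes: int = 1
    supported_outside_3prime: bool = True
    strand_bias: bool = False

    def __post_init__(self) -> None:
        if self.mapping_phred < 0:
            raise ValueError("mapping_phred must be >= 0")
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")


@dataclass
class GermlineVariant:
    """One candidate germline variant with paired allelic depths.

    ``ad_normal``/``ad_tumor`` are (ref reads, alt reads); ``ad_tumor`` may be
    None when no tumor data cover the locus.  ``pop_af`` is None for variants
    unseen in the population database.  ``curated_retain`` carries the manual
    curation verdict for established-gene variants.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str = "missense_inframe"  # missense_inframe | truncating | splice_region
    ad_normal: tuple[int, int] = (0, 0)
    ad_tumor: Optional[tuple[int, int]] = None
    pop_af: Optional[float] = None
    n_damaging: int = 0
    n_splice: int = 0
    quality: QualityFlags = field(default_factory=lambda: QualityFlags(60.0))
    curated_retain: bool = False

    def __post_init__(self) -> None:
        if min(self.ad_normal) < 0:
            raise ValueError("read counts must be >= 0")
        if self.ad_tumor is not None and min(self.ad_tumor) < 0:
            raise ValueError("read counts must be >= 0")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af outside [0,1]: {self.pop_af}")
        if not (0 <= self.n_damaging <= N_PREDICTORS):
            raise ValueError(f"n_damaging must be in [0, {N_PREDICTORS}]")
        if not (0 <= self.n_splice <= N_SPLICE_METHODS):
            raise ValueError(f"n_splice must be in [0, {N_SPLICE_METHODS}]")

    @property
    def variant_id(self) -> str:
        return f"{self.sample}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def gene_tier(gene: str, established: frozenset[str] = ESTABLISHED_BC_GENES) -> GeneTier:
    """Tier of a gene symbol: established breast-cancer gene or candidate."""
    return GeneTier.ESTABLISHED_BC if gene in established else GeneTier.CANDIDATE


def passes_quality(flags: QualityFlags, min_mapq_phred: float = DEFAULT_MIN_MAPQ_PHRED) -> bool:
    """True iff all four sequencing-quality criteria hold (mapq strictly above threshold)."""
    return (
        flags.mapping_phred > min_mapq_phred
        and flags.n_haplotypes <= 2
        and flags.supported_outside_3prime
        and not flags.strand_bias
    )


def passes_population_frequency(
    pop_af: Optional[float], max_af: float = DEFAULT_MAX_POP_AF
) -> bool:
    """True iff the population allele frequency is strictly below ``max_af``.

    A variant absent from the database (``pop_af is None``) passes: it is by
    construction rarer than any reportable frequency.
    """
    if pop_af is None:
        return True
    if not (0.0 <= pop_af <= 1.0):
        raise ValueError(f"pop_af outside [0,1]: {pop_af}")
    return pop_af < max_af


def passes_pathogenicity(
    n_damaging: int, n_splice: int, min_damaging: int = DEFAULT_MIN_DAMAGING
) -> bool:
    """True iff >= ``min_damaging`` predictors call damaging, or any splice method fires."""
    return n_damaging >= min_damaging or n_splice >= 1


@dataclass
class FilterSummary:
    """Retention table plus per-patient counts for a filtered cohort."""

    table: pd.DataFrame
    per_patient: pd.Series
    n_retained: int
    mean_per_patient: float
    sd_per_patient: float


def filter_cohort(
    variants: Iterable[GermlineVariant],
    gene_list: Sequence[str],
    *,
    max_af: float = DEFAULT_MAX_POP_AF,
    min_damaging: int = DEFAULT_MIN_DAMAGING,
    min_mapq_phred: float = DEFAULT_MIN_MAPQ_PHRED,
    established: frozenset[str] = ESTABLISHED_BC_GENES,
) -> FilterSummary:
    """Apply the retention rules to a cohort of candidate variant calls.

    Returns a table with one row per input variant carrying the rule-by-rule
    pass booleans, the gene tier, and the final ``retained`` verdict, together
    with per-patient retained counts and their cohort mean/SD.  Established-
    gene variants flagged ``curated_retain`` bypass the pathogenicity rule
    (the manual ACMG step) but not quality or gene-list membership.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene list is empty")

    rows = []
    for v in variants:
        tier = gene_tier(v.gene, established)
        in_list = v.gene in genes
        q = passes_quality(v.quality, min_mapq_phred)
        f = passes_population_frequency(v.pop_af, max_af)
        p = passes_pathogenicity(v.n_damaging, v.n_splice, min_damaging)
        curated = tier is GeneTier.ESTABLISHED_BC and v.curated_retain
        retained = in_list and q and f and (p or curated)
        rows.append(
            {
                "variant_id": v.variant_id,
                "sample": v.sample,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "tier": tier.value,
                "variant_class": v.variant_class,
                "in_gene_list": in_list,
                "pass_quality": q,
                "pass_frequency": f,
                "pass_pathogenicity": p,
                "curated_retain": curated,
                "needs_curation": tier is GeneTier.ESTABLISHED_BC,
                "retained": retained,
            }
        )

    cols = [
        "variant_id", "sample", "chrom", "pos", "ref", "alt", "gene", "tier",
        "variant_class", "in_gene_list", "pass_quality", "pass_frequency",
        "pass_pathogenicity", "curated_retain", "needs_curation", "retained",
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        per_patient = table.groupby("sample")["retained"].sum().astype(int)
    else:
        per_patient = pd.Series(dtype=int, name="retained")
    n_ret = int(table["retained"].sum()) if len(table) else 0
    mean = float(per_patient.mean()) if len(per_patient) else 0.0
    sd = float(per_patient.std(ddof=1)) if len(per_patient) > 1 else 0.0
    return FilterSummary(table, per_patient, n_ret, mean, sd)
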