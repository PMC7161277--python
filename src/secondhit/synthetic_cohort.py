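"""Synthetic matched germline/tumor cohorts with known ground truth.

The generator emulates the observable consequences of tumor purity and locus
copy state on exome sequencing data, so that every downstream stage —
germline filtering, allele-balance testing, second-hit classification, and
the global somatic-pattern readouts — can be exercised against a planted
truth without access to patient data.

The depth model is deliberately simple: per-site sequencing depth is Poisson
around the configured mean (scaled by the local DNA content in the tumor),
and allele counts are binomial.  At a germline-heterozygous site in a tumor
of purity rho, where the locus has total copy number t of which v copies
carry the variant allele, the expected variant-allele read fraction is

    f = (rho * v + (1 - rho) * 1) / (rho * t + (1 - rho) * 2)

— the admixture of tumor cells (v of t copies) with normal cells (1 of 2).
Homozygous deletions (t = 0) leave only the normal-cell contribution.

Defaults mirror the study conditions the pipeline targets: 60x normal and
120x tumor mean coverage, tumor purity drawn uniformly on 0.3-0.9, about
five candidate variants per patient, a 17% second-hit planting rate that is
CNA-dominated with a roughly even enrichment/depletion split, and a 60 Mb
exome capture.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .allele_balance import HetSnv
from .germline_filter import GermlineVariant, QualityFlags
from .second_hit import CnSegment, Event, CallDirection
from .somatic_patterns import CONTEXT_CLASSES, SomaticMutation
from . import io as shio

__all__ = [
    "DEFAULT_GENOME",
    "CohortConfig",
    "PlantedVariant",
    "GroundTruth",
    "PatientData",
    "expected_alt_fraction",
    "make_signature_matrix",
    "make_gene_table",
    "plan_patient",
    "simulate_patient",
    "simulate_cohort",
    "simulate_somatic_catalog",
    "write_fixtures",
]

#: (name, length bp, centromere bp) — a compact four-chromosome genome.
DEFAULT_GENOME: tuple[tuple[str, int, int], ...] = (
    ("chr1", 100_000_000, 48_000_000),
    ("chr2", 90_000_000, 40_000_000),
    ("chr3", 80_000_000, 30_000_000),
    ("chr4", 60_000_000, 25_000_000),
)

#: Planted second-hit class mix, CNA-dominated with a small somatic-mutation share.
DEFAULT_EVENT_MIX: dict[str, float] = {
    "LOH": 0.30,
    "CN_LOH": 0.30,
    "HZ_DEL": 0.15,
    "AMPLIFICATION": 0.15,
    "SOMATIC_MUTATION": 0.10,
}


@dataclass
class CohortConfig:
    n_patients: int = 10
    depth_normal: float = 60.0
    depth_tumor: float = 120.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    snv_backbone_density: float = 10.0  # het SNVs per Mb
    genome: tuple[tuple[str, int, int], ...] = DEFAULT_GENOME
    capture_size_mb: float = 60.0
    seed: int = 0
    error_rate: float = 0.0  # symmetric per-read error
    variants_per_patient: int = 5
    decoys_per_patient: int = 3  # candidate calls planted to fail a filter rule
    second_hit_rate: float = 0.17
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    event_segment_mb: float = 20.0
    background_alteration_rate: float = 0.2  # per chromosome arm
    tmb_range: tuple[float, float] = (0.5, 3.0)  # somatic variants per Mb
    indel_fraction: float = 0.1
    n_signatures: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must lie within [0,1]")
        if self.depth_normal <= 0 or self.depth_tumor <= 0:
            raise ValueError("depths must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        for name, length, cen in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if not (0 < cen < length):
                raise ValueError(f"centromere of {name} outside (0, length)")

    @property
    def genome_size(self) -> int:
        return sum(length for _, length, _ in self.genome)

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, length) for name, length, _ in self.genome]

    def chrom_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, l, c) for n, l, c in self.genome],
            columns=["chrom", "length", "centromere"],
        )


@dataclass
class PlantedVariant:
    """Ground truth for one planted candidate germline variant."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    event: str  # truth label: NONE / LOH / CN_LOH / HZ_DEL / AMPLIFICATION / SOMATIC_MUTATION
    direction: str  # ENRICHED / DEPLETED / BALANCED / NA
    total_cn: int
    minor_cn: int
    variant_copies: int
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError("minor_cn exceeds major allele")
        if not (0 <= self.variant_copies <= self.total_cn):
            raise ValueError("variant_copies outside [0, total_cn]")


@dataclass
class GroundTruth:
    """Latent state of one simulated patient."""

    sample: str
    purity: float
    segments: list[CnSegment]
    variants: list[PlantedVariant]
    mixture: np.ndarray  # signature weights, sum 1
    n_somatic: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity outside [0,1]")
        if len(self.mixture) and abs(float(np.sum(self.mixture)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class PatientData:
    """Observable outputs of the simulator for one patient."""

    sample: str
    germline_variants: list[GermlineVariant]
    het_backbone: list[HetSnv]
    segments: list[CnSegment]
    somatic_mutations: list[SomaticMutation]


def expected_alt_fraction(purity: float, total_cn: int, variant_copies: int) -> float:
    """Expected tumor alt-allele fraction at a germline-heterozygous site.

    Mixes ``variant_copies`` of ``total_cn`` tumor copies with the one-of-two
    contribution of admixed normal cells.  Raises for the degenerate case of
    a pure tumor with no DNA at the locus (purity 1, total copy 0).
    """
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity outside [0,1]")
    if total_cn < 0 or not (0 <= variant_copies <= total_cn):
        raise ValueError("need 0 <= variant_copies <= total_cn")
    denom = purity * total_cn + (1.0 - purity) * 2.0
    if denom == 0:
        raise ValueError("degenerate input: purity 1 with total copy number 0 (no DNA)")
    return (purity * variant_copies + (1.0 - purity) * 1.0) / denom


def make_signature_matrix(
    k: int = 5, seed: int = 0, disjoint: bool = False
) -> pd.DataFrame:
    """A synthetic 96 x k signature matrix with well-separated columns.

    Each signature concentrates 90% of its mass on its own block of contexts
    (all of it when ``disjoint``), giving the near-orthogonal supports that
    make mixture recovery identifiable.  Columns sum to 1.
    """
    rng = np.random.default_rng(seed)
    blocks = np.array_split(np.arange(96), k)
    M = np.zeros((96, k))
    for j, block in enumerate(blocks):
        col = np.zeros(96)
        col[block] = rng.dirichlet(np.ones(len(block)) * 2.0)
        if not disjoint:
            noise = rng.dirichlet(np.ones(96))
            col = 0.9 * col + 0.1 * noise
        M[:, j] = col / col.sum()
    return pd.DataFrame(M, index=list(CONTEXT_CLASSES), columns=[f"SYN{j+1}" for j in range(k)])


def make_gene_table(config: CohortConfig, spacing_mb: float = 2.0, size_kb: float = 200.0) -> pd.DataFrame:
    """Gene intervals tiling the synthetic genome (columns gene/chrom/start/end)."""
    rows = []
    for ci, (chrom, length, _cen) in enumerate(config.genome, start=1):
        step = int(spacing_mb * 1e6)
        size = int(size_kb * 1e3)
        n = (length - size) // step
        for gi in range(n):
            start = gi * step + step // 2
            rows.append((f"G{ci}_{gi + 1:03d}", chrom, start, start + size))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _context_ref_alt(context: str) -> tuple[str, str]:
    # "A[C>T]G" -> ("C", "T")
    return context[2], context[4]


def _sample_event_state(event: str, enriched: bool, rng: np.random.Generator) -> tuple[int, int, int]:
    """(total_cn, minor_cn, variant_copies) realizing a planted event class."""
    if event == "LOH":
        t = int(rng.choice([1, 3]))
        return t, 0, t if enriched else 0
    if event == "CN_LOH":
        return 2, 0, 2 if enriched else 0
    if event == "HZ_DEL":
        return 0, 0, 0
    if event == "AMPLIFICATION":
        t = int(rng.choice([6, 7, 8]))
        balanced = rng.random() < 0.2
        if balanced and t % 2 == 0:
            return t, t // 2, t // 2
        return t, 1, t - 1 if enriched else 1
    # NONE and SOMATIC_MUTATION: balanced diploid locus
    return 2, 1, 1


def plan_patient(config: CohortConfig, sample: str, rng: np.random.Generator) -> GroundTruth:
    """Draw the latent state of one patient: purity, segments, planted variants."""
    purity = float(rng.uniform(*config.purity_range))
    genes = make_gene_table(config)
    chrom_len = {name: length for name, length, _ in config.genome}

    events = list(config.event_mix.keys())
    probs = np.array([config.event_mix[e] for e in events], dtype=float)
    probs = probs / probs.sum()

    planted: list[PlantedVariant] = []
    placed: dict[str, list[tuple[int, int, int, int]]] = {c: [] for c in chrom_len}
    used_genes: set[str] = set()
    half = int(config.event_segment_mb * 1e6 / 2)

    def try_place(gene_row, t, m, pad: Optional[int] = None) -> Optional[tuple[int, int]]:
        chrom = gene_row.chrom
        mid = (gene_row.start + gene_row.end) // 2
        w = half if pad is None else pad
        start = max(0, mid - w)
        end = min(chrom_len[chrom], mid + w)
        for s0, e0, _, _ in placed[chrom]:
            if start < e0 and s0 < end:
                return None
        placed[chrom].append((start, end, t, m))
        return start, end

    n_real = config.variants_per_patient
    for _ in range(n_real):
        has_hit = rng.random() < config.second_hit_rate
        event = str(rng.choice(events, p=probs)) if has_hit else "NONE"
        enriched = bool(rng.random() < 0.5)
        t, m, v = _sample_event_state(event, enriched, rng)
        gene_row = None
        for _attempt in range(200):
            cand = genes.iloc[int(rng.integers(len(genes)))]
            if cand.gene in used_genes:
                continue
            if event in ("NONE", "SOMATIC_MUTATION"):
                # reserve a diploid block so the locus stays truly neutral
                if try_place(cand, 2, 1, pad=500_000) is not None:
                    gene_row = cand
                    break
                continue
            if try_place(cand, t, m) is not None:
                gene_row = cand
                break
        if gene_row is None:  # genome too crowded: fall back to a neutral locus
            event, t, m, v = "NONE", 2, 1, 1
            gene_row = genes.iloc[int(rng.integers(len(genes)))]
        used_genes.add(gene_row.gene)
        pos = int(rng.integers(gene_row.start + 1, gene_row.end))
        ref, alt = [str(b) for b in rng.choice(list("ACGT"), size=2, replace=False)]
        if event == "HZ_DEL":
            direction = "DEPLETED"
        elif event in ("NONE", "SOMATIC_MUTATION"):
            direction = "NA"
        elif m == t - m:
            direction = "BALANCED"
        else:
            direction = "ENRICHED" if enriched else "DEPLETED"
        planted.append(
            PlantedVariant(
                gene=str(gene_row.gene), chrom=str(gene_row.chrom), pos=pos,
                ref=ref, alt=alt, event=event, direction=direction,
                total_cn=t, minor_cn=m, variant_copies=v,
            )
        )

    # decoy candidates that must fail exactly one retention rule
    for _ in range(config.decoys_per_patient):
        gene_row = genes.iloc[int(rng.integers(len(genes)))]
        pos = int(rng.integers(gene_row.start + 1, gene_row.end))
        ref, alt = [str(b) for b in rng.choice(list("ACGT"), size=2, replace=False)]
        planted.append(
            PlantedVariant(
                gene=str(gene_row.gene), chrom=str(gene_row.chrom), pos=pos,
                ref=ref, alt=alt, event="NONE", direction="NA",
                total_cn=2, minor_cn=1, variant_copies=1, is_decoy=True,
            )
        )

    # background alterations away from planted loci, for aneuploidy spread
    for chrom, length, cen in config.genome:
        for arm_lo, arm_hi in ((0, cen), (cen, length)):
            if rng.random() >= config.background_alteration_rate:
                continue
            seg_len = int(rng.uniform(10e6, min(30e6, arm_hi - arm_lo)))
            for _attempt in range(20):
                s0 = int(rng.integers(arm_lo, arm_hi - seg_len))
                e0 = s0 + seg_len
                if all(not (s0 < e and s < e0) for s, e, _, _ in placed[chrom]):
                    t, m = (3, 1) if rng.random() < 0.5 else (1, 0)
                    placed[chrom].append((s0, e0, t, m))
                    break

    # tile the rest of the genome with balanced diploid segments
    segments: list[CnSegment] = []
    for chrom, length, _cen in config.genome:
        cursor = 0
        for s0, e0, t, m in sorted(placed[chrom]):
            if s0 > cursor:
                segments.append(CnSegment(sample, chrom, cursor, s0, 2, 1))
            segments.append(CnSegment(sample, chrom, s0, e0, t, m))
            cursor = e0
        if cursor < length:
            segments.append(CnSegment(sample, chrom, cursor, length, 2, 1))

    k = config.n_signatures
    active = rng.choice(k, size=min(3, k), replace=False)
    mixture = np.zeros(k)
    mixture[active] = rng.dirichlet(np.ones(len(active)))
    tmb = rng.uniform(*config.tmb_range)
    n_somatic = int(rng.poisson(tmb * config.capture_size_mb))
    return GroundTruth(
        sample=sample, purity=purity, segments=segments,
        variants=planted, mixture=mixture, n_somatic=n_somatic,
    )


def _draw_het_ad(depth_mean: float, p: float, rng: np.random.Generator,
                 require_het: bool = False) -> tuple[int, int]:
    for _ in range(1000):
        d = int(rng.poisson(depth_mean))
        if d <= (1 if require_het else 0):
            continue
        a = int(rng.binomial(d, p))
        if require_het and (a == 0 or a == d):
            continue
        return d - a, a
    raise RuntimeError("could not draw a heterozygous depth (depth too low?)")


def _observed_fraction(p: float, error_rate: float) -> float:
    return p * (1.0 - error_rate) + (1.0 - p) * error_rate


def simulate_patient(
    config: CohortConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    signature_matrix: Optional[pd.DataFrame] = None,
) -> PatientData:
    """Sample the observable data for one patient from its latent truth.

    Normal allelic depths are binomial around 0.5; tumor depths are Poisson
    with mean scaled by the local DNA content, and tumor alt counts binomial
    around :func:`expected_alt_fraction` for the locus state.
    """
    if signature_matrix is None:
        signature_matrix = make_signature_matrix(config.n_signatures, seed=config.seed)
    rho = truth.purity
    seg_by_chrom: dict[str, list[CnSegment]] = {}
    for s in truth.segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for v in seg_by_chrom.values():
        v.sort(key=lambda s: s.start)

    def locus_state(chrom: str, pos: int) -> tuple[int, int]:
        for s in seg_by_chrom.get(chrom, []):
            if s.contains(pos):
                return s.total_cn, s.minor_cn
        return 2, 1

    def tumor_ad(t: int, v: int) -> tuple[int, int]:
        dna = rho * t + (1.0 - rho) * 2.0
        depth = config.depth_tumor * dna / 2.0
        d = int(rng.poisson(max(depth, 1e-9)))
        if d == 0:
            return 0, 1  # keep a token read so downstream depth checks stay explicit
        if dna == 0:
            return d, 0
        p = _observed_fraction(expected_alt_fraction(rho, t, v), config.error_rate)
        a = int(rng.binomial(d, p))
        return d - a, a

    # candidate germline variants with annotations
    variants: list[GermlineVariant] = []
    for pv in truth.variants:
        ad_n = _draw_het_ad(config.depth_normal, 0.5, rng, require_het=True)
        ad_t = tumor_ad(pv.total_cn, pv.variant_copies)
        if pv.is_decoy:
            mode = int(rng.integers(3))
            pop_af = float(rng.uniform(0.015, 0.2)) if mode == 0 else float(10 ** rng.uniform(-6, -2.5))
            n_dam = int(rng.integers(0, 2)) if mode == 1 else int(rng.integers(2, 9))
            quality = (
                QualityFlags(mapping_phred=float(rng.uniform(5, 30)), strand_bias=bool(rng.random() < 0.5))
                if mode == 2
                else QualityFlags(mapping_phred=60.0)
            )
        else:
            pop_af = float(10 ** rng.uniform(-6, -2.5))
            n_dam = int(rng.integers(2, 9))
            quality = QualityFlags(mapping_phred=60.0)
        variants.append(
            GermlineVariant(
                sample=truth.sample, chrom=pv.chrom, pos=pv.pos, ref=pv.ref, alt=pv.alt,
                gene=pv.gene, ad_normal=ad_n, ad_tumor=ad_t, pop_af=pop_af,
                n_damaging=n_dam, n_splice=0, quality=quality,
            )
        )

    # heterozygous SNV backbone
    backbone: list[HetSnv] = []
    occupied = {(v.chrom, v.pos) for v in variants}
    for chrom, length, _cen in config.genome:
        n_snv = int(round(config.snv_backbone_density * length / 1e6))
        positions = np.sort(rng.integers(1, length, size=n_snv))
        for pos in positions:
            pos = int(pos)
            if (chrom, pos) in occupied:
                continue
            t, m = locus_state(chrom, pos)
            v = m if rng.random() < 0.5 else t - m  # unknown phase
            ad_n = _draw_het_ad(config.depth_normal, 0.5, rng, require_het=True)
            ad_t = tumor_ad(t, v)
            backbone.append(HetSnv(chrom=chrom, pos=pos, ad_normal=ad_n, ad_tumor=ad_t))

    # somatic catalog from the planted signature mixture
    _counts, somatic = simulate_somatic_catalog(
        truth.mixture, signature_matrix, truth.n_somatic, rng, genome=config.genome
    )
    n_indel = int(round(config.indel_fraction * len(somatic) / (1 - config.indel_fraction)))
    for _ in range(n_indel):
        chrom, length, _cen = config.genome[int(rng.integers(len(config.genome)))]
        somatic.append(
            SomaticMutation(
                chrom=chrom, pos=int(rng.integers(2, length)), ref="AT", alt="A",
                type="INDEL", allele_fraction=float(rng.uniform(0.05, 0.5)),
            )
        )
    # planted somatic second mutations in the variant's gene
    for pv in truth.variants:
        if pv.event == "SOMATIC_MUTATION":
            ctx = str(CONTEXT_CLASSES[int(rng.integers(96))])
            ref, alt = _context_ref_alt(ctx)
            somatic.append(
                SomaticMutation(
                    chrom=pv.chrom, pos=pv.pos + 50, ref=ref, alt=alt, type="SNV",
                    context=ctx, allele_fraction=float(rng.uniform(0.05, 0.4)),
                    gene=pv.gene,
                )
            )
    somatic.sort(key=lambda m: (m.chrom, m.pos))
    return PatientData(
        sample=truth.sample,
        germline_variants=variants,
        het_backbone=backbone,
        segments=truth.segments,
        somatic_mutations=somatic,
    )


def simulate_somatic_catalog(
    mixture: Sequence[float],
    signature_matrix,
    n_mutations: int,
    rng: np.random.Generator,
    genome: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[np.ndarray, list[SomaticMutation]]:
    """Draw a 96-context somatic SNV catalog from a signature mixture.

    Counts are multinomial with category probabilities ``M @ mixture``; one
    mutation record (with folded context and a random genomic position when a
    genome is supplied) is emitted per count.
    """
    w = np.asarray(mixture, dtype=float)
    if np.any(w < 0):
        raise ValueError("mixture weights must be non-negative")
    if isinstance(signature_matrix, pd.DataFrame):
        M = signature_matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(signature_matrix, dtype=float)
    if M.shape != (96, w.size):
        raise ValueError(f"signature matrix shape {M.shape} does not match {w.size} weights")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    total = w.sum()
    if n_mutations > 0 and total <= 0:
        raise ValueError("mixture weights sum to zero")
    probs = M @ (w / total) if total > 0 else np.full(96, 1 / 96)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_mutations, probs) if n_mutations > 0 else np.zeros(96, dtype=int)

    records: list[SomaticMutation] = []
    genome = list(genome) if genome is not None else [("chr1", 10_000_000, 5_000_000)]
    for ci, c in enumerate(counts):
        ctx = CONTEXT_CLASSES[ci]
        ref, alt = _context_ref_alt(ctx)
        for _ in range(int(c)):
            chrom, length, _cen = genome[int(rng.integers(len(genome)))]
            records.append(
                SomaticMutation(
                    chrom=chrom, pos=int(rng.integers(2, length)), ref=ref, alt=alt,
                    type="SNV", context=ctx,
                    allele_fraction=float(rng.uniform(0.05, 0.5)),
                )
            )
    return counts, records


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientData], list[GroundTruth], pd.DataFrame]:
    """Simulate a full cohort; returns (patients, truths, signature matrix)."""
    rng = np.random.default_rng(config.seed)
    signature_matrix = make_signature_matrix(config.n_signatures, seed=config.seed)
    patients, truths = [], []
    for i in range(config.n_patients):
        truth = plan_patient(config, f"P{i + 1:03d}", rng)
        patients.append(simulate_patient(config, truth, rng, signature_matrix))
        truths.append(truth)
    return patients, truths, signature_matrix


def truth_table(truths: Iterable[GroundTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for pv in t.variants:
            rows.append(
                (t.sample, pv.gene, pv.chrom, pv.pos, pv.ref, pv.alt, pv.event,
                 pv.direction, pv.total_cn, pv.minor_cn, pv.variant_copies,
                 pv.is_decoy, t.purity)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "gene", "chrom", "pos", "ref", "alt", "event", "direction",
            "total_cn", "minor_cn", "variant_copies", "is_decoy", "purity",
        ],
    )


def write_fixtures(
    patients: Sequence[PatientData],
    truths: Sequence[GroundTruth],
    config: CohortConfig,
    out_dir: str,
    signature_matrix: Optional[pd.DataFrame] = None,
) -> dict:
    """Write a cohort to disk and return the pipeline manifest (also saved).

    Emits, per patient, a paired germline VCF, a somatic VCF, and a SEG file;
    plus cohort-level gene list/table, chromosome table, signature matrix,
    ground-truth TSV, config YAML, and a manifest YAML tying them together.
    """
    os.makedirs(out_dir, exist_ok=True)
    if signature_matrix is None:
        signature_matrix = make_signature_matrix(config.n_signatures, seed=config.seed)
    genes = make_gene_table(config)
    manifest: dict = {"patients": []}

    for pat in patients:
        g = os.path.join(out_dir, f"{pat.sample}.germline.vcf")
        s = os.path.join(out_dir, f"{pat.sample}.somatic.vcf")
        seg = os.path.join(out_dir, f"{pat.sample}.seg")
        shio.write_germline_vcf(g, pat.germline_variants, pat.het_backbone, config.contigs)
        shio.write_somatic_vcf(s, pat.somatic_mutations, config.contigs)
        shio.write_segments(seg, pat.segments)
        manifest["patients"].append(
            {"id": pat.sample, "germline_vcf": g, "somatic_vcf": s, "segments": seg}
        )

    gene_list_path = os.path.join(out_dir, "genes.txt")
    shio.write_gene_list(gene_list_path, list(genes["gene"]))
    gene_table_path = os.path.join(out_dir, "gene_table.tsv")
    genes.to_csv(gene_table_path, sep="\t", index=False)
    chrom_path = os.path.join(out_dir, "chroms.tsv")
    config.chrom_table().to_csv(chrom_path, sep="\t", index=False)
    sig_path = os.path.join(out_dir, "signatures.tsv")
    signature_matrix.to_csv(sig_path, sep="\t")
    truth_path = os.path.join(out_dir, "truth.tsv")
    truth_table(truths).to_csv(truth_path, sep="\t", index=False)
    purities = {t.sample: t.purity for t in truths}
    for entry in manifest["patients"]:
        entry["purity"] = purities.get(entry["id"])

    manifest.update(
        {
            "gene_list": gene_list_path,
            "gene_table": gene_table_path,
            "chrom_table": chrom_path,
            "signatures": sig_path,
            "truth": truth_path,
            "capture_size_mb": config.capture_size_mb,
        }
    )
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "n_patients": config.n_patients,
                "depth_normal": config.depth_normal,
                "depth_tumor": config.depth_tumor,
                "purity_range": list(config.purity_range),
                "snv_backbone_density": config.snv_backbone_density,
                "capture_size_mb": config.capture_size_mb,
                "seed": config.seed,
            },
            fh,
        )
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    manifest["path"] = manifest_path
    return manifest
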