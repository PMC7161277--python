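"""End-to-end orchestration: filter -> DAB -> second hit -> somatic patterns.

`run_pipeline` consumes a manifest (YAML or dict) listing, per patient, a
paired germline VCF, a somatic VCF and an allele-specific segment file, plus
cohort-level resources (candidate-gene list, chromosome/centromere table and
optionally a gene-interval table and a signature matrix).  It produces one
`PatientReport` per patient and a cohort summary, both JSON-serializable,
and echoes every effective threshold into the report header so that each
verdict can be audited.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as shio
from .allele_balance import (
    DEFAULT_ALPHA,
    DEFAULT_NEIGHBORS,
    DEFAULT_WINDOW_MB,
    DabResult,
    confirm_dab,
    scan_patient,
)
from .germline_filter import (
    DEFAULT_MAX_POP_AF,
    DEFAULT_MIN_DAMAGING,
    DEFAULT_MIN_MAPQ_PHRED,
    filter_cohort,
)
from .second_hit import (
    CallDirection,
    Event,
    SecondHitCall,
    calls_table,
    call_direction,
    classify_cna,
    find_somatic_second_mutation,
    locate_segment,
    summarize_cohort,
)
from .somatic_patterns import (
    aneuploidy_fraction,
    catalog_from_records,
    hrd_scores,
    indel_count,
    refit_signatures,
    tmb,
)

logger = logging.getLogger("secondhit")

__all__ = ["PipelineConfig", "PatientReport", "run_pipeline", "export_waterfall", "CohortResult"]


@dataclass
class PipelineConfig:
    alpha: float = DEFAULT_ALPHA
    bh_family: str = "genome"
    neighbors: int = DEFAULT_NEIGHBORS
    window_mb: float = DEFAULT_WINDOW_MB
    max_af: float = DEFAULT_MAX_POP_AF
    min_damaging: int = DEFAULT_MIN_DAMAGING
    min_mapq_phred: float = DEFAULT_MIN_MAPQ_PHRED
    capture_size_mb: float = 60.0
    chi2_correction: bool = False
    low_purity_threshold: float = 0.3

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PatientReport:
    patient_id: str
    config: dict
    retained_variants: list[dict]
    second_hit_calls: list[dict]
    patterns: dict
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatientReport":
        return cls(**d)


@dataclass
class CohortResult:
    reports: list[PatientReport]
    summary: dict
    calls: list[SecondHitCall]


def _load_manifest(manifest: Union[str, dict]) -> dict:
    if isinstance(manifest, dict):
        return manifest
    with open(manifest) as fh:
        return yaml.safe_load(fh)


def _require(path: Optional[str], what: str, patient: str) -> str:
    if not path or not os.path.exists(path):
        raise FileNotFoundError(f"patient {patient}: missing {what}: {path!r}")
    return path


def run_pipeline(manifest: Union[str, dict], config: Optional[PipelineConfig] = None) -> CohortResult:
    """Run the full per-patient pipeline over a cohort manifest."""
    config = config or PipelineConfig()
    man = _load_manifest(manifest)
    gene_list = shio.read_gene_list(man["gene_list"])
    chrom_table = shio.read_chrom_table(man["chrom_table"]) if man.get("chrom_table") else None
    gene_table = shio.read_gene_table(man["gene_table"]) if man.get("gene_table") else None
    signatures = shio.read_signature_matrix(man["signatures"]) if man.get("signatures") else None
    capture = float(man.get("capture_size_mb", config.capture_size_mb))
    genome_size = int(chrom_table["length"].sum()) if chrom_table is not None else None

    reports: list[PatientReport] = []
    all_calls: list[SecondHitCall] = []
    aneuploidy_by_sample: dict[str, float] = {}

    for entry in man["patients"]:
        pid = entry["id"]
        t0 = time.time()
        germ = _require(entry.get("germline_vcf"), "germline VCF", pid)
        som = _require(entry.get("somatic_vcf"), "somatic VCF", pid)
        segf = _require(entry.get("segments"), "segment file", pid)

        candidates, het_sites = shio.read_germline_vcf(germ)
        for v in candidates:
            v.sample = pid
        somatic = shio.read_somatic_vcf(som)
        segments = shio.read_segments(segf)

        flags: list[str] = []
        purity = entry.get("purity")
        if purity is not None and purity < config.low_purity_threshold:
            flags.append("low-purity")

        summary = filter_cohort(
            candidates, gene_list,
            max_af=config.max_af, min_damaging=config.min_damaging,
            min_mapq_phred=config.min_mapq_phred,
        )
        retained = summary.table[summary.table["retained"]]

        dab_results = scan_patient(het_sites, alpha=config.alpha, bh_family=config.bh_family)
        by_site = {(r.chrom, r.pos): r for r in dab_results}

        calls: list[SecondHitCall] = []
        for row in retained.itertuples():
            dab = by_site.get((row.chrom, row.pos))
            if dab is not None:
                conf = confirm_dab(
                    dab, dab_results, segments,
                    k=config.neighbors, window_mb=config.window_mb, alpha=config.alpha,
                )
                dab = DabResult(**{**dab.__dict__})
                dab.confirmed = dab.p_adj < config.alpha and conf.confirmed
                if conf.insufficient_neighbors:
                    flags.append(f"insufficient-neighbors:{row.variant_id}")
            else:
                conf = None

            try:
                seg = locate_segment(row.chrom, row.pos, segments)
            except ValueError as exc:
                raise ValueError(f"patient {pid}: {exc}") from exc

            call_flags: list[str] = []
            if seg is None:
                event = Event.NONE
                call_flags.append("uncovered")
            else:
                event, call_flags = classify_cna(seg, dab)
            direction = call_direction(event, dab, seg)

            evidence = ""
            if seg is not None:
                evidence = f"segment {seg.chrom}:{seg.start}-{seg.end} cn={seg.total_cn}/{seg.minor_cn}"
            if event is Event.NONE:
                muts = find_somatic_second_mutation(row.gene, somatic, direction)
                if muts:
                    event = Event.SOMATIC_MUTATION
                    m0 = muts[0]
                    evidence = (
                        f"somatic {m0['chrom']}:{m0['pos']} {m0['ref']}>{m0['alt']} "
                        f"AF={m0['allele_fraction']:.2f}"
                    )
            calls.append(
                SecondHitCall(
                    variant_id=row.variant_id, sample=pid, gene=row.gene,
                    event=event, direction=direction,
                    dab_confirmed=bool(dab is not None and dab.confirmed),
                    evidence=evidence, flags=call_flags,
                )
            )
        if any("uncovered" in c.flags for c in calls):
            flags.append("uncovered-loci")

        # global somatic patterns
        patterns: dict = {
            "tmb": round(tmb(len(somatic), capture), 1),
            "n_somatic": len(somatic),
            "indel_count": indel_count(somatic),
        }
        snvs_with_ctx = [m for m in somatic if m.type == "SNV" and m.context is not None]
        if signatures is not None and snvs_with_ctx:
            fit = refit_signatures(catalog_from_records(snvs_with_ctx), signatures)
            patterns["signature_relative"] = {
                n: round(float(x), 4) for n, x in zip(fit.names, fit.relative)
            }
            patterns["signature_residual"] = round(fit.residual, 3)
        if chrom_table is not None:
            hrd = hrd_scores(segments, chrom_table)
            patterns["hrd"] = {
                "tai": hrd.tai, "lst": hrd.lst, "loh": hrd.loh,
                "mean_hrd": round(hrd.mean_hrd, 3),
            }
            frac, n_genes = aneuploidy_fraction(segments, genome_size, gene_table)
            patterns["aneuploidy_fraction"] = round(frac, 4)
            if n_genes is not None:
                patterns["aneuploidy_genes"] = n_genes
            aneuploidy_by_sample[pid] = frac

        reports.append(
            PatientReport(
                patient_id=pid,
                config=config.to_dict(),
                retained_variants=retained.to_dict(orient="records"),
                second_hit_calls=[
                    {
                        "variant_id": c.variant_id, "gene": c.gene,
                        "event": c.event.value, "direction": c.direction.value,
                        "dab_confirmed": c.dab_confirmed, "evidence": c.evidence,
                        "flags": c.flags,
                    }
                    for c in calls
                ],
                patterns=patterns,
                flags=flags,
            )
        )
        all_calls.extend(calls)
        logger.info("patient %s: %d retained, %d second hits (%.1fs)",
                    pid, len(retained), sum(c.is_second_hit for c in calls), time.time() - t0)

    cohort = summarize_cohort(all_calls, aneuploidy_by_sample or None)
    summary = {
        "config": config.to_dict(),
        "n_patients": len(reports),
        "n_retained_variants": cohort.n_variants,
        "mean_retained_per_patient": round(cohort.n_variants / len(reports), 2) if reports else 0.0,
        "n_second_hit": cohort.n_second_hit,
        "second_hit_pct": round(100.0 * cohort.n_second_hit / cohort.n_variants, 1)
        if cohort.n_variants else 0.0,
        "n_cna": cohort.n_cna,
        "n_somatic_mutation": cohort.n_somatic_mutation,
        "n_enriched": cohort.n_enriched,
        "n_depleted": cohort.n_depleted,
        "n_balanced": cohort.n_balanced,
        "events": cohort.events,
        "aneuploidy_mannwhitney_p": cohort.aneuploidy_p_value,
        "notes": cohort.aneuploidy_note,
    }
    return CohortResult(reports=reports, summary=summary, calls=all_calls)


def export_waterfall(result: CohortResult) -> pd.DataFrame:
    """Long-format (patient, variant, event, direction) table for waterfall plots."""
    return calls_table(result.calls)


def write_outputs(result: CohortResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for rep in result.reports:
        with open(os.path.join(out_dir, f"{rep.patient_id}.report.json"), "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
    with open(os.path.join(out_dir, "cohort_summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2)
    export_waterfall(result).to_csv(os.path.join(out_dir, "waterfall.tsv"), sep="\t", index=False)
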