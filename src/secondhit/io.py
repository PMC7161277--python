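"""File formats consumed and produced by the pipeline.

Variants travel as VCF 4.2.  The germline file carries two samples (NORMAL,
TUMOR) with allelic depths in the ``AD`` FORMAT field; candidate variants are
annotated through INFO keys (``GENE``, ``POPAF``, ``NDAMAGING``, ``SPLICEHIT``
plus quality flags), while unannotated heterozygous records form the backbone
used for chromosome-wide allele-balance scans.  The somatic file has a single
TUMOR sample and may carry the folded trinucleotide context in ``CTX``.

Allele-specific copy-number segments use a SEG-like tab-delimited layout
(``sample chrom start end total_cn minor_cn``) with half-open intervals.
Variant positions are 1-based as in VCF.

Reading goes through :mod:`pysam`; writing emits plain VCF text, which the
pysam readers round-trip.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .allele_balance import HetSnv
from .germline_filter import GermlineVariant, QualityFlags
from .second_hit import CnSegment
from .somatic_patterns import SomaticMutation

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]

_GERMLINE_HEADER_INFO = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=NDAMAGING,Number=1,Type=Integer,Description="Predictors calling damaging (0-8)">',
    '##INFO=<ID=SPLICEHIT,Number=1,Type=Integer,Description="Splice methods calling altered (0-2)">',
    '##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">',
    '##INFO=<ID=MAPQP,Number=1,Type=Float,Description="Phred-scaled mapping quality">',
    '##INFO=<ID=NHAP,Number=1,Type=Integer,Description="Haplotypes at the position">',
    '##INFO=<ID=OUT3P,Number=1,Type=Integer,Description="Supported outside 3-prime read ends (0/1)">',
    '##INFO=<ID=SBIAS,Number=0,Type=Flag,Description="Strand bias detected">',
    '##INFO=<ID=CURATE,Number=0,Type=Flag,Description="Manually curated as retained">',
]
_SOMATIC_HEADER_INFO = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CTX,Number=1,Type=String,Description="Folded trinucleotide substitution class">',
]
_FORMAT_AD = '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'


def _vcf_header(contigs: Sequence[tuple[str, int]], info_lines: list[str], samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
    lines += info_lines
    lines.append(_FORMAT_AD)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def write_germline_vcf(
    path: str,
    variants: Iterable[GermlineVariant],
    backbone: Iterable[HetSnv],
    contigs: Sequence[tuple[str, int]],
) -> str:
    """Write candidates plus the heterozygous backbone as a paired-sample VCF."""
    rows = []
    for v in variants:
        info = [
            f"GENE={v.gene}",
            f"NDAMAGING={v.n_damaging}",
            f"SPLICEHIT={v.n_splice}",
            f"VCLASS={v.variant_class}",
            f"MAPQP={v.quality.mapping_phred:g}",
            f"NHAP={v.quality.n_haplotypes}",
            f"OUT3P={int(v.quality.supported_outside_3prime)}",
        ]
        if v.pop_af is not None:
            info.insert(1, f"POPAF={v.pop_af:.6g}")
        if v.quality.strand_bias:
            info.append("SBIAS")
        if v.curated_retain:
            info.append("CURATE")
        ad_t = v.ad_tumor if v.ad_tumor is not None else (0, 0)
        rows.append(
            (v.chrom, v.pos, v.ref, v.alt, ";".join(info),
             f"{v.ad_normal[0]},{v.ad_normal[1]}", f"{ad_t[0]},{ad_t[1]}")
        )
    for s in backbone:
        rows.append(
            (s.chrom, s.pos, "A", "G", ".",
             f"{s.ad_normal[0]},{s.ad_normal[1]}", f"{s.ad_tumor[0]},{s.ad_tumor[1]}")
        )
    order = {name: i for i, (name, _) in enumerate(contigs)}
    rows.sort(key=lambda r: (order.get(r[0], len(order)), r[1]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, _GERMLINE_HEADER_INFO, ["NORMAL", "TUMOR"]))
        for chrom, pos, ref, alt, info, adn, adt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tAD\t{adn}\t{adt}\n")
    return path


def read_germline_vcf(path: str) -> tuple[list[GermlineVariant], list[HetSnv]]:
    """Read a paired germline VCF into candidate variants and het backbone sites.

    Records annotated with ``GENE`` become candidates; every record that is
    heterozygous in the normal sample (both allelic depths > 0), candidates
    included, contributes a backbone site for the allele-balance scan.
    """
    sample = os.path.basename(path).split(".")[0]
    candidates: list[GermlineVariant] = []
    het: list[HetSnv] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            adn = tuple(int(x) for x in rec.samples["NORMAL"]["AD"])
            adt = tuple(int(x) for x in rec.samples["TUMOR"]["AD"])
            info = rec.info
            if "GENE" in info:
                popaf = float(info["POPAF"]) if "POPAF" in info else None
                candidates.append(
                    GermlineVariant(
                        sample=sample,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        gene=str(info["GENE"]),
                        variant_class=str(info.get("VCLASS", "missense_inframe")),
                        ad_normal=adn,
                        ad_tumor=adt,
                        pop_af=popaf,
                        n_damaging=int(info.get("NDAMAGING", 0)),
                        n_splice=int(info.get("SPLICEHIT", 0)),
                        quality=QualityFlags(
                            mapping_phred=float(info.get("MAPQP", 60.0)),
                            n_haplotypes=int(info.get("NHAP", 1)),
                            supported_outside_3prime=bool(int(info.get("OUT3P", 1))),
                            strand_bias=bool(info.get("SBIAS", False)),
                        ),
                        curated_retain=bool(info.get("CURATE", False)),
                    )
                )
            if min(adn) > 0:
                het.append(HetSnv(chrom=rec.chrom, pos=rec.pos, ad_normal=adn, ad_tumor=adt))
    return candidates, het


def write_somatic_vcf(
    path: str,
    mutations: Iterable[SomaticMutation],
    contigs: Sequence[tuple[str, int]],
    depth: int = 100,
) -> str:
    """Write somatic calls as a single-sample VCF with AD encoding allele fraction."""
    rows = []
    for m in mutations:
        info_parts = []
        if m.gene:
            info_parts.append(f"GENE={m.gene}")
        if m.context:
            info_parts.append(f"CTX={m.context}")
        info = ";".join(info_parts) if info_parts else "."
        alt_reads = int(round(m.allele_fraction * depth))
        rows.append((m.chrom, m.pos, m.ref, m.alt, info, f"{depth - alt_reads},{alt_reads}"))
    order = {name: i for i, (name, _) in enumerate(contigs)}
    rows.sort(key=lambda r: (order.get(r[0], len(order)), r[1]))
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, _SOMATIC_HEADER_INFO, ["TUMOR"]))
        for chrom, pos, ref, alt, info, ad in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tAD\t{ad}\n")
    return path


def read_somatic_vcf(path: str) -> list[SomaticMutation]:
    out: list[SomaticMutation] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0]
            mtype = "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"
            ad = tuple(int(x) for x in rec.samples["TUMOR"]["AD"])
            total = sum(ad)
            af = ad[1] / total if total else 0.0
            info = rec.info
            out.append(
                SomaticMutation(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    type=mtype,
                    context=str(info["CTX"]) if "CTX" in info else None,
                    allele_fraction=af,
                    gene=str(info["GENE"]) if "GENE" in info else None,
                )
            )
    return out


def write_segments(path: str, segments: Iterable[CnSegment]) -> str:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.total_cn, s.minor_cn) for s in segments],
        columns=SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_segments(path: str) -> list[CnSegment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment file {path} lacks columns: {sorted(missing)}")
    return [
        CnSegment(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            total_cn=int(r.total_cn),
            minor_cn=int(r.minor_cn),
        )
        for r in df.itertuples()
    ]


def read_gene_list(path: str) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(path: str, genes: Sequence[str]) -> str:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
    return path


def read_chrom_table(path: str) -> pd.DataFrame:
    """Chromosome sizes and centromeres: columns ``chrom length centromere``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "length", "centromere"} - set(df.columns)
    if missing:
        raise ValueError(f"chromosome table {path} lacks columns: {sorted(missing)}")
    return df


def read_gene_table(path: str) -> pd.DataFrame:
    """Gene intervals: columns ``gene chrom start end`` (half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns: {sorted(missing)}")
    return df


def read_signature_matrix(path: str) -> pd.DataFrame:
    """96-row signature definitions, context labels in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"signature matrix must have 96 rows, got {df.shape[0]}")
    return df
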