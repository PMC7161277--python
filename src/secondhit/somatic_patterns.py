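"""Global somatic-pattern readouts for a tumor exome.

These are the cohort-level corroborators used alongside locus-level second
hits: tumor mutation burden (TMB), somatic indel count, the 96-trinucleotide-
context mutational catalog and its non-negative least-squares refit against a
known signature matrix, the three homologous-recombination-deficiency (HRD)
scar scores, and the genome-wide aneuploidy fraction.

The 96 classes are the six pyrimidine-strand substitutions (C>A, C>G, C>T,
T>A, T>C, T>G) crossed with the 4x4 flanking bases; purine-strand mutations
are folded onto the pyrimidine strand by reverse complement.

HRD components follow the published scar-score family:

* LOH score — number of loss-of-heterozygosity segments (minor copy 0, total
  copy > 0) longer than 15 Mb that do not span a whole chromosome;
* telomeric allelic imbalance (TAI) — number of allelically imbalanced
  segments that reach a telomere, do not cross the centromere, do not span
  the whole chromosome, and exceed a minimum size (default 11 Mb);
* large-scale state transitions (LST) — number of breakpoints between
  adjacent segments each >= 10 Mb after smoothing away segments < 3 Mb,
  counted per chromosome arm.

The mean HRD score is the unweighted arithmetic mean of the three counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .second_hit import CnSegment

__all__ = [
    "SomaticMutation",
    "SignatureFit",
    "HrdScores",
    "CONTEXT_CLASSES",
    "SUBSTITUTION_TYPES",
    "fold_context",
    "tmb",
    "indel_count",
    "context_matrix",
    "catalog_from_records",
    "refit_signatures",
    "hrd_scores",
    "aneuploidy_fraction",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical ordering of the 96 trinucleotide substitution classes.
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)
_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}


@dataclass
class SomaticMutation:
    """One somatic small variant; ``context`` holds the folded class for SNVs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    type: str = "SNV"  # SNV | INDEL
    context: Optional[str] = None
    allele_fraction: float = 0.0
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in ("SNV", "INDEL"):
            raise ValueError(f"unknown mutation type {self.type!r}")
        if not (0.0 <= self.allele_fraction <= 1.0):
            raise ValueError("allele fraction outside [0,1]")
        if self.context is not None and self.context not in _CLASS_INDEX:
            raise ValueError(f"not a canonical 96-class context: {self.context!r}")


def fold_context(five: str, ref: str, alt: str, three: str) -> str:
    """Canonical 96-class label, reverse-complementing purine-strand mutations."""
    five, ref, alt, three = five.upper(), ref.upper(), alt.upper(), three.upper()
    if ref in ("G", "A"):
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in _CLASS_INDEX:
        raise ValueError(f"invalid substitution context {label!r}")
    return label


def tmb(n_somatic_variants: int, capture_size_mb: float = 60.0) -> float:
    """Tumor mutation burden: somatic variants per megabase of capture."""
    if capture_size_mb <= 0:
        raise ValueError("capture size must be > 0")
    if n_somatic_variants < 0:
        raise ValueError("variant count must be >= 0")
    return n_somatic_variants / capture_size_mb


def indel_count(mutations: Iterable[SomaticMutation]) -> int:
    """Number of somatic small insertions/deletions."""
    return sum(1 for m in mutations if m.type == "INDEL")


def _fetch_triplet(reference, chrom: str, pos: int) -> str:
    """Reference bases at pos-1..pos+1 (1-based) from a FASTA handle or dict."""
    seq = reference[chrom]
    if isinstance(seq, str):
        return seq[pos - 2 : pos + 1].upper()
    # pyfaidx.FastaRecord supports 0-based slicing
    return str(seq[pos - 2 : pos + 1]).upper()


def context_matrix(snvs: Iterable[SomaticMutation], reference) -> np.ndarray:
    """96-context count vector for an SNV catalog, given a reference sequence.

    ``reference`` maps chromosome name to sequence (a ``pyfaidx.Fasta`` or a
    plain dict of strings).  The stated reference base must match each SNV's
    ref allele; the vector sums to the number of SNVs.
    """
    counts = np.zeros(96, dtype=int)
    for m in snvs:
        if m.type != "SNV":
            continue
        triplet = _fetch_triplet(reference, m.chrom, m.pos)
        if len(triplet) != 3:
            raise ValueError(f"reference does not cover {m.chrom}:{m.pos}+-1")
        if triplet[1] != m.ref.upper():
            raise ValueError(
                f"reference base {triplet[1]} != variant ref {m.ref} at {m.chrom}:{m.pos}"
            )
        counts[_CLASS_INDEX[fold_context(triplet[0], m.ref, m.alt, triplet[2])]] += 1
    return counts


def catalog_from_records(mutations: Iterable[SomaticMutation]) -> np.ndarray:
    """96-context vector from SNV records that already carry a folded context."""
    counts = np.zeros(96, dtype=int)
    for m in mutations:
        if m.type != "SNV":
            continue
        if m.context is None:
            raise ValueError(f"SNV at {m.chrom}:{m.pos} has no context annotation")
        counts[_CLASS_INDEX[m.context]] += 1
    return counts


@dataclass
class SignatureFit:
    contributions: np.ndarray        # absolute weight per signature, >= 0
    relative: np.ndarray             # contributions / sum, or zeros when undefined
    residual: float                  # ||catalog - M w||_2
    undefined: bool = False          # True for an all-zero catalog
    names: Optional[list[str]] = None


def refit_signatures(
    catalog: np.ndarray,
    signature_matrix,
    names: Optional[Sequence[str]] = None,
) -> SignatureFit:
    """Non-negative least-squares refit of a 96-context catalog.

    Solves min ||catalog - M w||_2 subject to w >= 0, where M has one column
    per signature (each column a probability distribution over the 96
    classes).  Relative contributions are w normalized to sum 1; they are
    undefined (flagged, all zeros) for an empty catalog.
    """
    if isinstance(signature_matrix, pd.DataFrame):
        if names is None:
            names = list(signature_matrix.columns)
        M = signature_matrix.to_numpy(dtype=float)
    else:
        M = np.asarray(signature_matrix, dtype=float)
    y = np.asarray(catalog, dtype=float)
    if M.ndim != 2 or M.shape[0] != y.shape[0]:
        raise ValueError(f"signature matrix shape {M.shape} does not match catalog {y.shape}")
    if np.any(M < 0):
        raise ValueError("signature matrix must be non-negative")
    w, rnorm = nnls(M, y)
    total = w.sum()
    undefined = total <= 0
    rel = w / total if not undefined else np.zeros_like(w)
    return SignatureFit(
        contributions=w,
        relative=rel,
        residual=float(rnorm),
        undefined=bool(undefined),
        names=list(names) if names is not None else None,
    )


@dataclass
class HrdScores:
    tai: int
    lst: int
    loh: int

    @property
    def mean_hrd(self) -> float:
        return (self.tai + self.lst + self.loh) / 3.0


def _merge_adjacent(segs: list[CnSegment]) -> list[tuple[int, int, int, int]]:
    """Merge touching/adjacent same-state segments into (start, end, t, m) runs."""
    out: list[list[int]] = []
    for s in sorted(segs, key=lambda x: x.start):
        if out and out[-1][2] == s.total_cn and out[-1][3] == s.minor_cn:
            out[-1][1] = max(out[-1][1], s.end)
        else:
            out.append([s.start, s.end, s.total_cn, s.minor_cn])
    return [tuple(x) for x in out]


def _smooth(runs: list[tuple[int, int, int, int]], min_len: float) -> list[tuple[int, int, int, int]]:
    """Iteratively drop runs shorter than min_len, rejoining equal-state neighbors."""
    runs = list(runs)
    changed = True
    while changed:
        changed = False
        short = [i for i, r in enumerate(runs) if r[1] - r[0] < min_len]
        if short:
            i = min(short, key=lambda j: runs[j][1] - runs[j][0])
            runs.pop(i)
            changed = True
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][2] == r[2] and merged[-1][3] == r[3]:
                merged[-1][1] = max(merged[-1][1], r[1])
                changed = changed or True
            else:
                merged.append(list(r))
        if len(merged) != len(runs):
            changed = True
        runs = [tuple(x) for x in merged]
    return runs


def hrd_scores(
    segments: Iterable[CnSegment],
    chrom_table: pd.DataFrame,
    *,
    loh_min_mb: float = 15.0,
    tai_min_mb: float = 11.0,
    lst_min_mb: float = 10.0,
    lst_smooth_mb: float = 3.0,
) -> HrdScores:
    """The three HRD scar counts and their mean for one tumor sample.

    ``chrom_table`` must have columns ``chrom``, ``length``, ``centromere``.
    Segments on a chromosome missing from the table raise a configuration
    error.  Adjacent same-state segments are merged before counting, so the
    scores are invariant to how upstream callers split identical regions.
    """
    segs = list(segments)
    info = {r.chrom: (int(r.length), int(r.centromere)) for r in chrom_table.itertuples()}
    by_chrom: dict[str, list[CnSegment]] = {}
    for s in segs:
        if s.chrom not in info:
            raise ValueError(f"no chromosome/centromere entry for {s.chrom}")
        by_chrom.setdefault(s.chrom, []).append(s)

    loh = tai = lst = 0
    for chrom, chrom_segs in by_chrom.items():
        length, cen = info[chrom]
        runs = _merge_adjacent(chrom_segs)
        lo = min(r[0] for r in runs)
        hi = max(r[1] for r in runs)

        for start, end, t, m in runs:
            spans_whole = (start == lo and end == hi)
            # LOH score: minor allele lost, large, not the whole chromosome
            if m == 0 and t > 0 and (end - start) > loh_min_mb * 1e6 and not spans_whole:
                loh += 1
            # Telomeric allelic imbalance
            imbalanced = m != t - m
            telomeric = start <= lo or end >= hi
            at_start = start == lo
            at_end = end == hi
            crosses_cen = start < cen < end
            if (
                imbalanced
                and (at_start or at_end)
                and not spans_whole
                and not crosses_cen
                and (end - start) >= tai_min_mb * 1e6
            ):
                tai += 1

        # LST: per arm, smoothed breakpoint count
        for arm_lo, arm_hi in ((lo, cen), (cen, hi)):
            arm_runs = []
            for start, end, t, m in runs:
                s0, e0 = max(start, arm_lo), min(end, arm_hi)
                if e0 > s0:
                    arm_runs.append((s0, e0, t, m))
            arm_runs = _smooth(arm_runs, lst_smooth_mb * 1e6)
            for a, b in zip(arm_runs, arm_runs[1:]):
                if (a[2], a[3]) != (b[2], b[3]):
                    if (a[1] - a[0]) >= lst_min_mb * 1e6 and (b[1] - b[0]) >= lst_min_mb * 1e6:
                        lst += 1
    return HrdScores(tai=tai, lst=lst, loh=loh)


def _check_non_overlapping(segs: list[CnSegment]) -> None:
    by_chrom: dict[str, list[CnSegment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        ss = sorted(ss, key=lambda x: x.start)
        for a, b in zip(ss, ss[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )


def aneuploidy_fraction(
    segments: Iterable[CnSegment],
    genome_size_bp: int,
    gene_table: Optional[pd.DataFrame] = None,
) -> tuple[float, Optional[int]]:
    """Fraction of the genome in an altered copy state, plus gene overlap count.

    A segment is altered when its total copy number differs from 2 or its
    minor copy number is 0 (amplifications, deletions, LOH, and copy-neutral
    LOH all qualify).  When ``gene_table`` (columns ``gene``, ``chrom``,
    ``start``, ``end``) is given, the number of listed genes overlapped by at
    least one altered segment is also returned.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be > 0")
    segs = list(segments)
    _check_non_overlapping(segs)
    altered = [s for s in segs if s.total_cn != 2 or s.minor_cn == 0]
    frac = sum(s.length for s in altered) / genome_size_bp

    n_genes: Optional[int] = None
    if gene_table is not None:
        hit = set()
        for g in gene_table.itertuples():
            for s in altered:
                if s.chrom == g.chrom and s.start < g.end and g.start < s.end:
                    hit.add(g.gene)
                    break
        n_genes = len(hit)
    return frac, n_genes
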