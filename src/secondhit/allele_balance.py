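"""Difference-in-allele-balance (DAB) analysis.

At a germline-heterozygous site, roughly half the reads in blood carry the
alternate allele.  A somatic copy-number event (or strong selection) in the
tumor shifts that fraction.  The DAB test compares the tumor and normal
allelic depths at one site with a Pearson chi-square on the 2x2 table

    [[ref_normal, alt_normal],
     [ref_tumor,  alt_tumor ]]

without continuity correction (depths of 60-120x make the Yates correction
immaterial; it remains available via ``correction=True``).

A single significant site is weak evidence: FFPE artifacts and mapping noise
produce isolated outliers.  A shift is therefore *confirmed* only when the
surrounding region — the enclosing copy-number segment, or a genomic window
when segments are unavailable — contains enough neighboring heterozygous
SNVs that shift in magnitude as well.  Neighbor comparisons use |delta|
because the phase of backbone SNVs relative to the variant is unknown, so
the *sign* of a neighbor's shift is arbitrary.

Multiple testing over all heterozygous sites of a patient is handled with
the Benjamini-Hochberg step-up procedure (per-patient genome-wide family by
default; per-chromosome optionally).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HetSnv",
    "Direction",
    "DabResult",
    "Confirmation",
    "dab_test",
    "bh_adjust",
    "chromosome_scan",
    "scan_patient",
    "confirm_dab",
    "DEFAULT_ALPHA",
    "DEFAULT_NEIGHBORS",
    "DEFAULT_WINDOW_MB",
    "LOW_DEPTH_THRESHOLD",
]

DEFAULT_ALPHA = 0.05
DEFAULT_NEIGHBORS = 3
DEFAULT_WINDOW_MB = 5.0
LOW_DEPTH_THRESHOLD = 10


class Direction(str, Enum):
    ENRICHED = "ENRICHED"
    DEPLETED = "DEPLETED"
    NONE = "NONE"


@dataclass(frozen=True)
class HetSnv:
    """A germline-heterozygous SNV with paired allelic depths (ref, alt)."""

    chrom: str
    pos: int
    ad_normal: tuple[int, int]
    ad_tumor: tuple[int, int]

    def __post_init__(self) -> None:
        if min(self.ad_normal) <= 0:
            raise ValueError(
                f"not heterozygous in normal at {self.chrom}:{self.pos}: AD={self.ad_normal}"
            )
        if min(self.ad_tumor) < 0:
            raise ValueError("tumor depths must be >= 0")


@dataclass
class DabResult:
    chrom: str
    pos: int
    chi2: float
    p_raw: float
    p_adj: float = 1.0
    delta_ab: float = 0.0
    direction: Direction = Direction.NONE
    confirmed: bool = False
    low_depth: bool = False


def dab_test(
    ad_normal: tuple[int, int],
    ad_tumor: tuple[int, int],
    correction: bool = False,
) -> tuple[float, float, float]:
    """Pearson chi-square comparison of tumor vs normal allele balance.

    Returns ``(chi2, p_raw, delta_ab)`` where ``delta_ab`` is the tumor alt
    fraction minus the normal alt fraction.  A degenerate table in which one
    allele is absent from both samples carries no imbalance information and
    yields ``(0, 1, delta)``.
    """
    rn, an = ad_normal
    rt, at = ad_tumor
    if min(rn, an, rt, at) < 0:
        raise ValueError("allelic depths must be >= 0")
    n_tot = rn + an
    t_tot = rt + at
    if n_tot == 0 or t_tot == 0:
        raise ValueError("zero total depth in a sample")
    delta = at / t_tot - an / n_tot
    ref_tot = rn + rt
    alt_tot = an + at
    if ref_tot == 0 or alt_tot == 0:
        return 0.0, 1.0, delta
    n = n_tot + t_tot
    chi2 = n * (rn * at - an * rt) ** 2 / (n_tot * t_tot * ref_tot * alt_tot)
    if correction:
        num = abs(rn * at - an * rt) - n / 2.0
        chi2 = n * max(num, 0.0) ** 2 / (n_tot * t_tot * ref_tot * alt_tot)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, float(delta)


def _dab_test_arrays(
    rn: np.ndarray, an: np.ndarray, rt: np.ndarray, at: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson 2x2 test used by the per-patient scans."""
    rn = rn.astype(float)
    an = an.astype(float)
    rt = rt.astype(float)
    at = at.astype(float)
    n_tot = rn + an
    t_tot = rt + at
    if np.any(n_tot == 0) or np.any(t_tot == 0):
        raise ValueError("zero total depth in a sample")
    delta = at / t_tot - an / n_tot
    ref_tot = rn + rt
    alt_tot = an + at
    n = n_tot + t_tot
    denom = n_tot * t_tot * ref_tot * alt_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (rn * at - an * rt) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(denom > 0, p, 1.0)
    return chi2, p, delta


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan_patient(
    het_snvs: Iterable[HetSnv],
    alpha: float = DEFAULT_ALPHA,
    bh_family: str = "genome",
    low_depth: int = LOW_DEPTH_THRESHOLD,
) -> list[DabResult]:
    """DAB-test every heterozygous site of a patient and BH-adjust jointly.

    ``bh_family='genome'`` adjusts over all sites of the patient (the default:
    a single Manhattan-style family per patient); ``'chromosome'`` adjusts
    each chromosome separately.
    """
    snvs = list(het_snvs)
    if not snvs:
        return []
    rn = np.array([s.ad_normal[0] for s in snvs])
    an = np.array([s.ad_normal[1] for s in snvs])
    rt = np.array([s.ad_tumor[0] for s in snvs])
    at = np.array([s.ad_tumor[1] for s in snvs])
    chi2, p_raw, delta = _dab_test_arrays(rn, an, rt, at)

    p_adj = np.empty_like(p_raw)
    if bh_family == "genome":
        p_adj[:] = bh_adjust(p_raw)
    elif bh_family == "chromosome":
        chroms = np.array([s.chrom for s in snvs])
        for c in np.unique(chroms):
            idx = chroms == c
            p_adj[idx] = bh_adjust(p_raw[idx])
    else:
        raise ValueError(f"unknown bh_family: {bh_family!r}")

    out = []
    for i, s in enumerate(snvs):
        sig = p_adj[i] < alpha
        if not sig:
            direction = Direction.NONE
        else:
            direction = Direction.ENRICHED if delta[i] > 0 else Direction.DEPLETED
        out.append(
            DabResult(
                chrom=s.chrom,
                pos=s.pos,
                chi2=float(chi2[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                delta_ab=float(delta[i]),
                direction=direction,
                low_depth=(s.ad_tumor[0] + s.ad_tumor[1]) < low_depth,
            )
        )
    return out


def chromosome_scan(
    het_snvs: Iterable[HetSnv],
    chrom: str,
    alpha: float = DEFAULT_ALPHA,
    bh_family: str = "genome",
) -> list[DabResult]:
    """Per-site DAB results for one chromosome, adjusted within the patient family."""
    results = scan_patient(het_snvs, alpha=alpha, bh_family=bh_family)
    return [r for r in results if r.chrom == chrom]


@dataclass
class Confirmation:
    """Outcome of the regional confirmation of a candidate DAB."""

    confirmed: bool
    n_significant: int
    n_neighbors: int
    insufficient_neighbors: bool
    used_window: bool


def confirm_dab(
    variant_result: DabResult,
    neighbor_results: Sequence[DabResult],
    segments: Optional[Sequence] = None,
    k: int = DEFAULT_NEIGHBORS,
    window_mb: float = DEFAULT_WINDOW_MB,
    alpha: float = DEFAULT_ALPHA,
) -> Confirmation:
    """Confirm a candidate allele-balance shift from its genomic neighborhood.

    Neighbors are the other heterozygous SNVs on the variant's chromosome that
    lie in the same copy-number segment (half-open intervals) or, when no
    segment covers the variant, within ``window_mb`` megabases.  The shift is
    confirmed when at least ``k`` neighbors are significant after adjustment
    and shift by at least half the variant's |delta_ab|.
    """
    lo: float
    hi: float
    used_window = True
    if segments:
        seg = next(
            (
                s
                for s in segments
                if s.chrom == variant_result.chrom and s.start <= variant_result.pos < s.end
            ),
            None,
        )
        if seg is not None:
            lo, hi = seg.start, seg.end
            used_window = False
    if used_window:
        half = window_mb * 1e6 / 2.0
        lo, hi = variant_result.pos - half, variant_result.pos + half

    half_mag = abs(variant_result.delta_ab) / 2.0
    neighbors = [
        r
        for r in neighbor_results
        if r.chrom == variant_result.chrom and lo <= r.pos < hi and r.pos != variant_result.pos
    ]
    n_sig = sum(1 for r in neighbors if r.p_adj < alpha and abs(r.delta_ab) >= half_mag)
    insufficient = len(neighbors) < k
    return Confirmation(
        confirmed=(not insufficient) and n_sig >= k,
        n_significant=n_sig,
        n_neighbors=len(neighbors),
        insufficient_neighbors=insufficient,
        used_window=used_window,
    )


def results_table(results: Sequence[DabResult]) -> pd.DataFrame:
    """Long-format per-site table (Manhattan-plot ready: -log10 adjusted p included)."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "chi2": [r.chi2 for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "delta_ab": [r.delta_ab for r in results],
            "direction": [r.direction.value for r in results],
            "confirmed": [r.confirmed for r in results],
            "low_depth": [r.low_depth for r in results],
        }
    )
    with np.errstate(divide="ignore"):
        df["neglog10_p_adj"] = -np.log10(df["p_adj"].to_numpy(dtype=float))
    return df
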