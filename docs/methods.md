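# Methods

## The allele-balance model

A germline-heterozygous locus in blood yields alternate-allele reads at
fraction ~0.5. In a tumor sample of purity ρ (fraction of tumor-derived
cells), where the locus has total copy number t of which v copies carry the
variant allele, the expected variant-allele read fraction is the DNA-weighted
admixture of the tumor (v of t copies) and contaminating normal cells
(1 of 2 copies):

    f(ρ, t, v) = (ρ·v + (1 − ρ)) / (ρ·t + 2(1 − ρ)).

f is strictly increasing in v for any ρ > 0 and equals 0.5 exactly when
v = t/2 — balanced states are invisible to allele-balance analysis, which is
why amplifications of both alleles are reported as BALANCED rather than
enriched or depleted. The degenerate case ρ = 1, t = 0 (no DNA at the locus)
is rejected as an error.

## The DAB test and its confirmation

Each heterozygous site is tested by the Pearson chi-square (1 df) on the
2×2 table of (ref, alt) depths in normal vs tumor, without continuity
correction: at the 60–120× coverages this analysis targets, the Yates
correction changes nothing material, and leaving it off keeps the statistic
equal to the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) used as the test
oracle. The correction remains available (`correction=True`). A table in
which one allele is absent from both samples carries no imbalance signal and
is defined as χ² = 0, p = 1; zero total depth in either sample is an error.
Tumor depth below 10 reads is tested but flagged `low_depth`.

Multiple testing is controlled with Benjamini–Hochberg. The family is all
heterozygous sites of a patient (genome-wide) by default: the analysis is a
single per-patient Manhattan-style scan, and restricting the family per
chromosome would make a site's verdict depend on which chromosome list it
was submitted in. A per-chromosome family is available
(`bh_family="chromosome"`).

An isolated significant site is not believed. Confirmation requires at
least K = 3 neighboring heterozygous SNVs — in the same copy-number segment
as the variant, or within a W = 5 Mb window when no segment covers it — to
be significant after adjustment with |Δ| at least half the variant's |Δ|.
Neighbors are compared on magnitude, not sign: backbone SNVs are unphased
relative to the variant, so a copy-number event pushes each one toward 0 or
1 at random and the sign of its shift is arbitrary. K and W are exposed
because "the surrounding region" has no canonical size; with ~10 het SNVs
per Mb a 20 Mb event offers ~200 neighbors, so K = 3 is a weak requirement
that mainly suppresses isolated artifacts. Fewer than K neighbors in the
region yields "unconfirmed" with an explicit insufficient-neighbors flag
rather than a silent pass or fail.

## Second-hit classification

Copy states come from upstream allele-specific segmentation (e.g. FACETS)
and are consumed, not inferred. The decision table over (t, m, DAB):

| state                         | event           | rationale |
|-------------------------------|-----------------|-----------|
| t = 0                         | HZ_DEL          | both alleles lost |
| t ≥ 6                         | AMPLIFICATION   | the clinically meaningful gain threshold |
| t = 2, m = 0, DAB confirmed   | CN_LOH          | diploid with one parental allele lost |
| t = 2, m = 0, unconfirmed     | NONE + flag     | indistinguishable from a segmentation artifact |
| m = 0, 1 ≤ t < 6, t ≠ 2       | LOH             | one parental allele lost, incl. 3+0/4+0/5+0 gained-LOH states |
| otherwise                     | NONE            | balanced diploid or sub-threshold balanced gain |

The classes are mutually exclusive and exhaustive over the (t, m, DAB)
space (verified by brute force in the tests). Gained LOH above 2 copies but
below 6 is labelled LOH rather than amplification: the defining biology is
the absent parental allele, not the modest gain. A discordance flag is set
whenever the segment's allele state and the DAB verdict disagree (an
imbalanced segment without a confirmed shift, or a balanced one with it) —
this is the cross-check that vets upstream allele calls, and for 2+0
segments it is promoted into the classification itself.

Direction of selection: HZ_DEL is always DEPLETED (both alleles are gone);
otherwise a confirmed shift's sign decides ENRICHED/DEPLETED; an
amplification without a confirmed shift is BALANCED; anything else is NA.
A deletion at t = 1 is read through the shift sign: enrichment means the
normal allele was lost, depletion means the variant allele was.

Somatic second mutations in the variant's gene are reported with their
allele fraction for human review — no automated driver/passenger verdict —
and are suppressed when the germline variant is somatically depleted, since
a cell losing the germline variant cannot be selected for cooperating hits
in the same gene. Loci uncovered by any segment get NONE with an
`uncovered` flag: absence of evidence is kept distinct from evidence of
absence.

## Global somatic patterns

* **TMB** = somatic variant count / capture size, default 60 Mb, reported
  to one decimal. SNVs and indels both count by default (the defensible
  reading of "somatic variants"); a caller can restrict to SNVs by passing
  the filtered count.
* **Signature refit**: the 96-context catalog (pyrimidine-strand folded) is
  decomposed against a user-supplied signature matrix by non-negative least
  squares, min ‖y − Mw‖₂ s.t. w ≥ 0; relative contributions are w/Σw,
  undefined (flagged) for an empty catalog. The refit is exact when the
  catalog lies in the non-negative column span.
* **HRD scars**, computed on segments merged across identical adjacent
  states (so every score is invariant to how a caller split a region):
  LOH score counts minor-copy-0 segments (t > 0) longer than 15 Mb that do
  not span a whole chromosome; TAI counts allelically imbalanced
  (m ≠ t − m) segments reaching a telomere, not crossing the centromere,
  not spanning the whole chromosome, and ≥ 11 Mb; LST counts breakpoints
  between adjacent ≥ 10 Mb segments per arm after iteratively smoothing
  away runs < 3 Mb. All thresholds are keyword-configurable; the mean HRD
  score is the unweighted mean of the three counts. Telomere/whole-
  chromosome checks use the extent of segment coverage per chromosome,
  which for exome-derived segmentation is the practical proxy for the
  telomeres. The homozygous-deletion exclusion (t > 0) in the LOH score
  keeps rare large deletions from double-counting as LOH.
* **Aneuploidy fraction** = summed length of segments with t ≠ 2 or m = 0
  over the genome size — amplifications, deletions, LOH and copy-neutral
  LOH all count as altered. Optionally the number of candidate-list genes
  overlapped by altered segments is reported. Patients with vs without a
  second hit are compared on this fraction by a two-sided Mann–Whitney
  rank-sum test.

## The synthetic cohort

The generator emulates exactly the observables the pipeline consumes:
paired allelic depths at candidate and backbone het sites, allele-specific
segments, and a somatic catalog. Depth is Poisson around the configured
mean — in the tumor scaled by local DNA content (ρt + 2(1−ρ))/2 — and
allele counts are binomial around f(ρ, t, v); an optional symmetric
per-read error rate (default 0) is available as a robustness knob.
Backbone SNVs take v ∈ {m, t − m} by a fair coin, modelling unknown phase.

Defaults encode the study conditions the pipeline targets: 60× normal and
120× tumor coverage, purity uniform on 0.3–0.9 (samples below 30% purity
are the acknowledged blind spot of allele-balance methods), 5 candidate
variants per patient, a 17% second-hit planting rate dominated by CNAs with
an even enrichment/depletion split, a 60 Mb capture, and ~10 het SNVs per
Mb on a compact 330 Mb four-chromosome genome (full-size chromosomes would
only scale runtime, not behavior). Each patient also receives decoy
candidate calls that fail exactly one retention rule, background
copy-number alterations away from variant loci (so aneuploidy varies
between patients), and a somatic catalog drawn multinomially from a planted
mixture of synthetic signatures with near-disjoint context support.
Planted neutral loci reserve a diploid block around their gene so that a
background alteration cannot silently turn a "no second hit" truth label
false.

What passing tests on this cohort do **not** show: robustness to FFPE
artifacts, mapping bias, subclonal copy-number mixtures, tumor-in-normal
contamination (assumed absent), or segmentation error — the segments the
classifier reads are the planted truth, so classification accuracy on
synthetic data isolates the logic downstream of segmentation, and the
stochastic element is confined to read sampling at the variant and backbone
sites (which is what limits CN-LOH confirmation at moderate purity).

## Numerical and design notes

* BH adjustment delegates to statsmodels' `fdr_bh`; the tests hold it to a
  brute-force step-up oracle on all orderings of ≤ 6 p-values.
* The chi-square p-value uses the χ²₁ survival function; statistics are
  computed vectorized for whole-patient scans (~3–10k sites in well under a
  second).
* Problem sizes in the shipped checks — 20-patient cohorts, 1000-site null
  calibrations, 10 000-mutation signature refits — were chosen to make the
  binomial/multinomial error bands comfortably smaller than the thresholds
  they are compared against while keeping a full run in seconds.
* Established-gene variants flagged `curated_retain` bypass only the
  pathogenicity rule: manual ACMG curation can rescue a variant with weak
  in-silico support, but not a technically unreliable call.
* Report JSON is round-trip lossless; all effective thresholds are echoed
  into each patient report header for auditability.

## Known limitations

Phasing, haplotype-aware imbalance models, read-level bias correction,
epigenetic second hits, clonality/timing inference, microsatellite
instability scoring and driver-gene significance testing are out of scope.
The aneuploidy/TAI telomere proxy (segment-coverage extent) slightly
undercounts telomeric events when upstream segmentation does not reach the
chromosome ends.
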