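# secondhit

Tumor-informed refinement of germline variants in cancer-predisposition
genes.

When a family at high cancer risk is screened with a multigene panel, most
findings are variants of unknown significance (VUS). Under the two-hit model
of tumor-suppressor inactivation, a germline variant that truly drives
oncogenesis should be accompanied in the patient's tumor by a somatic second
hit in the same gene — a copy-number alteration (CNA) that removes or
outcompetes the normal allele, or a second small mutation. `secondhit`
implements the analysis that turns matched tumor/normal exome calls into
that evidence, for clinical genetics and translational oncology groups who
already have upstream variant and copy-number calls in hand.

## What it computes

**Germline filtering.** Rare candidate variants are retained when they lie
in a configurable candidate-gene list and pass mapping quality (Phred > 30,
≤ 2 haplotypes, support outside 3′ read ends, no strand bias), population
rarity (database allele frequency < 0.015, with unseen variants passing),
and in-silico pathogenicity (≥ 2 of 8 missense predictors, or a splice-effect
call). Variants in the nine established breast-cancer genes (*BRCA1*,
*BRCA2*, *TP53*, *PALB2*, *ATM*, *CHEK2*, *CDH1*, *PTEN*, *STK11*) are
flagged for manual curation.

**Allele-balance testing (DAB).** At a germline-heterozygous site with
allelic depths $(r_N, a_N)$ in blood and $(r_T, a_T)$ in tumor, the
difference in allele balance is tested with the Pearson chi-square on the
2×2 table (no continuity correction, 1 df), with
$\Delta = a_T/(r_T{+}a_T) - a_N/(r_N{+}a_N)$ carrying the direction
(enrichment vs depletion of the variant allele). All heterozygous SNVs of a
patient are tested and Benjamini–Hochberg adjusted as one family; a shift at
the variant is *confirmed* only when ≥ K (default 3) neighboring SNVs in the
same copy-number segment (or a 5 Mb window) are also significant with at
least half the variant's |Δ|.

**Second-hit classification.** From allele-specific segments (total copy t,
minor copy m, e.g. from FACETS): homozygous deletion (t = 0), amplification
(t ≥ 6), copy-neutral LOH (t = 2, m = 0 **and** confirmed DAB), LOH (m = 0,
1 ≤ t < 6, t ≠ 2). Somatic small mutations in the same gene are reported as
candidate second hits with their allele fraction, unless the germline
variant is somatically depleted (negative selection refutes cooperation).

**Global somatic patterns.** Tumor mutation burden (variants per Mb of a
60 Mb capture), somatic indel count, the 96-trinucleotide-context catalog
and its non-negative least-squares refit against a signature matrix, the
three HRD scar scores (LOH > 15 Mb, telomeric allelic imbalance, large-scale
state transitions) with their mean, and the genome-wide aneuploidy fraction
with a Mann–Whitney comparison between patients with and without second
hits.

A first-class synthetic-cohort generator produces matched fixtures with
known ground truth (purity, copy states, planted events, signature
mixtures), so the whole pipeline is testable without patient data: tumor
alt-allele fractions follow
$f = \frac{\rho v + (1-\rho)}{\rho t + 2(1-\rho)}$
for purity ρ and v variant-carrying of t copies, with Poisson depth and
binomial allele sampling.

## Worked example

```bash
secondhit simulate --out-dir demo --patients 5 --seed 21
secondhit run --manifest demo/manifest.yaml --out-dir demo_out
```

The run prints the cohort summary (this output, seed 21):

```json
{
  "n_patients": 5,
  "n_retained_variants": 25,
  "mean_retained_per_patient": 5.0,
  "n_second_hit": 1,
  "second_hit_pct": 4.0,
  "n_cna": 1,
  "n_somatic_mutation": 0,
  "n_enriched": 0,
  "n_depleted": 1,
  "n_balanced": 0,
  "events": {"LOH": 0, "CN_LOH": 1, "HZ_DEL": 0, "AMPLIFICATION": 0,
             "SOMATIC_MUTATION": 0, "NONE": 24},
  "aneuploidy_mannwhitney_p": 0.8
}
```

Each patient gets 5 retained candidates (the planted rate, with decoy calls
failing the filters removed); at this seed one of the 25 loci carries a
somatic second hit — a copy-neutral LOH that depletes the germline variant
in the tumor — and the aneuploidy burden does not differ between patients
with and without a hit (Mann–Whitney p = 0.8). Per-patient
JSON reports in `demo_out/` list every call with its segment evidence and
confirmation flags, and `waterfall.tsv` is the long-format table for a
waterfall plot of events across the cohort.

Library use mirrors the CLI: `filter_cohort`, `scan_patient`/`confirm_dab`,
`classify_cna`/`call_direction`, `tmb`/`refit_signatures`/`hrd_scores`, and
`run_pipeline` over a YAML manifest.

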