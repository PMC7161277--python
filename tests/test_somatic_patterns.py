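"""TMB, 96-context catalogs, signature refitting, HRD scars, aneuploidy."""
import numpy as np
import pandas as pd
import pytest

from secondhit import (
    CONTEXT_CLASSES,
    CnSegment,
    SomaticMutation,
    aneuploidy_fraction,
    catalog_from_records,
    context_matrix,
    fold_context,
    hrd_scores,
    indel_count,
    make_signature_matrix,
    refit_signatures,
    simulate_somatic_catalog,
    tmb,
)


class TestTmb:
    def test_hypermutated_sample(self):
        # 5444 somatic variants over a 60 Mb capture
        assert int(tmb(5444, 60)) == 90

    def test_moderately_mutated_sample(self):
        assert round(tmb(395, 60), 1) == 6.6

    def test_zero_variants(self):
        assert tmb(0, 60) == 0.0

    def test_linear_in_count(self):
        assert tmb(2000, 60) == pytest.approx(2 * tmb(1000, 60))

    def test_invalid_capture(self):
        with pytest.raises(ValueError):
            tmb(10, 0)


def test_indel_count():
    muts = [
        SomaticMutation("chr1", i, "C", "T", type="SNV", context="A[C>T]A")
        for i in range(1, 97)
    ] + [
        SomaticMutation("chr1", 200 + i, "AT", "A", type="INDEL") for i in range(4)
    ]
    assert indel_count(muts) == 4
    assert indel_count([]) == 0
    assert indel_count(muts[:96]) == 0


class TestContextMatrix:
    def test_purine_fold_hand_oracle(self):
        """A>G at T[A]C folds by reverse complement to G[T>C]A."""
        ref = {"chr1": "AATACAA"}  # pos 4 (1-based) is the A of TAC
        snv = SomaticMutation("chr1", 4, "A", "G", type="SNV")
        counts = context_matrix([snv], ref)
        assert counts.sum() == 1
        assert counts[CONTEXT_CLASSES.index("G[T>C]A")] == 1
        assert fold_context("T", "A", "G", "C") == "G[T>C]A"

    def test_pyrimidine_untouched(self):
        assert fold_context("A", "C", "T", "G") == "A[C>T]G"

    def test_empty_catalog(self):
        assert context_matrix([], {"chr1": "ACGT"}).sum() == 0

    def test_strand_fold_invariance(self, rng):
        """A catalog plus its reverse-complemented copy doubles the vector."""
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ref = {"chr1": seq, "chr1_rc": "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in reversed(seq)
        )}
        snvs, mirrored = [], []
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        n = len(seq)
        for pos in range(2, n):
            b = seq[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[b]
            snvs.append(SomaticMutation("chr1", pos, b, alt, type="SNV"))
            mirrored.append(
                SomaticMutation("chr1_rc", n - pos + 1, comp[b], comp[alt], type="SNV")
            )
        single = context_matrix(snvs, ref)
        double = context_matrix(snvs + mirrored, ref)
        np.testing.assert_array_equal(double, 2 * single)
        assert single.sum() == len(snvs)

    def test_reference_mismatch_raises(self):
        ref = {"chr1": "AATACAA"}
        snv = SomaticMutation("chr1", 4, "C", "T", type="SNV")
        with pytest.raises(ValueError, match="ref"):
            context_matrix([snv], ref)

    def test_pyfaidx_fasta_input(self, tmp_path):
        pyfaidx = pytest.importorskip("pyfaidx")
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr1\nAATACAA\n")
        snv = SomaticMutation("chr1", 4, "A", "G", type="SNV")
        counts = context_matrix([snv], pyfaidx.Fasta(str(fasta)))
        assert counts[CONTEXT_CLASSES.index("G[T>C]A")] == 1


class TestRefitSignatures:
    def test_exact_single_signature(self):
        M = make_signature_matrix(4, seed=0)
        catalog = 500 * M.to_numpy()[:, 2]
        fit = refit_signatures(catalog, M)
        assert fit.contributions[2] == pytest.approx(500, rel=1e-9)
        assert np.all(np.delete(fit.contributions, 2) < 1e-9)
        assert fit.residual == pytest.approx(0, abs=1e-9)

    def test_disjoint_two_component_mixture(self):
        M = make_signature_matrix(2, seed=1, disjoint=True)
        catalog = 300 * M.to_numpy()[:, 0] + 700 * M.to_numpy()[:, 1]
        fit = refit_signatures(catalog, M)
        np.testing.assert_allclose(fit.relative, [0.3, 0.7], atol=1e-9)

    def test_scale_equivariance(self):
        M = make_signature_matrix(3, seed=2)
        catalog = 100 * M.to_numpy() @ np.array([0.2, 0.5, 0.3])
        f1 = refit_signatures(catalog, M)
        f2 = refit_signatures(2 * catalog, M)
        np.testing.assert_allclose(f2.contributions, 2 * f1.contributions, rtol=1e-8)
        np.testing.assert_allclose(f2.relative, f1.relative, atol=1e-9)

    def test_zero_catalog_flagged(self):
        M = make_signature_matrix(3, seed=0)
        fit = refit_signatures(np.zeros(96), M)
        assert fit.undefined and np.all(fit.relative == 0)

    def test_dimension_mismatch(self):
        M = make_signature_matrix(3, seed=0)
        with pytest.raises(ValueError):
            refit_signatures(np.zeros(95), M)

    def test_noisy_mixture_recovery(self, rng):
        """Multinomial sampling at n=10000 recovers weights within 0.05 MAE."""
        M = make_signature_matrix(5, seed=7)
        truth = np.array([0.4, 0.0, 0.25, 0.05, 0.3])
        counts, _ = simulate_somatic_catalog(truth, M, 10_000, rng)
        fit = refit_signatures(counts, M)
        assert np.mean(np.abs(fit.relative - truth)) < 0.05


def _chrom_table():
    return pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "length": [100_000_000, 90_000_000],
         "centromere": [48_000_000, 40_000_000]}
    )


def _diploid(chrom, start, end):
    return CnSegment("S", chrom, start, end, 2, 1)


class TestHrdScores:
    def test_empty_segments(self):
        h = hrd_scores([], _chrom_table())
        assert (h.tai, h.lst, h.loh, h.mean_hrd) == (0, 0, 0, 0)

    def test_interstitial_loh(self):
        """A 20 Mb interior LOH region counts for LOH but not TAI."""
        segs = [
            _diploid("chr1", 0, 30_000_000),
            CnSegment("S", "chr1", 30_000_000, 50_000_000, 1, 0),
            _diploid("chr1", 50_000_000, 100_000_000),
        ]
        h = hrd_scores(segs, _chrom_table())
        assert h.loh == 1 and h.tai == 0

    def test_whole_chromosome_loh_excluded(self):
        segs = [CnSegment("S", "chr1", 0, 100_000_000, 1, 0)]
        h = hrd_scores(segs, _chrom_table())
        assert h.loh == 0 and h.tai == 0

    def test_telomeric_allelic_imbalance(self):
        """A 20 Mb imbalanced region touching the p telomere, clear of the centromere."""
        segs = [
            CnSegment("S", "chr1", 0, 20_000_000, 3, 1),
            _diploid("chr1", 20_000_000, 100_000_000),
        ]
        h = hrd_scores(segs, _chrom_table())
        assert h.tai == 1

    def test_centromere_crossing_imbalance_not_tai(self):
        segs = [
            CnSegment("S", "chr1", 0, 60_000_000, 3, 1),  # spans the 48 Mb centromere
            _diploid("chr1", 60_000_000, 100_000_000),
        ]
        assert hrd_scores(segs, _chrom_table()).tai == 0

    def test_lst_breakpoint_count(self):
        # one state transition between two >=10 Mb runs on the p arm
        segs = [
            _diploid("chr1", 0, 20_000_000),
            CnSegment("S", "chr1", 20_000_000, 40_000_000, 1, 0),
            _diploid("chr1", 40_000_000, 100_000_000),
        ]
        h = hrd_scores(segs, _chrom_table())
        # transitions at 20 Mb (both sides >=10 Mb) and 40 Mb (8 Mb to centromere: no)
        assert h.lst == 1
        assert h.mean_hrd == pytest.approx((h.tai + h.lst + h.loh) / 3)

    def test_small_segment_smoothed_away_for_lst(self):
        base = [
            _diploid("chr1", 0, 20_000_000),
            CnSegment("S", "chr1", 20_000_000, 40_000_000, 1, 0),
            _diploid("chr1", 40_000_000, 100_000_000),
        ]
        with_blip = [
            _diploid("chr1", 0, 20_000_000),
            CnSegment("S", "chr1", 20_000_000, 28_000_000, 1, 0),
            CnSegment("S", "chr1", 28_000_000, 30_000_000, 3, 1),  # 2 Mb blip
            CnSegment("S", "chr1", 30_000_000, 40_000_000, 1, 0),
            _diploid("chr1", 40_000_000, 100_000_000),
        ]
        assert hrd_scores(base, _chrom_table()).lst == hrd_scores(with_blip, _chrom_table()).lst

    def test_split_segment_invariance(self):
        """Splitting any segment into same-state pieces leaves all scores unchanged."""
        merged = [
            _diploid("chr1", 0, 30_000_000),
            CnSegment("S", "chr1", 30_000_000, 50_000_000, 1, 0),
            _diploid("chr1", 50_000_000, 100_000_000),
        ]
        split = [
            _diploid("chr1", 0, 12_000_000),
            _diploid("chr1", 12_000_000, 30_000_000),
            CnSegment("S", "chr1", 30_000_000, 31_000_000, 1, 0),
            CnSegment("S", "chr1", 31_000_000, 50_000_000, 1, 0),
            _diploid("chr1", 50_000_000, 77_000_000),
            _diploid("chr1", 77_000_000, 100_000_000),
        ]
        a, b = hrd_scores(merged, _chrom_table()), hrd_scores(split, _chrom_table())
        assert (a.tai, a.lst, a.loh) == (b.tai, b.lst, b.loh)

    def test_missing_centromere_is_config_error(self):
        segs = [CnSegment("S", "chrX", 0, 1_000_000, 2, 1)]
        with pytest.raises(ValueError, match="chrX"):
            hrd_scores(segs, _chrom_table())


class TestAneuploidy:
    def test_direct_ratio(self):
        segs = [
            CnSegment("S", "chr1", 0, 13_600_000, 1, 0),
            _diploid("chr1", 13_600_000, 100_000_000),
        ]
        frac, _ = aneuploidy_fraction(segs, 100_000_000)
        assert frac == pytest.approx(0.136)

    def test_all_balanced_diploid_is_zero(self):
        frac, _ = aneuploidy_fraction([_diploid("chr1", 0, 100_000_000)], 100_000_000)
        assert frac == 0.0

    def test_cn_loh_counts_as_altered(self):
        segs = [CnSegment("S", "chr1", 0, 10_000_000, 2, 0)]
        frac, _ = aneuploidy_fraction(segs, 100_000_000)
        assert frac == pytest.approx(0.1)

    def test_gene_overlap_count(self):
        genes = pd.DataFrame(
            {
                "gene": ["GA", "GB", "GC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [1_000_000, 50_000_000, 1_000_000],
                "end": [1_200_000, 50_200_000, 1_200_000],
            }
        )
        segs = [
            CnSegment("S", "chr1", 0, 2_000_000, 1, 0),
            CnSegment("S", "chr1", 49_000_000, 51_000_000, 6, 2),
            CnSegment("S", "chr2", 5_000_000, 6_000_000, 0, 0),
        ]
        frac, n_genes = aneuploidy_fraction(segs, 190_000_000, genes)
        assert n_genes == 2
        assert frac == pytest.approx(5_000_000 / 190_000_000)

    def test_overlapping_segments_rejected(self):
        segs = [
            CnSegment("S", "chr1", 0, 2_000_000, 1, 0),
            CnSegment("S", "chr1", 1_000_000, 3_000_000, 1, 0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            aneuploidy_fraction(segs, 100_000_000)
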