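"""DAB chi-square test, BH adjustment, scans and regional confirmation."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from secondhit import (
    CohortConfig,
    DabResult,
    Direction,
    HetSnv,
    bh_adjust,
    chromosome_scan,
    confirm_dab,
    dab_test,
    scan_patient,
    simulate_cohort,
)
from secondhit.second_hit import CnSegment


def pearson_2x2(a, b, c, d):
    """Closed-form Pearson statistic n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def bh_bruteforce(pvals):
    """Step-up BH: p(i) * m / i with cumulative minimum from the largest rank."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestDabTest:
    def test_identical_proportions(self):
        chi2, p, delta = dab_test((50, 50), (50, 50))
        assert chi2 == 0.0 and p == pytest.approx(1.0) and delta == 0.0

    def test_strong_shift_matches_closed_form(self):
        chi2, p, delta = dab_test((40, 40), (10, 70))
        assert chi2 == pytest.approx(26.1818, abs=1e-3)
        assert chi2 == pytest.approx(pearson_2x2(40, 40, 10, 70))
        assert delta == pytest.approx(0.375)
        assert p < 1e-5

    def test_degenerate_single_allele_table(self):
        chi2, p, delta = dab_test((0, 100), (0, 100))
        assert chi2 == 0.0 and p == 1.0 and delta == 0.0

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError, match="depth"):
            dab_test((0, 0), (10, 10))

    def test_matches_closed_form_on_random_tables(self, rng):
        """Oracle equivalence on 1000 random tables to 1e-9."""
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 200, size=4)
            if a + b == 0 or c + d == 0:
                continue
            chi2, _, _ = dab_test((int(a), int(b)), (int(c), int(d)))
            assert abs(chi2 - pearson_2x2(a, b, c, d)) < 1e-9

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_swap_invariance_and_depth_scaling(self, a, b, c, d):
        chi2, p, delta = dab_test((a, b), (c, d))
        chi2s, ps, deltas = dab_test((b, a), (d, c))
        assert chi2s == pytest.approx(chi2, rel=1e-12, abs=1e-12)
        assert deltas == pytest.approx(-delta, abs=1e-12)
        chi2x2, _, _ = dab_test((2 * a, 2 * b), (2 * c, 2 * d))
        assert chi2x2 == pytest.approx(2 * chi2, rel=1e-9, abs=1e-9)

    def test_continuity_correction_option_reduces_statistic(self):
        plain, _, _ = dab_test((40, 40), (10, 70))
        corrected, _, _ = dab_test((40, 40), (10, 70), correction=True)
        assert 0 < corrected < plain


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(size=50))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_all_orderings(self):
        """All permutations of up to 6 p-values agree with the step-up oracle."""
        base = [0.001, 0.011, 0.02, 0.2, 0.5, 0.9]
        for k in range(1, 7):
            for perm in itertools.permutations(base[:k]):
                np.testing.assert_allclose(
                    bh_adjust(list(perm)), bh_bruteforce(list(perm)), atol=1e-12
                )

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(50):
            p = rng.uniform(size=6)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


def _null_sites(n, depth, rng, chrom="chr1"):
    sites = []
    pos = 0
    while len(sites) < n:
        pos += 1000
        dn = rng.poisson(depth)
        dt = rng.poisson(depth)
        if dn < 2 or dt < 2:
            continue
        an = rng.binomial(dn, 0.5)
        if an in (0, dn):
            continue
        at = rng.binomial(dt, 0.5)
        sites.append(HetSnv(chrom, pos, (dn - an, an), (dt - at, at)))
    return sites


class TestScan:
    def test_null_scan_fdr_controlled(self, rng):
        """Under the global null (purity 0) almost no adjusted p < 0.05."""
        sites = _null_sites(1000, 100, rng)
        results = scan_patient(sites)
        frac_adj = np.mean([r.p_adj < 0.05 for r in results])
        assert frac_adj <= 0.01
        assert all(r.direction is Direction.NONE for r in results if r.p_adj >= 0.05)

    def test_raw_type_i_calibration(self, rng):
        sites = _null_sites(1000, 100, rng)
        results = scan_patient(sites)
        frac_raw = np.mean([r.p_raw < 0.05 for r in results])
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac_raw - 0.05) < 3 * se

    def test_planted_loh_arm_mostly_significant(self, rng):
        """A copy-neutral LOH arm at purity 0.8 and depth 200 lights up."""
        sites = []
        pos = 0
        for _ in range(200):
            pos += 100_000
            dn, dt = rng.poisson(200), rng.poisson(200)
            an = rng.binomial(dn, 0.5)
            if an in (0, dn):
                continue
            p_alt = 0.9 if rng.random() < 0.5 else 0.1  # unknown phase
            at = rng.binomial(dt, p_alt)
            sites.append(HetSnv("chr1", pos, (dn - an, an), (dt - at, at)))
        sites += _null_sites(200, 200, rng, chrom="chr2")
        results = [r for r in scan_patient(sites) if r.chrom == "chr1"]
        assert np.mean([r.p_adj < 0.05 for r in results]) > 0.9

    def test_single_site_equals_plain_test(self):
        s = HetSnv("chr1", 10, (40, 40), (10, 70))
        [r] = scan_patient([s])
        chi2, p, delta = dab_test((40, 40), (10, 70))
        assert r.chi2 == pytest.approx(chi2) and r.p_adj == pytest.approx(p)
        assert r.delta_ab == pytest.approx(delta)

    def test_chromosome_scan_is_patient_family_view(self, rng):
        sites = _null_sites(50, 100, rng, "chr1") + _null_sites(50, 100, rng, "chr2")
        full = scan_patient(sites)
        chr1 = chromosome_scan(sites, "chr1")
        assert [(r.pos, r.p_adj) for r in chr1] == [
            (r.pos, r.p_adj) for r in full if r.chrom == "chr1"
        ]

    def test_per_chromosome_family_option(self, rng):
        sites = _null_sites(20, 100, rng, "chr1") + _null_sites(20, 100, rng, "chr2")
        res = scan_patient(sites, bh_family="chromosome")
        chr1_p = [r.p_raw for r in res if r.chrom == "chr1"]
        np.testing.assert_allclose(
            [r.p_adj for r in res if r.chrom == "chr1"], bh_adjust(chr1_p)
        )

    def test_low_depth_flagged(self):
        s = HetSnv("chr1", 10, (40, 40), (4, 3))
        [r] = scan_patient([s])
        assert r.low_depth


def _result(pos, p_adj, delta, chrom="chr1"):
    return DabResult(chrom=chrom, pos=pos, chi2=10.0, p_raw=p_adj, p_adj=p_adj,
                     delta_ab=delta)


class TestConfirmDab:
    def test_confirmed_on_loh_segment(self):
        seg = [CnSegment("S", "chr1", 0, 10_000_000, 1, 0)]
        var = _result(5_000_000, 0.001, 0.3)
        neighbors = [_result(1_000_000 * i, 0.001, 0.28) for i in range(1, 10)]
        conf = confirm_dab(var, neighbors, seg)
        assert conf.confirmed and not conf.used_window

    def test_isolated_significant_site_unconfirmed(self):
        seg = [CnSegment("S", "chr1", 0, 10_000_000, 2, 1)]
        var = _result(5_000_000, 0.001, 0.3)
        neighbors = [_result(1_000_000 * i, 0.9, 0.01) for i in range(1, 10)]
        conf = confirm_dab(var, neighbors, seg)
        assert not conf.confirmed and not conf.insufficient_neighbors

    def test_zero_neighbors_flagged_insufficient(self):
        seg = [CnSegment("S", "chr1", 0, 10_000_000, 1, 0)]
        var = _result(5_000_000, 0.001, 0.3)
        conf = confirm_dab(var, [], seg)
        assert not conf.confirmed and conf.insufficient_neighbors

    def test_window_fallback_without_segments(self):
        var = _result(5_000_000, 0.001, 0.3)
        near = [_result(5_000_000 + 100_000 * i, 0.001, 0.3) for i in (1, 2, 3)]
        far = [_result(50_000_000, 0.001, 0.3)]
        conf = confirm_dab(var, near + far, segments=None)
        assert conf.confirmed and conf.used_window and conf.n_neighbors == 3

    def test_neighbor_magnitude_not_sign(self):
        """Neighbors confirm via |delta|: opposite-phase backbone SNVs still count."""
        seg = [CnSegment("S", "chr1", 0, 10_000_000, 2, 0)]
        var = _result(5_000_000, 0.001, 0.4)
        neighbors = [_result(1_000_000 * i, 0.001, -0.35) for i in range(1, 5)]
        assert confirm_dab(var, neighbors, seg).confirmed
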