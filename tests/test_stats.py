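import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegecg.stats import (
    bh_fdr,
    cohens_d_from_t,
    effect_label,
    paired_compare,
    perm_maxstat_corr,
    perm_maxstat_paired,
    power_sample_size,
    rank_biserial,
    sample_size_with_margin,
    shapiro_normality,
    t_p_value,
    tier_of,
    wilcoxon_p,
)


class TestPrintedStatistics:
    """Worked-example values that are pure functions of printed inputs."""

    def test_t_to_p(self):
        assert t_p_value(2.06, 30) == pytest.approx(0.048, abs=5e-4)
        assert t_p_value(0.0, 17) == 1.0
        # textbook two-sided critical value at df = 30
        assert t_p_value(2.042, 30) == pytest.approx(0.050, abs=5e-4)

    def test_t_to_cohens_d(self):
        assert cohens_d_from_t(2.06, 31) == pytest.approx(0.37, abs=5e-3)
        assert cohens_d_from_t(0.0, 31) == 0.0

    def test_rank_biserial(self):
        assert rank_biserial(358.5, 31) == pytest.approx(0.45, abs=5e-3)
        S = 31 * 32 / 2
        assert rank_biserial(S, 31) == 1.0
        assert rank_biserial(S / 2, 31) == 0.0

    def test_wilcoxon_continuity_corrected(self):
        assert wilcoxon_p(358.5, 31) == pytest.approx(0.031, abs=5e-4)
        assert wilcoxon_p(31 * 32 / 4, 31) == 1.0  # null centre, capped

    def test_power_sample_sizes(self):
        assert power_sample_size(0.5) == 32
        assert power_sample_size(1.0) == 8  # ceil(7.849)
        assert sample_size_with_margin(32) == 34
        assert power_sample_size(0.5, mode="exact") == 34

    def test_d_from_t_equals_direct_formula(self, rng):
        diff = rng.normal(0.3, 1.0, 25)
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(25))
        assert cohens_d_from_t(t, 25) == pytest.approx(
            diff.mean() / diff.std(ddof=1), rel=1e-12
        )


class TestWilcoxonExact:
    def test_exact_matches_brute_force_enumeration(self):
        n = 10
        ranks = np.arange(1, n + 1)
        # distribution of W over all 2^10 sign assignments
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        ws = np.array(ws)
        total = 2.0**n
        S = n * (n + 1) / 2
        for W in (5, 12, 27.0, 40, 55):
            lo = min(W, S - W)
            brute = 2 * np.sum(ws <= lo) / total
            assert wilcoxon_p(W, n, mode="exact") == pytest.approx(min(brute, 1.0), rel=1e-12)

    @given(st.integers(0, 210))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, w):
        n = 20
        S = n * (n + 1) / 2
        for mode in ("exact", "approx"):
            assert wilcoxon_p(w, n, mode=mode) == pytest.approx(
                wilcoxon_p(S - w, n, mode=mode), rel=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_p(500.0, 10)


class TestShapiro:
    def test_uniform_p_under_normality(self):
        ps = [
            shapiro_normality(np.random.default_rng(s).normal(size=31))
            for s in range(200)
        ]
        from scipy import stats as sps

        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_heavy_skew(self):
        rejected = sum(
            shapiro_normality(np.exp(np.random.default_rng(s).normal(size=31))) < 0.05
            for s in range(100)
        )
        assert rejected >= 90

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            shapiro_normality(np.full(10, 1.0))


class TestPairedCompare:
    def test_shifted_normal_routes_to_t_with_matching_sign(self, rng):
        x = rng.normal(size=30)
        y = x - 0.8 + rng.normal(0, 0.3, 30)
        res = paired_compare(x, y)
        assert res.method == "paired_t"
        assert res.statistic > 0 and res.effect > 0
        assert res.tier == "significant"

    def test_identical_samples_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="zero"):
            paired_compare(x, x)

    def test_skewed_differences_route_to_wilcoxon(self, rng):
        x = np.exp(rng.normal(size=40) * 2)
        y = np.zeros(40)
        res = paired_compare(x, y)
        assert res.method == "wilcoxon"
        assert res.effect_type == "r"
        assert res.effect == 1.0  # all differences positive

    def test_tier_and_effect_labels(self):
        assert tier_of(0.049) == "significant"
        assert tier_of(0.05) == "trend"  # half-open boundary convention
        assert tier_of(0.0999) == "trend"
        assert tier_of(0.10) == "ns"
        assert effect_label(0.79, "d") == "medium"
        assert effect_label(0.8, "d") == "large"
        assert effect_label(-0.35, "r") == "medium"
        assert effect_label(0.05, "r") == "none"


class TestBhFdr:
    def test_hand_applied_step_up(self):
        cmap = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.2], q=0.05)
        assert list(cmap.significant) == [True, True, True, True, False]
        # step-up adjusted values computed by hand:
        # sorted p * m/k = (.05, .05, .05, .05, .2); monotone from the top
        np.testing.assert_allclose(cmap.p_corrected, [0.05, 0.05, 0.05, 0.05, 0.2])

    def test_all_ones(self):
        cmap = bh_fdr([1.0, 1.0, 1.0])
        assert not cmap.significant.any()
        np.testing.assert_allclose(cmap.p_corrected, 1.0)

    def test_single_p_identity(self):
        cmap = bh_fdr([0.037])
        assert cmap.p_corrected[0] == pytest.approx(0.037)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_rank_and_nested_rejections(self, ps):
        cmap = bh_fdr(ps, q=0.05)
        order = np.argsort(ps)
        adj_sorted = cmap.p_corrected[order]
        assert np.all(np.diff(adj_sorted) >= -1e-12)
        strict = bh_fdr(ps, q=0.01)
        assert set(np.nonzero(strict.significant)[0]) <= set(
            np.nonzero(cmap.significant)[0]
        )


class TestPermMaxstatPaired:
    def test_identical_maps_give_p_one(self, rng):
        maps = rng.normal(size=(8, 5))
        cmap = perm_maxstat_paired(maps, maps.copy(), n_perm=200, seed=0)
        np.testing.assert_allclose(cmap.p_corrected, 1.0)

    def test_exhaustive_enumeration_matches_monte_carlo(self, rng):
        A = rng.normal(0.8, 1.0, size=(6, 4))
        B = rng.normal(0.0, 1.0, size=(6, 4))
        exact = perm_maxstat_paired(A, B, exhaustive=True)
        mc = perm_maxstat_paired(A, B, n_perm=5000, seed=1)
        np.testing.assert_allclose(mc.p_corrected, exact.p_corrected, atol=0.02)

    def test_single_site_reduces_to_sign_flip_test(self, rng):
        A = rng.normal(0.5, 1.0, size=(10, 1))
        B = rng.normal(0.0, 1.0, size=(10, 1))
        cmap = perm_maxstat_paired(A, B, exhaustive=True)
        # oracle: direct enumeration of the sign-flip t distribution
        diff = (A - B)[:, 0]
        t_obs = abs(diff.mean() / (diff.std(ddof=1) / np.sqrt(10)))
        count = 0
        for signs in itertools.product([-1.0, 1.0], repeat=10):
            d = diff * np.array(signs)
            t = abs(d.mean() / (d.std(ddof=1) / np.sqrt(10)))
            count += t >= t_obs - 1e-12
        assert cmap.p_corrected[0] == pytest.approx(count / 2**10, rel=1e-9)

    def test_corrected_p_bounds(self, rng):
        A = rng.normal(1.5, 1.0, size=(12, 6))
        B = rng.normal(0.0, 1.0, size=(12, 6))
        cmap = perm_maxstat_paired(A, B, n_perm=500, seed=2)
        assert np.all(cmap.p_corrected >= 1.0 / 501.0)
        assert np.all(cmap.p_corrected >= cmap.p_raw - 1e-12)

    def test_degenerate_site_flagged(self, rng):
        A = rng.normal(size=(8, 3))
        B = A + rng.normal(0, 1, size=(8, 3))
        B[:, 1] = A[:, 1] - 2.0  # constant difference: zero variance at site b
        cmap = perm_maxstat_paired(A, B, n_perm=100, seed=0, sites=("a", "b", "c"))
        assert tuple(cmap.degenerate) == ("b",)


class TestPermMaxstatCorr:
    def test_perfect_correlation_hits_floor(self, rng):
        maps = rng.normal(size=(12, 5))
        index = maps[:, 2].copy()
        cmap = perm_maxstat_corr(index, maps, n_perm=999, seed=3)
        assert cmap.p_corrected[2] == pytest.approx(1.0 / 1000.0)
        assert cmap.raw_stat[2] == pytest.approx(1.0)

    def test_sign_flip_negates_correlations_same_p(self, rng):
        maps = rng.normal(size=(10, 4))
        index = rng.normal(size=10)
        a = perm_maxstat_corr(index, maps, n_perm=300, seed=4)
        b = perm_maxstat_corr(-index, maps, n_perm=300, seed=4)
        np.testing.assert_allclose(b.raw_stat, -a.raw_stat, rtol=1e-9)
        np.testing.assert_allclose(b.p_corrected, a.p_corrected)

    def test_constant_index_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            perm_maxstat_corr(np.ones(8), rng.normal(size=(8, 3)), n_perm=10, seed=0)


class TestPowerSampleSize:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(0.0)
        with pytest.raises(ValueError):
            power_sample_size(0.5, alpha=1.5)
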