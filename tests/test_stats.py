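import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conemosaic.stats import (
    bland_altman,
    friedman_test,
    holm_bonferroni,
    icc_2way_random_single_absolute,
    wilcoxon_signed_rank,
)


def brute_force_icc21(x):
    """ICC(2,1) assembled from explicit sums of squares (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i].sum() / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].sum() / n - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_identity_gives_zero_everything(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = bland_altman(a, a)
        assert (r.mean_diff, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)
        assert r.sd_diff == 0.0 and r.prop_bias_slope == 0.0

    def test_hand_computed_differences(self):
        # d = [1, 2, 3]: mean 2, sd 1, limits 2 ± 1.96
        r = bland_altman(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert r.mean_diff == pytest.approx(2.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(0.04)
        assert r.loa_high == pytest.approx(3.96)

    def test_constant_offset(self):
        b = np.array([1.0, 5.0, 9.0, 2.0])
        r = bland_altman(b + 3.0, b)
        assert r.mean_diff == pytest.approx(3.0) and r.sd_diff == 0.0

    def test_limits_cover_95pct_of_normal_differences(self):
        rng = np.random.default_rng(4)
        b = rng.normal(100, 10, 4000)
        a = b + rng.normal(0, 2, 4000)
        r = bland_altman(a, b)
        inside = np.mean((a - b >= r.loa_low) & (a - b <= r.loa_high))
        assert inside == pytest.approx(0.95, abs=0.015)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        c = np.full(5, 3.0)
        with pytest.raises(ValueError):
            bland_altman(c, c)  # zero variance in pairwise means


class TestICC:
    def test_identical_sessions_give_exactly_one(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        r = icc_2way_random_single_absolute(x)
        assert r.icc == 1.0 and r.ci_low == 1.0 and r.ci_high == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_anova(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(4, 20), rng.integers(2, 5)
        x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.5, (n, 1))
        r = icc_2way_random_single_absolute(x)
        assert r.icc == pytest.approx(brute_force_icc21(x), abs=1e-10)
        assert r.ci_low <= r.icc <= r.ci_high

    def test_near_zero_under_null(self):
        rng = np.random.default_rng(12)
        vals = [icc_2way_random_single_absolute(rng.normal(size=(50, 2))).icc for _ in range(20)]
        assert abs(np.mean(vals)) < 0.3

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, (8, 3))
        base = icc_2way_random_single_absolute(x).icc
        assert icc_2way_random_single_absolute(x + 100.0).icc == pytest.approx(base, abs=1e-9)
        assert icc_2way_random_single_absolute(x * 7.0).icc == pytest.approx(base, abs=1e-9)

    def test_incomplete_table_rejected(self):
        x = np.ones((4, 2))
        x[1, 1] = np.nan
        with pytest.raises(ValueError):
            icc_2way_random_single_absolute(x)


class TestFriedman:
    def test_all_tied_blocks_give_zero_statistic(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 4))  # each block constant
        r = friedman_test(x)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_perfect_ordering_closed_form(self):
        n, k = 8, 4
        x = np.tile(np.arange(1.0, k + 1), (n, 1)) + np.arange(n)[:, None] * 10
        r = friedman_test(x)
        expected = 12.0 * n / (k * (k + 1)) * sum((j - (k + 1) / 2) ** 2 for j in range(1, k + 1))
        assert r.statistic == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=(12, 4)).astype(float)
        mine = friedman_test(x)
        stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(4)])
        assert mine.statistic == pytest.approx(stat, rel=1e-10)
        assert mine.p_value == pytest.approx(p, rel=1e-10)


class TestWilcoxon:
    def test_all_positive_small_sample_exact(self):
        # d = [1..6], all positive: W = 0, p = 2/2^6
        r = wilcoxon_signed_rank(np.arange(1.0, 7.0), np.zeros(6))
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 64)
        assert r.method == "wilcoxon-exact"

    def test_antisymmetric_differences_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        r = wilcoxon_signed_rank(x, np.zeros(6))
        assert r.p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, x)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=14), rng.normal(size=14)
        mine = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, method="exact")
        assert mine.statistic == pytest.approx(float(ref.statistic))
        assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_normal_approx_matches_scipy_on_tied_data(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 10, 40).astype(float)
        b = rng.integers(0, 10, 40).astype(float)
        mask = a != b
        mine = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a[mask], b[mask], zero_method="wilcox", correction=True, method="approx")
        assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestHolm:
    def test_hand_examples(self):
        rej, _ = holm_bonferroni([0.01, 0.02, 0.03], alpha=0.05)
        assert rej == [True, True, True]
        rej2, _ = holm_bonferroni([0.04, 0.04], alpha=0.05)
        assert rej2 == [False, False]
        rej3, _ = holm_bonferroni([0.5], alpha=0.05)
        assert rej3 == [False]

    def test_empty_input_is_noop(self):
        assert holm_bonferroni([], alpha=0.05) == ([], [])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(12)
        rej, adj = holm_bonferroni(p, 0.05)
        srej, sadj, _, _ = multipletests(p, 0.05, method="holm")
        assert np.allclose(adj, sadj) and list(rej) == list(srej)

    @settings(deadline=None, max_examples=80)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_sandwiched_between_bonferroni_and_unadjusted(self, pvals):
        alpha = 0.05
        m = len(pvals)
        holm_rej, _ = holm_bonferroni(pvals, alpha)
        bonf = [p <= alpha / m for p in pvals]
        unadj = [p <= alpha for p in pvals]
        for b, h, u in zip(bonf, holm_rej, unadj):
            assert (not b) or h  # bonferroni rejections ⊆ holm
            assert (not h) or u  # holm rejections ⊆ unadjusted
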