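"""Rank-sum, Hodges-Lehmann, FDR and formula kernels against independent
oracles (brute-force enumeration, scipy, statsmodels, hand calculation)."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from atrace.stats import (adjust_pvalues, exact_u_pmf, fraction_diluted,
                          hodges_lehmann, quantify_standard_curve,
                          wilcoxon_ranksum)


def brute_force_u_pmf(n1, n2):
    """Enumerate all C(n1+n2, n1) rank assignments explicitly."""
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1)
    for sub in itertools.combinations(range(1, n + 1), n1):
        counts[sum(sub) - n1 * (n1 + 1) // 2] += 1
    return counts / counts.sum()


class TestExactRankSum:
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 2),
                                       (5, 5), (6, 6), (5, 4)])
    def test_pmf_equals_full_enumeration(self, n1, n2):
        np.testing.assert_allclose(exact_u_pmf(n1, n2),
                                   brute_force_u_pmf(n1, n2), atol=1e-12)

    def test_complete_separation_5v5_prints_0_008(self):
        """All-x-below-all-y at n=5 vs 5: exact two-sided p = 2/252."""
        res = wilcoxon_ranksum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 252)
        assert round(res.p, 3) == 0.008

    def test_complete_separation_5v4_prints_0_016(self):
        res = wilcoxon_ranksum([1, 2, 3, 4, 5], [6, 7, 8, 9])
        assert res.p == pytest.approx(2 / 126)
        assert round(res.p, 3) == 0.016

    def test_single_pair_tie_gives_p_1(self):
        assert wilcoxon_ranksum([1.0], [1.0]).p == 1.0

    def test_2v2_separation(self):
        assert wilcoxon_ranksum([1, 2], [3, 4]).p == pytest.approx(2 / 6)

    def test_exact_matches_scipy_on_random_tie_free_data(self):
        r = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = r.integers(1, 7, 2)
            x, y = r.normal(size=n1), r.normal(size=n2)
            mine = wilcoxon_ranksum(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, method="exact")
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.u == pytest.approx(ref.statistic)

    def test_one_sided_alternatives_sum_properly(self):
        x, y = [1, 2, 3], [4, 5, 6, 7]
        g = wilcoxon_ranksum(x, y, alternative="greater").p
        l = wilcoxon_ranksum(x, y, alternative="less").p
        # exact one-sided tails overlap in exactly one atom of the pmf
        pmf = exact_u_pmf(3, 4)
        assert g + l == pytest.approx(1 + pmf[0])

    def test_approx_close_to_exact_at_n12(self):
        r = np.random.default_rng(3)
        x, y = r.normal(size=12), r.normal(size=12)
        pe = wilcoxon_ranksum(x, y, mode="exact").p
        pa = wilcoxon_ranksum(x, y, mode="approx").p
        assert abs(pe - pa) < 0.01

    def test_exact_mode_refuses_ties(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_ranksum([1, 1, 2], [2, 3], mode="exact")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])

    def test_tied_data_uses_midranks_and_approx(self):
        res = wilcoxon_ranksum([1, 1, 2, 2], [2, 3, 3, 4])
        assert res.method == "approx"
        ref = sps.mannwhitneyu([1, 1, 2, 2], [2, 3, 3, 4], method="asymptotic")
        assert res.u == pytest.approx(ref.statistic)


class TestHodgesLehmann:
    def test_hand_enumerated_estimate(self):
        # pairwise diffs of {1,2} - {0,1} are {1, 0, 2, 1}; median 1
        assert hodges_lehmann([1, 2], [0, 1]).estimate == pytest.approx(1.0)

    def test_identical_samples_estimate_zero(self):
        x = [3.0, 1.0, 2.0]
        assert hodges_lehmann(x, x).estimate == pytest.approx(0.0)

    def test_shift_equivariance(self):
        r = np.random.default_rng(5)
        x, y = r.normal(size=8), r.normal(size=9)
        base = hodges_lehmann(x, y)
        shifted = hodges_lehmann(x + 2.5, y)
        assert shifted.estimate == pytest.approx(base.estimate + 2.5)
        assert shifted.conf_low == pytest.approx(base.conf_low + 2.5)

    def test_estimate_inside_interval(self):
        r = np.random.default_rng(6)
        for _ in range(20):
            x, y = r.normal(size=7), r.normal(1, 1, size=5)
            hl = hodges_lehmann(x, y)
            assert hl.conf_low <= hl.estimate <= hl.conf_high

    def test_interval_shrinks_with_n(self):
        r = np.random.default_rng(7)
        widths = []
        for n in (5, 20, 40):
            w = [hodges_lehmann(r.normal(size=n), r.normal(size=n)).conf_high
                 - hodges_lehmann(r.normal(size=n), r.normal(size=n)).conf_low
                 for _ in range(10)]
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_matches_r_style_achieved_level(self):
        hl = hodges_lehmann([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert hl.method == "exact"
        assert hl.achieved_level is not None
        assert 0.9 <= hl.achieved_level <= 1.0


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        # p_(i) * m / i = {0.04, 0.04, 0.04, 0.04}; cumulative min 0.04
        adj = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        np.testing.assert_allclose(adj, [0.04] * 4)

    def test_bonferroni_single_p_unchanged(self):
        assert adjust_pvalues([0.03], "bonferroni")[0] == pytest.approx(0.03)

    def test_bonferroni_is_direct_multiplication(self):
        r = np.random.default_rng(8)
        p = r.uniform(size=50)
        np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"),
                                   np.minimum(1, p * 50))

    def test_bky_worked_example_rejects_three(self):
        res = adjust_pvalues([0.001, 0.01, 0.02, 0.2], "bky_two_stage", q=0.05)
        assert res.n_rejected == 3
        assert res.q_stage1 == pytest.approx(0.05 / 1.05)
        assert res.q_stage2 == pytest.approx(0.05 / 1.05 * 4 / 1)
        np.testing.assert_array_equal(res.reject, [True, True, True, False])

    def test_bky_agrees_with_statsmodels_two_stage(self):
        r = np.random.default_rng(9)
        for _ in range(20):
            p = np.concatenate([r.uniform(0, 0.01, 5), r.uniform(size=30)])
            mine = adjust_pvalues(p, "bky_two_stage", q=0.05).reject
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_bky_rejections_contain_bh_rejections_under_signal(self):
        # the adaptive stage raises the working level whenever stage 1
        # finds enough signal, so BKY rejects a superset of BH there
        r = np.random.default_rng(10)
        for _ in range(50):
            p = np.concatenate([r.uniform(0, 1e-3, 8), r.uniform(size=32)])
            bky = adjust_pvalues(p, "bky_two_stage", q=0.05).reject
            bh = adjust_pvalues(p, "bh") <= 0.05
            assert (bky | ~bh).all()

    def test_bh_adjustment_equals_step_up_rejection(self):
        r = np.random.default_rng(11)
        p = r.uniform(size=60)
        adj = adjust_pvalues(p, "bh")
        for q in (0.01, 0.05, 0.2):
            srt = np.sort(p)
            k = np.where(srt <= (np.arange(1, 61) / 60) * q)[0]
            reject_direct = p <= (srt[k[-1]] if k.size else -1)
            np.testing.assert_array_equal(adj <= q, reject_direct)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")


class TestFractionDiluted:
    @pytest.mark.parametrize("profile,expected", [
        ([100, 0, 0], 0.0),
        ([0, 100], 1.0),
        ([50, 50], 1 / 3),          # (50/2) / (50 + 50/2)
        ([0, 0, 0, 8], 1.0),
        ([10, 10, 10], 0.4285714285714286),
    ])
    def test_formula(self, profile, expected):
        assert fraction_diluted(profile) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert fraction_diluted([3, 5, 7]) == pytest.approx(
            fraction_diluted([30, 50, 70]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fraction_diluted([0, 0])


class TestStandardCurve:
    def test_perfect_linear_inversion(self):
        curve, q, _, ex = quantify_standard_curve(
            [(6, 20.0), (5, 23.32), (4, 26.64)], [23.32])
        assert curve.slope == pytest.approx(-3.32)
        assert q[0] == pytest.approx(1e5, rel=1e-9)
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.32) - 1)
        assert curve.r_squared == pytest.approx(1.0)
        assert not ex[0]

    def test_protein_normalization_and_extrapolation_flag(self):
        _, q, normd, ex = quantify_standard_curve(
            [(6, 20.0), (5, 23.32), (4, 26.64)], [19.0, 25.0], [2.0, 4.0])
        assert normd[0] == pytest.approx(q[0] / 2.0)
        assert ex[0] and not ex[1]  # Cq 19 below the standards' range

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="dilution"):
            quantify_standard_curve([(4, 20.0), (5, 23.0), (6, 26.0)], [22.0])

    def test_narrow_range_rejected(self):
        with pytest.raises(ValueError):
            quantify_standard_curve([(5.0, 20), (5.5, 21), (5.9, 22)], [21.0])
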