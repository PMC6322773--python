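"""Percentage-error statistics, imputation and paired comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tapeweight.accuracy import (
    InsufficientDataError,
    compare_within_threshold,
    difference_summary,
    impute_p_within,
    mcnemar,
    paired_odds_ratio,
    paired_t,
    percentage_error,
    summarize,
)


class TestPercentageError:
    @pytest.mark.parametrize("est,actual,expected", [
        (10.0, 10.0, 0.0), (11.0, 10.0, 10.0), (8.0, 10.0, -20.0),
    ])
    def test_signed_formula(self, est, actual, expected):
        assert percentage_error(est, actual) == pytest.approx(expected)

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ValueError):
            percentage_error(10.0, 0.0)


class TestSummarize:
    def test_all_zero_errors(self):
        s = summarize([0.0, 0.0, 0.0, 0.0])
        assert (s.mpe, s.sd, s.loa_low, s.loa_high, s.rmspe) == (0, 0, 0, 0, 0)
        assert s.p10 == 100.0 and s.p20 == 100.0 and s.n == 4

    def test_symmetric_pair(self):
        s = summarize([-10.0, 10.0])
        assert s.mpe == pytest.approx(0.0)
        assert s.rmspe == pytest.approx(10.0)
        assert s.p10 == 100.0

    def test_large_normal_sample_matches_analytic(self):
        rng = np.random.default_rng(5)
        pe = rng.normal(2.0, 8.0, size=100_000)
        s = summarize(pe)
        assert s.mpe == pytest.approx(2.0, abs=0.1)
        assert s.loa_low == pytest.approx(2.0 - 1.96 * 8.0, abs=0.2)
        assert s.loa_high == pytest.approx(2.0 + 1.96 * 8.0, abs=0.2)
        assert s.p10 == pytest.approx(impute_p_within(2.0, -13.68, 17.68, 10.0), abs=0.5)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-60, 60), min_size=2, max_size=50), st.integers(0, 2**31 - 1))
    def test_internal_identities(self, pe, _seed):
        s = summarize(pe)
        assert s.loa_low == pytest.approx(s.mpe - 1.96 * s.sd)
        assert s.loa_high == pytest.approx(s.mpe + 1.96 * s.sd)
        assert s.rmspe >= abs(s.mpe) - 1e-12
        assert 0.0 <= s.p10 <= s.p20 <= 100.0


class TestImputation:
    def test_published_subgroup_rows_reproduced(self):
        # light-weight subgroup: MPE -1.6, LOA (-23.2, 19.9)
        assert round(impute_p_within(-1.6, -23.2, 19.9, 10.0), 1) == 63.2
        assert round(impute_p_within(-1.6, -23.2, 19.9, 20.0), 1) == 92.8
        # heavier subgroup: MPE 0.2, LOA (-18.5, 18.9)
        assert round(impute_p_within(0.2, -18.5, 18.9, 10.0), 1) == 70.5
        assert round(impute_p_within(0.2, -18.5, 18.9, 20.0), 1) == 96.4

    @pytest.mark.parametrize("sigma,threshold", [(5.0, 10.0), (8.0, 10.0), (12.0, 20.0)])
    def test_zero_bias_matches_quadrature(self, sigma, threshold):
        loa = 1.96 * sigma
        expected, _ = integrate.quad(
            lambda x: stats.norm.pdf(x, 0.0, sigma), -threshold, threshold
        )
        assert impute_p_within(0.0, -loa, loa, threshold) == pytest.approx(100 * expected, abs=1e-8)
        # closed form for the symmetric case
        assert impute_p_within(0.0, -loa, loa, threshold) == pytest.approx(
            100 * (2 * stats.norm.cdf(threshold / sigma) - 1)
        )

    def test_monotone_in_threshold_and_sigma(self):
        p = [impute_p_within(1.0, -19.6, 21.6, t) for t in (5.0, 10.0, 20.0, 30.0)]
        assert p == sorted(p)
        sig = [impute_p_within(1.0, 1.0 - 1.96 * s, 1.0 + 1.96 * s, 10.0)
               for s in (4.0, 8.0, 16.0)]
        assert sig == sorted(sig, reverse=True)

    def test_degenerate_loa_rejected(self):
        with pytest.raises(ValueError):
            impute_p_within(0.0, 5.0, 5.0, 10.0)


def _exact_mcnemar_oracle(b, c):
    """Brute-force two-sided binomial tail sum at p = 1/2."""
    m = b + c
    k = min(b, c)
    pmf = [math.comb(m, i) * 0.5 ** m for i in range(m + 1)]
    return min(1.0, 2.0 * sum(pmf[: k + 1]))


class TestMcNemar:
    def test_symmetric_counts_give_p_one(self):
        assert mcnemar(7, 7).p_value == pytest.approx(1.0)

    def test_corrected_chi_square_statistic(self):
        res = mcnemar(30, 10)
        assert not res.exact
        assert res.statistic == pytest.approx((abs(20) - 1) ** 2 / 40)  # 9.025
        assert res.p_value == pytest.approx(stats.chi2.sf(9.025, 1))

    @pytest.mark.parametrize("b,c", [(0, 5), (1, 3), (2, 18), (10, 10), (4, 16), (20, 0)])
    def test_exact_p_equals_enumeration(self, b, c):
        res = mcnemar(b, c)
        assert res.exact
        assert res.p_value == pytest.approx(_exact_mcnemar_oracle(b, c), abs=1e-12)

    def test_exact_exhaustive_small_tables(self):
        for m in range(1, 21):
            for b in range(m + 1):
                assert mcnemar(b, m - b).p_value == pytest.approx(
                    _exact_mcnemar_oracle(b, m - b), abs=1e-12
                )

    def test_symmetry_in_counts(self):
        for b, c in [(3, 9), (1, 20), (40, 15)]:
            assert mcnemar(b, c).p_value == pytest.approx(mcnemar(c, b).p_value)

    def test_matches_independent_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(3, 9), (12, 5), (60, 40)]:
            ours = mcnemar(b, c)
            table = [[0, b], [c, 0]]
            theirs = sm.mcnemar(table, exact=ours.exact, correction=True)
            assert ours.p_value == pytest.approx(float(theirs.pvalue), abs=1e-10)

    def test_no_discordant_pairs_undefined(self):
        with pytest.raises(InsufficientDataError):
            mcnemar(0, 0)


class TestOddsRatio:
    def test_equal_counts_give_unity(self):
        assert paired_odds_ratio(12, 12).odds_ratio == pytest.approx(1.0)

    def test_wald_interval_formula(self):
        res = paired_odds_ratio(40, 10)
        assert res.odds_ratio == pytest.approx(4.0)
        se = math.sqrt(1 / 40 + 1 / 10)
        assert res.ci_low == pytest.approx(math.exp(math.log(4.0) - 1.96 * se))
        assert res.ci_high == pytest.approx(math.exp(math.log(4.0) + 1.96 * se))

    @settings(max_examples=100, derandomize=True)
    @given(b=st.integers(1, 500), c=st.integers(1, 500))
    def test_interval_matches_log_scale_recomputation(self, b, c):
        res = paired_odds_ratio(b, c)
        log_or = math.log(b / c)
        se = math.sqrt(1 / b + 1 / c)
        assert math.log(res.ci_low) == pytest.approx(log_or - 1.96 * se)
        assert math.log(res.ci_high) == pytest.approx(log_or + 1.96 * se)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_zero_cell_continuity_corrected(self):
        res = paired_odds_ratio(5, 0)
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx(5.5 / 0.5)


class TestPairedT:
    def test_identical_samples_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 0.0 and res.t == np.inf

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        a = rng.normal(2, 5, size=20)
        b = rng.normal(0, 5, size=20)
        res = paired_t(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        assert res.t == pytest.approx(t_hand)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_hand), 19))


class TestDifferenceSummary:
    def test_no_difference(self):
        d = difference_summary(50.0, 50.0)
        assert d.absolute == 0.0 and d.relative == 0.0

    @pytest.mark.parametrize("p_a,p_b,rel", [(79.3, 55.5, 43), (79.3, 67.4, 18), (79.3, 64.3, 23)])
    def test_headline_relative_contrasts(self, p_a, p_b, rel):
        assert difference_summary(p_a, p_b).relative_rounded == rel

    def test_zero_denominator_undefined(self):
        assert difference_summary(10.0, 0.0).relative is None


class TestCompareWithinThreshold:
    def test_discordant_counts_and_flags(self):
        a = np.array([True, True, True, False, False])
        b = np.array([True, False, False, True, False])
        res = compare_within_threshold(a, b, metric="p10", method_a="A", method_b="B")
        assert (res.b, res.c) == (2, 1)
        assert res.value_a == pytest.approx(60.0) and res.value_b == pytest.approx(40.0)
        assert res.clinically_important  # 20-point gap

    def test_no_discordance_is_null_not_error(self):
        a = np.array([True, False, True])
        res = compare_within_threshold(a, a, metric="p10", method_a="A", method_b="A")
        assert res.degenerate and res.p_value == 1.0 and res.odds_ratio == 1.0
        assert not res.significant
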