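"""Agreement statistics: CCC, gold-standard coefficient, Bland-Altman, tests.

The concordance coefficient is checked against a definition-level moment
oracle coded from scratch in this file (explicit Python loops over the
moment definitions), so the vectorised implementation and the oracle share
no code path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sfconcord.agreement import (
    AgreementError,
    PairedSample,
    bland_altman,
    descriptive_summary,
    icc_sample_size,
    lin_ccc,
    paired_difference_test,
    pearson_r,
    st_laurent,
    st_laurent_coefficient,
)


# --- independent oracle: concordance from the raw moment definitions --------

def oracle_ccc(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((xi - mx) ** 2 for xi in x) / n
    sy2 = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def oracle_st_laurent(gold, test):
    mg = sum(gold) / len(gold)
    s_gg = sum((g - mg) ** 2 for g in gold)
    s_dd = sum((t - g) ** 2 for g, t in zip(gold, test))
    return s_gg / (s_gg + s_dd)


def ps(x, y):
    return PairedSample(np.asarray(x, float), np.asarray(y, float))


class TestDescriptiveSummary:
    def test_hand_example(self):
        s = descriptive_summary([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sd == pytest.approx(math.sqrt(5 / 3), abs=1e-12)
        assert (s.minimum, s.median, s.maximum, s.n) == (1, 2.5, 4, 4)

    def test_single_value_warns(self):
        with pytest.warns(UserWarning):
            s = descriptive_summary([5.0])
        assert (s.mean, s.sd, s.minimum, s.median, s.maximum) == (5, 0, 5, 5, 5)

    def test_constant_vector(self):
        s = descriptive_summary([2, 2, 2])
        assert s.sd == 0 and s.minimum == s.median == s.maximum == 2

    def test_empty_rejected(self):
        with pytest.raises(AgreementError):
            descriptive_summary([])


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expect",
        [([1, 2, 3], [2, 3, 4], 1.0), ([1, 2, 3], [3, 2, 1], -1.0),
         ([1, 2, 3, 4], [1, 3, 2, 4], 0.8)],
    )
    def test_known_values(self, x, y, expect):
        assert pearson_r(ps(x, y)) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(AgreementError):
            pearson_r(ps([1, 1, 1], [1, 2, 3]))


class TestLinCCC:
    def test_perfect_agreement(self):
        v = np.arange(1.0, 11.0)
        est = lin_ccc(PairedSample(v, v.copy()))
        assert est.coefficient == pytest.approx(1.0, abs=1e-15)

    def test_shifted_line_hand_value(self):
        est = lin_ccc(ps([1, 2, 3], [2, 3, 4]))
        assert est.coefficient == pytest.approx(4 / 7, abs=1e-12)
        r, cb = est.components
        assert r == pytest.approx(1.0, abs=1e-12)
        assert cb == pytest.approx(4 / 7, abs=1e-12)

    def test_perfect_inverse(self):
        est = lin_ccc(ps([1, 2, 3], [3, 2, 1]))
        assert est.coefficient == pytest.approx(-1.0, abs=1e-12)

    def test_matches_moment_oracle_on_1000_random_samples(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x = rng.normal(rng.normal(0, 3), rng.uniform(0.5, 4), n)
            y = x * rng.uniform(-1.5, 1.5) + rng.normal(0, 1, n)
            if np.var(x) == 0 or np.var(y) == 0:
                continue
            est = lin_ccc(PairedSample(x, y))
            assert est.coefficient == pytest.approx(oracle_ccc(x.tolist(), y.tolist()), abs=1e-12)

    def test_symmetric_and_bounded_by_pearson(self, rng):
        for _ in range(50):
            x = rng.normal(0, 2, 25)
            y = 0.7 * x + rng.normal(1.0, 1.5, 25)
            a = lin_ccc(PairedSample(x, y))
            b = lin_ccc(PairedSample(y, x))
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-12)
            assert abs(a.coefficient) <= abs(pearson_r(PairedSample(x, y))) + 1e-12

    def test_ci_brackets_estimate_and_orders(self, rng):
        x = rng.normal(30, 7, 90)
        y = x + rng.normal(3, 4, 90)
        est = lin_ccc(PairedSample(x, y))
        assert est.ci_lower < est.coefficient < est.ci_upper
        assert -1 <= est.ci_lower and est.ci_upper <= 1

    def test_degenerate_unity_ccc_returns_point_ci(self):
        v = np.arange(1.0, 6.0)
        with pytest.warns(UserWarning):
            est = lin_ccc(PairedSample(v, v.copy()))
        assert est.ci_lower == est.coefficient == est.ci_upper

    def test_zero_variance_rejected(self):
        with pytest.raises(AgreementError):
            lin_ccc(ps([1, 1, 1], [1, 2, 3]))


class TestStLaurent:
    def test_identity_gives_one(self):
        assert st_laurent_coefficient([1, 2, 3], [1, 2, 3]) == 1.0

    def test_biased_test_hand_value(self):
        assert st_laurent_coefficient([1, 2, 3], [2, 3, 4]) == pytest.approx(0.4, abs=1e-12)

    def test_small_deviations_hand_value(self):
        got = st_laurent_coefficient([1, 2, 3], [1.1, 1.9, 3.0])
        assert got == pytest.approx(2 / 2.02, abs=1e-12)

    def test_matches_definition_oracle(self, rng):
        for _ in range(200):
            g = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 5), 20)
            t = g + rng.normal(rng.uniform(-2, 2), rng.uniform(0, 3), 20)
            assert st_laurent_coefficient(g, t) == pytest.approx(
                oracle_st_laurent(g.tolist(), t.tolist()), abs=1e-12
            )

    def test_lies_in_unit_interval(self, rng):
        for _ in range(200):
            g = rng.normal(0, 2, 15)
            t = rng.normal(0, 5, 15)  # arbitrarily bad test method
            assert 0.0 <= st_laurent_coefficient(g, t) <= 1.0

    def test_noise_decreases_expected_agreement(self, rng):
        g = rng.normal(30, 6, 400)
        prev = 1.0
        for sd in (0.5, 2.0, 5.0):
            coef = st_laurent_coefficient(g, g + rng.normal(0, sd, g.size))
            assert coef < prev
            prev = coef

    def test_bootstrap_ci_seeded_and_bracketing(self, rng):
        g = rng.normal(30, 6, 60)
        t = g + rng.normal(1, 3, 60)
        a = st_laurent(g, t, seed=7)
        b = st_laurent(g, t, seed=7)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)
        assert a.ci_lower <= a.coefficient <= a.ci_upper

    def test_constant_gold_rejected(self):
        with pytest.raises(AgreementError):
            st_laurent_coefficient([2, 2, 2], [1, 2, 3])


class TestBlandAltman:
    def test_identical_methods(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(PairedSample(v, v.copy()))
        assert ba.bias == 0 and ba.sd_diff == 0
        assert ba.loa_lower == 0 and ba.loa_upper == 0

    @pytest.mark.parametrize("mult,lo,hi", [(1.96, -3.96, -0.04), (2.0, -4.0, 0.0)])
    def test_hand_example_multipliers(self, mult, lo, hi):
        ba = bland_altman(ps([0, 0, 0], [1, 2, 3]), multiplier=mult)
        assert ba.bias == pytest.approx(-2.0, abs=1e-12)
        assert ba.sd_diff == pytest.approx(1.0, abs=1e-12)
        assert ba.loa_lower == pytest.approx(lo, abs=1e-12)
        assert ba.loa_upper == pytest.approx(hi, abs=1e-12)

    def test_loa_cis_use_documented_se(self):
        x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        y = np.array([11.0, 11.5, 10.0, 12.0, 12.5])
        ba = bland_altman(PairedSample(x, y))
        n, sd = 5, ba.sd_diff
        se = sd * math.sqrt(1 / n + 1.96**2 / (2 * (n - 1)))
        tq = stats.t.ppf(0.975, n - 1)
        assert ba.ci_loa_lower[0] == pytest.approx(ba.loa_lower - tq * se, abs=1e-12)
        assert ba.ci_loa_upper[1] == pytest.approx(ba.loa_upper + tq * se, abs=1e-12)

    def test_plot_points_are_pairwise_average_and_difference(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        ba = bland_altman(PairedSample(x, y))
        np.testing.assert_allclose(ba.averages, (x + y) / 2)
        np.testing.assert_allclose(ba.differences, x - y)

    def test_coverage_converges_to_nominal(self, rng):
        d = rng.normal(0, 1, 10_000)
        ba = bland_altman(PairedSample(d, np.zeros_like(d)))
        frac = np.mean((d > ba.loa_lower) & (d < ba.loa_upper))
        assert frac == pytest.approx(0.95, abs=0.01)


class TestPairedDifference:
    def test_hand_t_example(self):
        res = paired_difference_test(ps([0, 0, 0], [1, 2, 3]))
        assert res.mean_diff == pytest.approx(-2.0)
        assert res.statistic == pytest.approx(-2 / (1 / math.sqrt(3)), abs=1e-9)
        assert res.df == 2
        assert res.p_value == pytest.approx(2 * stats.t.cdf(res.statistic, 2), abs=1e-12)

    def test_symmetric_differences_give_p_one(self):
        res = paired_difference_test(ps([0, 0, 0], [-1, 0, 1]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(AgreementError):
            paired_difference_test(ps([1, 2, 3], [1, 2, 3]))

    def test_wilcoxon_alternative_runs(self, rng):
        x = rng.normal(0, 1, 30)
        res = paired_difference_test(PairedSample(x, x + rng.normal(1, 1, 30)), test="wilcoxon")
        assert res.test == "wilcoxon" and 0 <= res.p_value <= 1


class TestIccSampleSize:
    def oracle(self, rho, w, k, alpha=0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return math.ceil(1 + 8 * z**2 * (1 - rho) ** 2 * (1 + (k - 1) * rho) ** 2 / (k * (k - 1) * w**2))

    @pytest.mark.parametrize("rho,w,k", [(0.70, 0.20, 2), (0.70, 0.20, 3), (0.9, 0.1, 2)])
    def test_matches_formula_oracle(self, rho, w, k):
        assert icc_sample_size(rho, w, k) == self.oracle(rho, w, k)

    def test_planning_anchor_values(self):
        assert icc_sample_size(0.70, 0.20, 2) == 101
        assert icc_sample_size(0.70, 0.20, 3) == 68

    def test_monotone_decreasing_in_rho(self):
        sizes = [icc_sample_size(r, 0.20, 2) for r in (0.5, 0.7, 0.9, 0.99)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] <= 3

    @pytest.mark.parametrize("rho,w,k", [(0.0, 0.2, 2), (1.0, 0.2, 2), (0.7, 0.0, 2), (0.7, 0.2, 1)])
    def test_domain_errors(self, rho, w, k):
        with pytest.raises(AgreementError):
            icc_sample_size(rho, w, k)


@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
    st.lists(st.floats(-100, 100), min_size=3, max_size=30),
)
@settings(max_examples=150, deadline=None)
def test_ccc_always_in_unit_disc(xs, ys):
    """|CCC| <= 1 for any non-degenerate paired sample."""
    n = min(len(xs), len(ys))
    x, y = np.array(xs[:n]), np.array(ys[:n])
    if np.var(x) == 0 or np.var(y) == 0:
        return
    est = lin_ccc(PairedSample(x, y))
    assert abs(est.coefficient) <= 1 + 1e-9
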