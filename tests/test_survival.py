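"""Kaplan–Meier, log-rank, and chi-square against hand computation and lifelines."""

import numpy as np
import pytest
from scipy import stats

from survexpect import chisquare_proportions, kaplan_meier, logrank_test


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        curve = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        curve = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0
        assert np.allclose(curve.annual_values(5), 1.0)

    def test_hand_product_limit_with_tied_censoring(self):
        """Death and censoring at t=1: the censored subject is still at risk."""
        curve = kaplan_meier([1, 1, 2, 3, 4], [1, 0, 1, 0, 1])
        assert np.allclose(curve.times, [1, 2, 4])
        assert curve.value_at(1) == pytest.approx(4 / 5)
        assert curve.value_at(2) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.value_at(4) == pytest.approx(0.0)

    def test_annual_readout_steps(self):
        curve = kaplan_meier([0.5, 1.5, 2.5, 10.0], [1, 1, 1, 0])
        annual = curve.annual_values(3)
        assert np.allclose(annual, [1.0, 3 / 4, 1 / 2, 1 / 4])

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier([], [])
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier([-1.0], [1])

    def test_zero_censoring_equals_ecdf_complement(self):
        rng = np.random.default_rng(77)
        times = rng.exponential(5, size=200)
        curve = kaplan_meier(times, np.ones(200, dtype=bool))
        for t in [1.0, 3.0, 7.0]:
            assert curve.value_at(t) == pytest.approx(np.mean(times > t))

    def test_agrees_with_lifelines_on_random_censored_data(self):
        """50 random censored datasets: 1e-10 agreement with lifelines."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(5, 80))
            death = rng.exponential(5, n)
            cens = rng.exponential(6, n)
            times = np.round(np.minimum(death, cens), 2)  # rounding creates ties
            events = death <= cens
            if times.size == 0:
                continue
            ours = kaplan_meier(times, events)
            kmf = lifelines.KaplanMeierFitter().fit(times, events)
            for t, s in zip(ours.times, ours.survival):
                theirs = float(kmf.survival_function_at_times(t).iloc[0])
                assert abs(s - theirs) < 1e-10


class TestLogrank:
    def test_identical_groups_degenerate(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere(self):
        stat, p = logrank_test([1, 2], [0, 0], [3], [0])
        assert (stat, p) == (0.0, 1.0)

    def test_six_patient_hand_table(self):
        """O/E/V accumulated by hand over the three distinct death times.

        A: deaths at 1, 3; B: death at 2, censored 2.5, survivors to 4.
        t=1: n=(3,3), d=1 in A -> E_A=0.5, V=0.25
        t=2: n=(2,3), d=1 in B -> E_A=0.4, V=0.24
        t=3: n=(2,1), d=1 in A -> E_A=2/3, V=2/9
        sum(O-E) = (1-.5)+(0-.4)+(1-2/3) = 0.4333..; V = 0.7122..
        """
        ta, ea = [1, 3, 4], [1, 1, 0]
        tb, eb = [2, 2.5, 4], [1, 0, 0]
        stat, p = logrank_test(ta, ea, tb, eb)
        o_minus_e = 0.5 - 0.4 + 1 / 3
        v = 0.25 + 0.24 + 2 / 9
        assert stat == pytest.approx(o_minus_e**2 / v, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(stat, 1)))

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(3, 30), rng.exponential(5, 40)
        ea, eb = rng.random(30) < 0.7, rng.random(40) < 0.7
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_agrees_with_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(17)
        ta, tb = rng.exponential(3, 40), rng.exponential(5, 35)
        ea = np.ones(40, dtype=bool)
        eb = rng.random(35) < 0.8
        stat, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_type_i_error_calibrated(self):
        """Same exponential law in both arms: rejection rate ~ alpha."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            ta, tb = rng.exponential(4, 40), rng.exponential(4, 40)
            ca, cb = rng.uniform(0, 12, 40), rng.uniform(0, 12, 40)
            _, p = logrank_test(
                np.minimum(ta, ca), ta <= ca, np.minimum(tb, cb), tb <= cb
            )
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestChiSquare:
    def test_uniform_table_null(self):
        stat, p = chisquare_proportions([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pearson_2x2(self):
        stat, p = chisquare_proportions([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(20 / 3, 1)))

    def test_matches_scipy_no_correction(self):
        rng = np.random.default_rng(3)
        tab = rng.integers(5, 50, size=(3, 4))
        stat, p = chisquare_proportions(tab)
        ref = stats.chi2_contingency(tab, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate margin"):
            chisquare_proportions([[0, 0], [5, 5]])

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.binomial(60, 0.5)
            b = rng.binomial(60, 0.5)
            _, p = chisquare_proportions([[a, 60 - a], [b, 60 - b]])
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02
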