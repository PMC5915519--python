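import math

import numpy as np
import pytest
from scipy import stats

import tatkit as tk
from tatkit.survstats import EndpointEvent


def events(days, statuses, prefix="s"):
    return [
        EndpointEvent(f"{prefix}{i}", d, "event" if s else "censored")
        for i, (d, s) in enumerate(zip(days, statuses))
    ]


def chi2_logrank_oracle(days_a, obs_a, days_b, obs_b):
    """Independent array-based log-rank statistic (hypergeometric moments)."""
    days_a, days_b = np.asarray(days_a, float), np.asarray(days_b, float)
    obs_a, obs_b = np.asarray(obs_a, bool), np.asarray(obs_b, bool)
    O = E = V = 0.0
    for t in np.unique(np.concatenate([days_a[obs_a], days_b[obs_b]])):
        n1, n2 = (days_a >= t).sum(), (days_b >= t).sum()
        d1, d2 = (obs_a & (days_a == t)).sum(), (obs_b & (days_b == t)).sum()
        n, d = n1 + n2, d1 + d2
        if d == 0 or n == 0:
            continue
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else math.nan


class TestKaplanMeier:
    def test_all_censored_is_unity(self):
        curve = tk.kaplan_meier(events([3, 7, 12], [0, 0, 0]))
        assert np.all(curve.survival == 1.0)

    def test_five_subjects_two_events(self):
        # events at days 2 and 4, no censoring: S = 0.8 on [2,4), 0.6 after
        curve = tk.kaplan_meier(events([2, 4, 9, 9, 9], [1, 1, 0, 0, 0]))
        assert curve.survival_at(1.0) == 1.0
        assert curve.survival_at(2.0) == pytest.approx(0.8)
        assert curve.survival_at(3.9) == pytest.approx(0.8)
        assert curve.survival_at(4.0) == pytest.approx(0.6)
        assert curve.survival_at(60.0) == pytest.approx(0.6)

    def test_simultaneous_events_drop_to_zero(self):
        curve = tk.kaplan_meier(events([5, 5, 5], [1, 1, 1]))
        assert curve.survival_at(4.9) == 1.0
        assert curve.survival_at(5.0) == 0.0

    def test_censoring_tied_with_event_still_at_risk(self):
        # censored subject at day 2 counts in the risk set of the day-2 event
        curve = tk.kaplan_meier(events([2, 2, 6], [1, 0, 0]))
        assert curve.survival_at(2.0) == pytest.approx(1 - 1 / 3)

    def test_non_increasing_and_bounded(self, rng):
        days = rng.integers(1, 30, size=40)
        statuses = rng.random(40) < 0.6
        curve = tk.kaplan_meier(events(days, statuses))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        days = rng.integers(1, 25, size=60)
        statuses = rng.random(60) < 0.7
        curve = tk.kaplan_meier(events(days, statuses))
        kmf = lifelines.KaplanMeierFitter().fit(days, statuses)
        for t in np.unique(days):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), rel=1e-9
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tk.kaplan_meier([])


class TestLogrank:
    def test_identical_groups_null(self):
        a = events([1, 3, 5], [1, 1, 1], "a")
        b = events([1, 3, 5], [1, 1, 1], "b")
        res = tk.logrank(a, b)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_vs_three_matches_hand_oracle(self):
        a_days, b_days = [1, 2, 3], [4, 5, 6]
        res = tk.logrank(events(a_days, [1] * 3, "a"), events(b_days, [1] * 3, "b"))
        expected = chi2_logrank_oracle(a_days, [1] * 3, b_days, [1] * 3)
        assert res.chi_square == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_symmetric_in_group_labels(self, rng):
        a = events(rng.integers(1, 20, 10), rng.random(10) < 0.7, "a")
        b = events(rng.integers(1, 20, 12), rng.random(12) < 0.7, "b")
        assert tk.logrank(a, b).chi_square == pytest.approx(tk.logrank(b, a).chi_square)

    def test_early_censored_subject_is_inert(self):
        a = events([5, 8, 11], [1, 1, 0], "a")
        b = events([6, 9, 14], [1, 0, 1], "b")
        base = tk.logrank(a, b)
        padded = tk.logrank(a + [EndpointEvent("extra", 1, "censored")], b)
        assert padded.chi_square == pytest.approx(base.chi_square)

    def test_no_events_undefined(self):
        res = tk.logrank(events([3, 4], [0, 0], "a"), events([5, 6], [0, 0], "b"))
        assert not res.defined

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        da, sa = rng.integers(1, 20, 15), rng.random(15) < 0.7
        db, sb = rng.integers(1, 25, 15), rng.random(15) < 0.5
        res = tk.logrank(events(da, sa, "a"), events(db, sb, "b"))
        ll = lifelines_stats.logrank_test(da, db, event_observed_A=sa, event_observed_B=sb)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)

    def test_p_value_consistent_with_permutation_null(self, rng):
        # moderate separation so p is mid-range and the chi2(1) reference
        # can be checked against an exhaustive label-shuffling null
        da, sa = [2, 4, 5, 7, 9, 12, 15, 20], [1, 1, 1, 0, 1, 1, 0, 1]
        db, sb = [3, 6, 10, 13, 16, 21, 24, 28], [1, 1, 1, 1, 0, 1, 1, 0]
        res = tk.logrank(events(da, sa, "a"), events(db, sb, "b"))
        days = np.array(da + db, float)
        obs = np.array(sa + sb, bool)
        n_a = len(da)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(days.size)
            chi = chi2_logrank_oracle(
                days[idx[:n_a]], obs[idx[:n_a]], days[idx[n_a:]], obs[idx[n_a:]]
            )
            if chi >= res.chi_square - 1e-12:
                count += 1
        p_perm = count / n_perm
        # MC standard error ~0.005 plus small-sample chi2 approximation error
        assert res.p_value == pytest.approx(p_perm, abs=0.04)


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self, rng):
        control = rng.normal(0, 1, 10)
        treat = rng.normal(0.8, 1, 10)
        res = tk.dunnett_many_to_one(control, [treat], mc_draws=200_000, seed=7)
        t_p = stats.ttest_ind(treat, control).pvalue
        assert res.p_adjusted[0] == pytest.approx(t_p, abs=0.01)

    def test_matches_scipy_dunnett(self, rng):
        control = rng.normal(0, 1, 8)
        treats = [rng.normal(mu, 1, 8) for mu in (0.0, 0.7, 1.5)]
        res = tk.dunnett_many_to_one(control, treats, mc_draws=200_000, seed=11)
        ref = stats.dunnett(*treats, control=control)
        np.testing.assert_allclose(res.p_adjusted, ref.pvalue, atol=0.01)

    def test_identical_treatment_near_one(self):
        control = [1.0, 2.0, 3.0, 4.0]
        res = tk.dunnett_many_to_one(control, [list(control)], mc_draws=20_000, seed=3)
        assert res.p_adjusted[0] > 0.95

    def test_adjusted_at_least_unadjusted(self, rng):
        control = rng.normal(0, 1, 6)
        treats = [rng.normal(mu, 1, 6) for mu in (0.0, 0.5, 1.0, 2.0)]
        res = tk.dunnett_many_to_one(control, treats, mc_draws=20_000, seed=5)
        assert np.all(res.p_adjusted >= res.p_unadjusted - 1e-12)

    def test_seed_reproducibility(self, rng):
        control = rng.normal(0, 1, 6)
        treats = [rng.normal(0.5, 1, 6)]
        r1 = tk.dunnett_many_to_one(control, treats, mc_draws=5_000, seed=42)
        r2 = tk.dunnett_many_to_one(control, treats, mc_draws=5_000, seed=42)
        np.testing.assert_array_equal(r1.p_adjusted, r2.p_adjusted)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            tk.dunnett_many_to_one([1.0, 1.0], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            tk.dunnett_many_to_one([1.0], [[1.0, 2.0]])

    def test_family_wise_error_calibrated_under_null(self):
        # 2000 simulated null experiments (3 treatments vs control, n=5):
        # the rate of any adjusted p <= 0.05 should be ~0.05
        rng = np.random.default_rng(2024)
        n_exp, alpha = 2000, 0.05
        rejections = 0
        for i in range(n_exp):
            control = rng.normal(0, 1, 5)
            treats = [rng.normal(0, 1, 5) for _ in range(3)]
            res = tk.dunnett_many_to_one(control, treats, mc_draws=2_000, seed=rng)
            rejections += bool(np.any(res.p_adjusted <= alpha))
        fwer = rejections / n_exp
        assert fwer == pytest.approx(alpha, abs=0.015)
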