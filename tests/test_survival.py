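import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from latebloom.survival import (
    SurvivalError,
    TimeWindow,
    contingency_test,
    cox_fit,
    kernel_hazard,
    km_estimate,
    landmark_restrict,
    make_dummies,
    nelson_aalen,
    schoenfeld_ph_test,
    wilcoxon_ranksum,
)

from conftest import two_group_exponential


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_all_censored_survival_is_one(self):
        rec = pd.DataFrame({"time_years": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        km = km_estimate(rec)
        assert len(km.times) == 0
        assert km.survival_at(2.5) == 1.0

    def test_hand_product_limit(self, km_fixture):
        km = km_estimate(km_fixture)
        np.testing.assert_allclose(km.times, [1.0, 2.0, 4.0])
        np.testing.assert_allclose(km.survival, [0.8, 0.4, 0.0])
        np.testing.assert_array_equal(km.at_risk, [5, 4, 1])
        np.testing.assert_array_equal(km.n_events, [1, 2, 1])

    def test_km_below_exp_neg_nelson_aalen(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3.0, 200)
        c = rng.uniform(0, 8, 200)
        rec = pd.DataFrame({"time_years": np.minimum(t, c),
                            "event": (t <= c).astype(int)})
        km = km_estimate(rec)
        times, inc = nelson_aalen(rec)
        cum = np.cumsum(inc)
        assert np.all(km.survival <= np.exp(-cum) + 1e-12)

    def test_no_censoring_matches_empirical_fraction(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(2.0, 150)
        rec = pd.DataFrame({"time_years": t, "event": np.ones(150, dtype=int)})
        km = km_estimate(rec)
        for q in (0.5, 1.0, 3.0):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(2.0, 100)
        c = rng.uniform(0, 5, 100)
        rec = pd.DataFrame({"time_years": np.minimum(t, c),
                            "event": (t <= c).astype(int)})
        km = km_estimate(rec)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


# ---------------------------------------------------------------------------
# Landmark restriction
# ---------------------------------------------------------------------------

class TestLandmark:
    def test_identity_window(self, km_fixture):
        out = landmark_restrict(km_fixture, TimeWindow(0.0))
        pd.testing.assert_frame_equal(out, km_fixture)

    def test_five_to_ten_example(self):
        rec = pd.DataFrame({"time_years": [3.0, 6.0, 12.0],
                            "event": [1, 1, 0]})
        out = landmark_restrict(rec, TimeWindow(5.0, 10.0))
        np.testing.assert_allclose(out["time_years"], [1.0, 5.0])
        np.testing.assert_array_equal(out["event"], [1, 0])

    def test_event_at_upper_bound_counts_inside(self):
        rec = pd.DataFrame({"time_years": [10.0], "event": [1]})
        out = landmark_restrict(rec, TimeWindow(5.0, 10.0))
        assert out["event"].iloc[0] == 1

    def test_counting_oracle(self):
        rng = np.random.default_rng(3)
        rec = two_group_exponential(rng, 400)
        out = landmark_restrict(rec, TimeWindow(5.0, 10.0))
        assert len(out) == int((rec["time_years"] > 5.0).sum())

    def test_empty_risk_set_errors(self, km_fixture):
        with pytest.raises(SurvivalError, match="risk set"):
            landmark_restrict(km_fixture, TimeWindow(50.0, 60.0))

    def test_event_partition_across_windows(self):
        rng = np.random.default_rng(4)
        rec = two_group_exponential(rng, 500, horizon=15.0)
        e_early = landmark_restrict(rec, TimeWindow(0, 5))["event"].sum()
        e_late = landmark_restrict(rec, TimeWindow(5, 10))["event"].sum()
        e_tail = ((rec["time_years"] > 10) & (rec["event"] == 1)).sum()
        assert e_early + e_late + e_tail == rec["event"].sum()

    def test_invalid_window(self):
        with pytest.raises(SurvivalError):
            TimeWindow(5.0, 5.0)


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

def efron_loglik_bruteforce(time, event, x, beta):
    """Independent scalar Efron log partial likelihood (naive loops)."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        dead = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(dead)
        s0_r = sum(math.exp(beta * x[i]) for i in risk)
        s0_d = sum(math.exp(beta * x[i]) for i in dead)
        ll += sum(beta * x[i] for i in dead)
        for l in range(d):
            ll -= math.log(s0_r - (l / d) * s0_d)
    return ll


class TestCox:
    def test_symmetric_groups_give_null_beta(self):
        rec = pd.DataFrame({
            "time_years": [1, 2, 3, 4, 1, 2, 3, 4],
            "event": [1, 1, 0, 1, 1, 1, 0, 1],
            "x": [0.0] * 4 + [1.0] * 4,
        })
        fit = cox_fit(rec, ["x"])
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, cox12_fixture):
        t = cox12_fixture["time_years"].to_numpy(dtype=float)
        d = cox12_fixture["event"].to_numpy(dtype=int)
        x = cox12_fixture["x"].to_numpy(dtype=float)
        grid = np.arange(-4.0, 4.0, 1e-4)
        lls = [efron_loglik_bruteforce(t, d, x, b) for b in grid]
        beta_oracle = grid[int(np.argmax(lls))]
        fit = cox_fit(cox12_fixture, ["x"])
        assert fit.coef[0] == pytest.approx(beta_oracle, abs=1e-4)
        assert fit.loglik == pytest.approx(
            efron_loglik_bruteforce(t, d, x, fit.coef[0]), abs=1e-9)

    def test_rescaling_invariance(self, cox12_fixture):
        fit1 = cox_fit(cox12_fixture, ["x"])
        scaled = cox12_fixture.assign(x=cox12_fixture["x"] * 10.0)
        fit2 = cox_fit(scaled, ["x"])
        assert fit2.coef[0] == pytest.approx(fit1.coef[0] / 10.0, rel=1e-8)
        assert fit2.p[0] == pytest.approx(fit1.p[0], abs=1e-10)

    def test_no_events_is_error(self):
        rec = pd.DataFrame({"time_years": [1.0, 2.0], "event": [0, 0],
                            "x": [0.0, 1.0]})
        with pytest.raises(SurvivalError, match="events"):
            cox_fit(rec, ["x"])

    def test_separation_flagged(self):
        # all events in group 1, all censored late in group 0 -> monotone lik
        rec = pd.DataFrame({
            "time_years": [1, 1.5, 2, 9, 9.5, 10],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        fit = cox_fit(rec, ["x"])
        assert any("diverging" in w for w in fit.warnings)

    def test_collinear_is_singular_error(self, cox12_fixture):
        rec = cox12_fixture.assign(x2=cox12_fixture["x"])
        with pytest.raises(SurvivalError, match="singular"):
            cox_fit(rec, ["x", "x2"])

    def test_ci_and_hr_relations(self, cox12_fixture):
        fit = cox_fit(cox12_fixture, ["x"])
        assert fit.hr[0] == pytest.approx(math.exp(fit.coef[0]))
        assert fit.ci_low[0] == pytest.approx(math.exp(fit.coef[0] - 1.96 * fit.se[0]))
        assert fit.ci_high[0] == pytest.approx(math.exp(fit.coef[0] + 1.96 * fit.se[0]))

    @pytest.mark.parametrize("hr", [1.0, 2.0])
    def test_parameter_recovery(self, hr):
        rng = np.random.default_rng(17)
        rec = two_group_exponential(rng, 1500, hr=hr)
        fit = cox_fit(rec, ["x"])
        assert fit.ci_low[0] < hr < fit.ci_high[0]

    def test_coverage_simulation(self):
        # 95% CI covers the true HR in >= 93% of 200 small simulations
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            rec = two_group_exponential(rng, 1000, hr=1.8)
            fit = cox_fit(rec, ["x"])
            hits += fit.ci_low[0] <= 1.8 <= fit.ci_high[0]
        assert hits / 200 >= 0.93

    def test_make_dummies_reference_checked(self, cox12_fixture):
        rec = cox12_fixture.assign(g=["a", "b"] * 6)
        with pytest.raises(SurvivalError, match="reference"):
            make_dummies(rec, "g", "missing_level")
        out, names = make_dummies(rec, "g", "a")
        assert names == ["g[b]"]
        assert out["g[b]"].sum() == 6


# ---------------------------------------------------------------------------
# Schoenfeld PH test
# ---------------------------------------------------------------------------

class TestPHTest:
    def test_degenerate_input_errors(self):
        rec = pd.DataFrame({"time_years": [1.0, 2.0, 3.0],
                            "event": [1, 0, 0], "x": [1.0, 0.0, 1.0]})
        fit = cox_fit(rec, ["x"])
        with pytest.raises(SurvivalError):
            schoenfeld_ph_test(fit, rec)

    def test_calibration_under_null(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            rec = two_group_exponential(rng, 150, hr=1.6)
            fit = cox_fit(rec, ["x"])
            rej += schoenfeld_ph_test(fit, rec).p[0] < 0.05
        assert abs(rej / n_rep - 0.05) <= 0.04

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            rec = two_group_exponential(rng, 120, hr=1.0)
            fit = cox_fit(rec, ["x"])
            pvals.append(schoenfeld_ph_test(fit, rec).p[0])
        assert stats.kstest(pvals, "uniform").statistic < 0.15

    @staticmethod
    def _crossing_hazards(rng, n=600):
        x = rng.binomial(1, 0.5, n).astype(float)
        lam1 = 0.15 * np.exp(np.log(3) * x)
        lam2 = 0.15 * np.exp(-np.log(3) * x)
        target = -np.log(rng.uniform(size=n))
        t = np.where(target <= lam1 * 5, target / lam1,
                     5 + (target - lam1 * 5) / lam2)
        return pd.DataFrame({
            "time_years": np.minimum(t, 10.0).clip(1e-9),
            "event": (t <= 10.0).astype(int),
            "x": x,
        })

    def test_power_under_crossing_hazards(self):
        rng = np.random.default_rng(21)
        rej = 0
        for _ in range(100):
            rec = self._crossing_hazards(rng)
            fit = cox_fit(rec, ["x"])
            rej += schoenfeld_ph_test(fit, rec).p[0] < 0.05
        assert rej / 100 >= 0.8

    def test_identity_transform_available(self):
        rng = np.random.default_rng(5)
        rec = two_group_exponential(rng, 200)
        fit = cox_fit(rec, ["x"])
        out = schoenfeld_ph_test(fit, rec, transform="identity")
        assert 0 <= out.p[0] <= 1
        assert out.transform == "identity"


# ---------------------------------------------------------------------------
# Kernel hazard
# ---------------------------------------------------------------------------

class TestKernelHazard:
    def test_no_events_zero_curve(self, caplog):
        rec = pd.DataFrame({"time_years": [1.0, 2.0], "event": [0, 0]})
        with caplog.at_level("WARNING"):
            out = kernel_hazard(rec)
        assert np.all(out.hazard == 0.0)

    def test_recovers_exponential_rate(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5.0, 2000)  # lambda = 0.2 / yr
        rec = pd.DataFrame({"time_years": np.minimum(t, 10.0).clip(1e-9),
                            "event": (t <= 10.0).astype(int)})
        grid = np.linspace(2.0, 8.0, 25)
        out = kernel_hazard(rec, grid=grid)
        rel_err = np.abs(out.hazard - 0.2) / 0.2
        assert rel_err.mean() <= 0.20

    def test_time_rescaling_units(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(4.0, 500)
        rec = pd.DataFrame({"time_years": np.minimum(t, 10.0).clip(1e-9),
                            "event": (t <= 10.0).astype(int)})
        grid = np.linspace(1.0, 9.0, 17)
        a = kernel_hazard(rec, bandwidth=1.5, grid=grid)
        c = 12.0  # e.g. years -> months
        rec2 = rec.assign(time_years=rec["time_years"] * c)
        b = kernel_hazard(rec2, bandwidth=1.5 * c, grid=grid * c)
        np.testing.assert_allclose(b.hazard, a.hazard / c, rtol=1e-9)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(10)
        rec = two_group_exponential(rng, 300)
        out = kernel_hazard(rec)
        assert np.all(out.hazard >= 0)

    def test_integral_matches_cumulative_hazard(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(5.0, 2000)
        rec = pd.DataFrame({"time_years": np.minimum(t, 10.0).clip(1e-9),
                            "event": (t <= 10.0).astype(int)})
        out = kernel_hazard(rec)
        km = km_estimate(rec)
        from scipy.integrate import trapezoid
        T = 8.0
        m = out.grid <= T
        integral = trapezoid(out.hazard[m], out.grid[m])
        target = -np.log(km.survival_at(T))
        assert abs(integral - target) / target <= 0.15

    def test_bad_bandwidth(self, km_fixture):
        with pytest.raises(SurvivalError):
            kernel_hazard(km_fixture, bandwidth=0.0)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_ranksum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_exact_matches_full_enumeration(self):
        # independent oracle: enumerate all rank assignments
        x = [1.0, 4.0, 6.0]
        y = [2.0, 3.0, 5.0, 7.0]
        ranks = stats.rankdata(x + y)
        w_obs = ranks[:3].sum()
        sums = [sum(c) for c in itertools.combinations(range(1, 8), 3)]
        lo = sum(s <= w_obs for s in sums) / len(sums)
        hi = sum(s >= w_obs for s in sums) / len(sums)
        expected = min(1.0, 2 * min(lo, hi))
        assert wilcoxon_ranksum(x, y) == pytest.approx(expected)

    def test_identical_samples_p_one(self):
        assert wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_large_sample_normal_approximation_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(0.5, 1.0, 55)
        # independent oracle: textbook normal approximation, no ties
        ranks = stats.rankdata(np.concatenate([x, y]))
        w = ranks[:40].sum()
        n1, n2 = 40, 55
        mu = n1 * (n1 + n2 + 1) / 2
        sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        z = (abs(w - mu) - 0.5) / sd
        expected = 2 * stats.norm.sf(z)
        assert wilcoxon_ranksum(x, y) == pytest.approx(expected, abs=1e-6)

    def test_empty_sample_errors(self):
        with pytest.raises(SurvivalError):
            wilcoxon_ranksum([], [1.0])


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

class TestContingency:
    def test_printed_counts_chi2_cc(self):
        p = contingency_test([[7, 8], [11, 0]], method="chi2_cc")
        assert round(p, 2) == 0.01
        assert round(p, 3) == 0.013

    def test_identical_rows_p_one(self):
        for method in ("chi2_cc", "fisher"):
            assert contingency_test([[5, 5], [5, 5]], method=method) == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[7, 8], [11, 0]])
        # oracle: sum of probabilities of all tables with the same margins
        # whose probability <= that of the observed table
        r0, c0, n = table[0].sum(), table[:, 0].sum(), table.sum()
        obs_p = stats.hypergeom.pmf(table[0, 0], n, r0, c0)
        total = sum(
            p for k in range(max(0, r0 + c0 - n), min(r0, c0) + 1)
            if (p := stats.hypergeom.pmf(k, n, r0, c0)) <= obs_p * (1 + 1e-9)
        )
        got = contingency_test(table, method="fisher")
        assert got == pytest.approx(total, rel=1e-9)
        assert got == pytest.approx(0.0074, abs=5e-4)

    def test_zero_margin_falls_back_to_fisher(self, caplog):
        with caplog.at_level("WARNING"):
            p = contingency_test([[0, 0], [5, 5]], method="chi2_cc")
        assert "Fisher" in caplog.text
        assert p == 1.0

    def test_invalid_table(self):
        with pytest.raises(SurvivalError):
            contingency_test([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(SurvivalError):
            contingency_test([[1.5, 2], [3, 4]])


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_km_invariants_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    t = rng.exponential(2.0, n).clip(1e-6)
    d = rng.binomial(1, 0.7, n)
    rec = pd.DataFrame({"time_years": t, "event": d})
    km = km_estimate(rec)
    assert np.all(np.diff(km.survival) <= 1e-15)
    assert np.all((km.survival >= -1e-15) & (km.survival <= 1 + 1e-15))
    assert km.survival_at(0.0) == 1.0 or len(km.times) == 0 or km.times[0] > 0
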