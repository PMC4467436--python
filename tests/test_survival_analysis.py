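"""KM curves, log-rank, Cox partial likelihood and treatment interactions."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from coexsig.survival_analysis import (
    cox_fit,
    km_estimate,
    logrank_test,
    predicted_curves,
    subtype_treatment_analysis,
)
from coexsig.synthetic_data import simulate_clinical, simulate_expression, two_program_config


def _random_cohort(seed, n=20, round_times=True):
    rng = np.random.default_rng(seed)
    t = rng.exponential(100, n)
    if round_times:
        t = np.maximum(np.round(t), 1.0)  # ties on purpose
    return pd.DataFrame({
        "time": t,
        "event": rng.integers(0, 2, n),
        "x1": rng.standard_normal(n),
        "x2": rng.integers(0, 2, n).astype(float),
    })


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_between_events_by_hand(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_no_events_flat_curve(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40))
        for et, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((t > et).mean(), abs=1e-12)

    def test_greenwood_se_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        df = _random_cohort(3, n=30)
        km = km_estimate(df["time"], df["event"])
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        ours = pd.Series(km.survival, index=km.event_times)
        theirs = kmf.survival_function_["KM_estimate"]
        for t in ours.index:
            assert ours[t] == pytest.approx(theirs.loc[t], abs=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_summed_observed_minus_expected(self):
        # two groups, six subjects, all events; O-E and V accumulated by hand
        g1 = ([1.0, 3.0, 5.0], [1, 1, 1])
        g2 = ([2.0, 4.0, 6.0], [1, 1, 1])
        res = logrank_test([g1, g2])
        o_minus_e = 0.0
        v = 0.0
        times = [1, 2, 3, 4, 5, 6]
        risk1 = [3, 2, 2, 1, 1, 0]
        risk2 = [3, 3, 2, 2, 1, 1]
        obs1 = [1, 0, 1, 0, 1, 0]
        for n1, n2, o1 in zip(risk1, risk2, obs1):
            n = n1 + n2
            e1 = n1 / n
            o_minus_e += o1 - e1
            v += (n1 * n2) / (n * n) if n > 1 else 0.0  # d=1, (n-d)/(n-1)=1
        assert res.statistic == pytest.approx(o_minus_e**2 / v, rel=1e-10)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        t1, t2 = rng.exponential(50, 40), rng.exponential(80, 35)
        e1, e2 = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        res = logrank_test([(t1, e1), (t2, e2)])
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1, 2], [1, 1]), ([], [])])


class TestCoxFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_reference_implementation(self, seed):
        df = _random_cohort(seed)
        if df["event"].sum() == 0:
            pytest.skip("degenerate draw")
        res = cox_fit(df, ["x1", "x2"])
        cph = CoxPHFitter().fit(
            df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-12},
        )
        np.testing.assert_allclose(
            res.summary["beta"].to_numpy(), cph.params_.to_numpy(), atol=1e-6
        )
        assert res.loglik == pytest.approx(cph.log_likelihood_, abs=1e-8)
        np.testing.assert_allclose(
            res.summary["se"].to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_null_covariate_recovered(self):
        rng = np.random.default_rng(10)
        n = 2000
        df = pd.DataFrame({
            "time": rng.exponential(100, n),
            "event": np.ones(n, dtype=int),
            "x": rng.standard_normal(n),
        })
        res = cox_fit(df, ["x"])
        assert abs(res.summary.loc["x", "beta"]) < 0.1
        assert res.summary.loc["x", "ci_low"] < 1.0 < res.summary.loc["x", "ci_high"]

    def test_time_rescaling_leaves_beta_unchanged(self):
        df = _random_cohort(5, n=40, round_times=False)
        r1 = cox_fit(df, ["x1"])
        df2 = df.assign(time=df["time"] * 365.25)
        r2 = cox_fit(df2, ["x1"])
        assert r1.summary.loc["x1", "beta"] == pytest.approx(
            r2.summary.loc["x1", "beta"], rel=1e-8
        )

    def test_covariate_rescaling_scales_beta(self):
        df = _random_cohort(6, n=40)
        r1 = cox_fit(df, ["x1"])
        r2 = cox_fit(df.assign(x1=df["x1"] / 10), ["x1"])
        assert r2.summary.loc["x1", "beta"] == pytest.approx(
            10 * r1.summary.loc["x1", "beta"], rel=1e-6
        )

    def test_constant_covariate_named_in_error(self):
        df = _random_cohort(7).assign(flat=1.0)
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["flat"])

    def test_separation_flagged_as_monotone_likelihood(self):
        # perfectly separating binary covariate drives beta to the boundary
        df = pd.DataFrame({
            "time": np.r_[np.arange(1, 11), np.arange(100, 110)].astype(float),
            "event": np.ones(20, dtype=int),
            "x": np.r_[np.ones(10), np.zeros(10)],
        })
        res = cox_fit(df, ["x"])
        assert "monotone-likelihood" in res.flags or not res.converged

    def test_missing_covariates_dropped(self):
        df = _random_cohort(8, n=30)
        df.loc[df.index[:5], "x1"] = np.nan
        res = cox_fit(df, ["x1"])
        assert res.n == 25


class TestPredictedCurves:
    def _fit(self):
        df = _random_cohort(9, n=80, round_times=False)
        return cox_fit(df, ["x1", "x2"]), df

    def test_mean_profile_is_baseline(self):
        res, df = self._fit()
        curves = predicted_curves(res, {"base": {}})
        np.testing.assert_allclose(
            curves["base"].to_numpy(), np.exp(-res.baseline_cumhaz)
        )

    def test_higher_risk_profile_lies_below(self):
        res, _ = self._fit()
        b = res.summary.loc["x1", "beta"]
        hi = {"x1": res.covariate_means["x1"] + (1 if b > 0 else -1)}
        lo = {"x1": res.covariate_means["x1"] - (1 if b > 0 else -1)}
        curves = predicted_curves(res, {"hi": hi, "lo": lo})
        assert (curves["hi"] <= curves["lo"] + 1e-12).all()

    def test_unknown_covariate_rejected(self):
        res, _ = self._fit()
        with pytest.raises(KeyError):
            predicted_curves(res, {"bad": {"nope": 1.0}})

    def test_protective_treatment_curve_lies_above(self):
        # planted protective treatment effect: treated curve above untreated
        cfg = two_program_config(n_genes=20, n_members=5, n_samples=1500, rng_seed=13)
        cfg.survival.treatment_log_hr = {
            ("B", "temozolomide"): -0.49,
            ("A", "temozolomide"): -0.49,
        }
        _, truth = simulate_expression(cfg)
        clin = simulate_clinical(cfg, truth)
        res = cox_fit(clin, ["age", "radiotherapy", "temozolomide"])
        curves = predicted_curves(res, {"treated": {"temozolomide": 1}, "untreated": {"temozolomide": 0}})
        median_idx = len(curves) // 2
        assert curves["treated"].iloc[median_idx] > curves["untreated"].iloc[median_idx]


class TestSubtypeTreatmentAnalysis:
    def test_planted_interaction_recovered(self):
        cfg = two_program_config(n_genes=20, n_members=5, n_samples=2000, rng_seed=3)
        cfg.survival.treatment_log_hr = {("A", "radiotherapy"): -1.25}
        _, truth = simulate_expression(cfg)
        clin = simulate_clinical(cfg, truth)
        report, fits = subtype_treatment_analysis(clin)
        report = report.set_index(["subtype", "treatment"])
        hr_a = report.loc[("A", "radiotherapy")]
        hr_b = report.loc[("B", "radiotherapy")]
        assert 0.22 <= hr_a["hr"] <= 0.37
        assert hr_b["ci_low"] < 1.0 < hr_b["ci_high"]
        assert fits["A"].converged and fits["B"].converged

    def test_identical_hazards_give_similar_strata(self):
        cfg = two_program_config(n_genes=20, n_members=5, n_samples=3000, rng_seed=21)
        cfg.survival.treatment_log_hr = {
            ("A", "radiotherapy"): -0.7, ("B", "radiotherapy"): -0.7,
        }
        _, truth = simulate_expression(cfg)
        clin = simulate_clinical(cfg, truth)
        report, _ = subtype_treatment_analysis(clin)
        report = report.set_index(["subtype", "treatment"])
        a = report.loc[("A", "radiotherapy")]
        b = report.loc[("B", "radiotherapy")]
        ba, bb = np.log(a["hr"]), np.log(b["hr"])
        se_a = (np.log(a["ci_high"]) - np.log(a["ci_low"])) / (2 * 1.959964)
        se_b = (np.log(b["ci_high"]) - np.log(b["ci_low"])) / (2 * 1.959964)
        # the two stratum coefficients agree within sampling error
        assert abs(ba - bb) < 3.5 * np.hypot(se_a, se_b)

    def test_missing_subtype_column_rejected(self):
        df = _random_cohort(2)
        with pytest.raises(KeyError):
            subtype_treatment_analysis(df)
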