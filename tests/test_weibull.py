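import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsurv.dataset import SurvivalDataset, ValidationError
from mrsurv.weibull import (
    WeibullPHFit,
    baseline_survivor,
    fit_weibull_ph,
    fp2_linearity_check,
    hazard_ratio_per_sd,
    stepwise_select,
    weibull_loglog_diagnostic,
)

from conftest import simulate_ph


class TestBaselineSurvivor:
    def test_study_constant(self):
        # the multiplicative constant of the published score formula
        assert baseline_survivor(1.7376, 1.0769, 1.0) == pytest.approx(0.1632, abs=5e-5)

    def test_origin_and_unit_exponential(self):
        assert baseline_survivor(2.3, 0.7, 0.0) == 1.0
        assert baseline_survivor(1.0, 1.0, 1.0) == pytest.approx(np.exp(-1), abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            baseline_survivor(1.0, 1.0, -0.1)
        with pytest.raises(ValidationError):
            baseline_survivor(-1.0, 1.0, 1.0)

    @given(lam=st.floats(0.05, 10), gam=st.floats(0.2, 5),
           t1=st.floats(0.0, 20), t2=st.floats(0.0, 20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_probability(self, lam, gam, t1, t2):
        s1, s2 = baseline_survivor(lam, gam, t1), baseline_survivor(lam, gam, t2)
        assert 0.0 <= s1 <= 1.0
        if t1 < t2:
            assert s1 >= s2


class TestHazardRatioPerSD:
    @pytest.mark.parametrize(
        "beta, sd, expected",
        [(-0.020, 51.73, 0.36), (-0.483, 2.88, 0.25), (0.0, 12.3, 1.0)],
    )
    def test_published_per_sd_ratios(self, beta, sd, expected):
        assert hazard_ratio_per_sd(beta, sd) == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            hazard_ratio_per_sd(0.1, 0.0)


class TestFit:
    def test_exponential_special_case(self):
        ds = simulate_ph(seed=3, n=2000, betas=[], lambda0=1.0, gamma0=1.0,
                         censor_max=50.0)
        fit = fit_weibull_ph(ds)
        se_g = fit.gamma * np.sqrt(fit.cov[1, 1])
        se_l = fit.lambda_ * np.sqrt(fit.cov[0, 0])
        assert abs(fit.gamma - 1.0) < 3 * se_g
        assert abs(fit.lambda_ - 1.0) < 3 * se_l

    def test_binary_covariate_recovery(self):
        def sampler(rng, n, p):
            return rng.integers(0, 2, size=(n, p)).astype(float)

        ds = simulate_ph(seed=11, n=2000, betas=[0.7], covariate_sampler=sampler)
        fit = fit_weibull_ph(ds, ["x0"])
        assert abs(fit.beta[0] - 0.7) < 3 * fit.se_beta[0]

    def test_agrees_with_lifelines_aft(self, simple_cohort):
        # independent route: Weibull AFT reparameterized to PH
        from lifelines import WeibullAFTFitter

        fit = fit_weibull_ph(simple_cohort, ["x0"])
        df = pd.DataFrame({"T": simple_cohort.time, "E": simple_cohort.event,
                           "x0": simple_cohort.covariates["x0"]})
        aft = WeibullAFTFitter().fit(df, "T", "E")
        rho = np.exp(aft.params_["rho_"]["Intercept"])
        lam = 1.0 / np.exp(aft.params_["lambda_"]["Intercept"])
        beta_ph = -rho * aft.params_["lambda_"]["x0"]
        assert fit.gamma == pytest.approx(rho, abs=1e-4)
        assert fit.lambda_ == pytest.approx(lam, abs=1e-4)
        assert fit.beta[0] == pytest.approx(beta_ph, abs=1e-4)
        assert fit.loglik == pytest.approx(aft.log_likelihood_, abs=1e-5)

    def test_time_rescaling_invariance(self, simple_cohort):
        fit = fit_weibull_ph(simple_cohort, ["x0"])
        scaled = SurvivalDataset(simple_cohort.time * 3.0, simple_cohort.event,
                                 simple_cohort.covariates)
        fit3 = fit_weibull_ph(scaled, ["x0"])
        assert fit3.gamma == pytest.approx(fit.gamma, rel=1e-5)
        assert fit3.lambda_ == pytest.approx(fit.lambda_ / 3.0, rel=1e-5)

    def test_centering_changes_only_intercept(self, simple_cohort):
        plain = fit_weibull_ph(simple_cohort, ["x0"])
        centered = fit_weibull_ph(simple_cohort, ["x0"], center=True)
        assert centered.beta[0] == pytest.approx(plain.beta[0], abs=1e-6)
        assert centered.gamma == pytest.approx(plain.gamma, abs=1e-6)
        assert centered.loglik == pytest.approx(plain.loglik, abs=1e-6)
        xbar = simple_cohort.covariates["x0"].mean()
        # intercept absorbs beta*xbar/gamma on the log-scale parameterisation
        shift = np.log(centered.lambda_) - np.log(plain.lambda_)
        assert shift == pytest.approx(plain.beta[0] * xbar / plain.gamma, abs=1e-5)

    def test_zero_events_rejected(self):
        ds = SurvivalDataset([1.0, 2.0], [0, 0], pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValidationError):
            fit_weibull_ph(ds, ["a"])

    def test_missing_covariates_rejected(self):
        ds = SurvivalDataset([1.0, 2.0], [1, 0],
                             pd.DataFrame({"a": [np.nan, 2.0]}))
        with pytest.raises(ValidationError):
            fit_weibull_ph(ds, ["a"])

    def test_json_round_trip(self, tmp_path, simple_cohort):
        fit = fit_weibull_ph(simple_cohort, ["x0"], center=True)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = WeibullPHFit.from_json(path)
        assert back.to_dict() == fit.to_dict()
        cov = simple_cohort.covariates
        np.testing.assert_array_equal(back.predict_risk(1.0, cov),
                                      fit.predict_risk(1.0, cov))


class TestStepwise:
    def test_single_true_predictor_selected(self):
        ds = simulate_ph(seed=0, n=500, betas=[0.8, 0, 0, 0, 0])
        res = stepwise_select(ds, [f"x{j}" for j in range(5)])
        assert res.selected == ["x0"]
        assert list(res.trace["action"]) == ["enter"]

    def test_null_selection_mostly_empty(self):
        # retention requires a Wald p below p_stay=0.05 for some candidate,
        # so the no-selection rate is about 0.95^5 ~ 77%
        empty = 0
        reps = 100
        for r in range(reps):
            ds = simulate_ph(seed=10_000 + r, n=300, betas=[0, 0, 0, 0, 0])
            empty += len(stepwise_select(ds, [f"x{j}" for j in range(5)]).selected) == 0
        assert empty >= 0.65 * reps

    def test_empty_candidates_returns_empty_model(self, simple_cohort):
        res = stepwise_select(simple_cohort, [])
        assert res.selected == [] and res.fit.names == []
        assert len(res.trace) == 0


class TestFP2:
    @staticmethod
    def _cohort(seed, transform):
        rng = np.random.default_rng(seed)
        n = 1000
        x = rng.uniform(0.3, 3.0, n)
        lp = transform(x)
        tt = -np.log(rng.uniform(size=n)) * np.exp(-lp)
        t = np.minimum(tt, 2.0)
        e = (tt <= 2.0).astype(int)
        return SurvivalDataset(t, e, pd.DataFrame({"x": x}))

    def test_linear_truth_mostly_linear_verdict(self):
        verdicts = [fp2_linearity_check(self._cohort(s, lambda x: 0.5 * x), "x").verdict
                    for s in range(12)]
        assert verdicts.count("linear") >= 10

    def test_log_truth_detected_nonlinear(self):
        verdicts = [
            fp2_linearity_check(self._cohort(s, lambda x: 1.2 * np.log(x)), "x").verdict
            for s in range(12)
        ]
        assert sum(v in ("FP1", "FP2") for v in verdicts) >= 9

    def test_constant_covariate_rejected(self):
        ds = SurvivalDataset(np.arange(1, 21, dtype=float), np.ones(20, int),
                             pd.DataFrame({"x": np.ones(20)}))
        with pytest.raises(ValidationError, match="constant"):
            fp2_linearity_check(ds, "x")

    def test_too_few_events_rejected(self):
        ds = SurvivalDataset([1.0, 2, 3, 4], [1, 0, 0, 0],
                             pd.DataFrame({"x": [1.0, 2, 3, 4]}))
        with pytest.raises(ValidationError, match="events"):
            fp2_linearity_check(ds, "x")

    def test_nonpositive_covariate_shift_recorded(self):
        ds = self._cohort(1, lambda x: 0.5 * x)
        shifted = SurvivalDataset(ds.time, ds.event,
                                  pd.DataFrame({"x": ds.covariates["x"] - 1.0}))
        res = fp2_linearity_check(shifted, "x")
        assert res.shift > 0


class TestLogLogDiagnostic:
    def test_weibull_data_near_linear_with_slope_gamma(self):
        gam = 1.0769
        ds = simulate_ph(seed=5, n=2000, betas=[], lambda0=1.7376, gamma0=gam,
                         censor_max=2.5)
        diag = weibull_loglog_diagnostic(ds)
        assert diag.r_squared > 0.98
        assert abs(diag.slope - gam) < 0.1

    def test_lognormal_data_fits_worse(self):
        gam = 1.0769
        ds_w = simulate_ph(seed=6, n=2000, betas=[], lambda0=1.7376, gamma0=gam,
                           censor_max=2.5)
        rng = np.random.default_rng(6)
        tt = rng.lognormal(mean=-0.7, sigma=1.4, size=2000)
        cens = rng.uniform(0, 2.5, 2000)
        ds_ln = SurvivalDataset(np.minimum(tt, cens), (tt <= cens).astype(int),
                                pd.DataFrame(index=range(2000)))
        r2_w = weibull_loglog_diagnostic(ds_w).r_squared
        r2_ln = weibull_loglog_diagnostic(ds_ln).r_squared
        assert r2_ln < r2_w - 0.01

    def test_single_event_rejected(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 0, 0],
                             pd.DataFrame(index=range(3)))
        with pytest.raises(ValidationError):
            weibull_loglog_diagnostic(ds)
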