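import itertools

import numpy as np
import pandas as pd
import pytest

from mrsurv.dataset import SurvivalDataset, ValidationError
from mrsurv.evaluation import (
    clinical_associations,
    compare_cstats,
    cstat_censored,
    kaplan_meier,
    mortality_rate,
)

from conftest import simulate_ph


def brute_force_concordance(time, event, risk):
    """Independent exhaustive-pair oracle (usable pairs, ties = 0.5)."""
    num = den = 0.0
    for i, j in itertools.permutations(range(len(time)), 2):
        usable = event[i] == 1 and (
            time[i] < time[j] or (time[i] == time[j] and event[j] == 0))
        if not usable:
            continue
        den += 1
        if risk[i] > risk[j]:
            num += 1
        elif risk[i] == risk[j]:
            num += 0.5
    return num / den


class TestCstat:
    def test_perfect_ordering_gives_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.1, 5, 20)
        ds = SurvivalDataset(t, np.ones(20, int), pd.DataFrame(index=range(20)))
        risk = -t  # highest risk fails first
        assert cstat_censored(risk, ds, n_boot=50).cstat == 1.0

    def test_four_patient_hand_example(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                             pd.DataFrame(index=range(4)))
        risk = np.array([0.9, 0.1, 0.8, 0.2])
        expected = brute_force_concordance(ds.time, ds.event, risk)  # = 4/6
        res = cstat_censored(risk, ds, n_boot=0)
        assert expected == pytest.approx(4 / 6)
        assert res.cstat == pytest.approx(expected)
        assert res.n_usable_pairs == 6

    def test_matches_exhaustive_oracle_with_censoring(self):
        ds = simulate_ph(seed=4, n=150, betas=[1.0], censor_max=1.0)
        risk = ds.covariates["x0"].to_numpy()
        res = cstat_censored(risk, ds, n_boot=100, seed=1)
        oracle = brute_force_concordance(ds.time, ds.event, risk)
        assert res.cstat == pytest.approx(oracle, abs=1e-12)
        assert res.ci_low <= res.cstat <= res.ci_high

    def test_uncensored_matches_lifelines_concordance(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(3)
        t = rng.exponential(size=100)
        risk = rng.normal(size=100)
        ds = SurvivalDataset(t, np.ones(100, int), pd.DataFrame(index=range(100)))
        mine = cstat_censored(risk, ds, n_boot=0).cstat
        assert mine == pytest.approx(concordance_index(t, -risk), abs=1e-12)

    def test_independent_risk_near_half(self):
        ds = simulate_ph(seed=5, n=2000, betas=[0.0], censor_max=2.0)
        risk = np.random.default_rng(9).normal(size=2000)
        assert cstat_censored(risk, ds, n_boot=0).cstat == pytest.approx(0.5, abs=0.03)

    def test_no_usable_pairs_rejected(self):
        ds = SurvivalDataset([1.0, 2.0], [0, 0], pd.DataFrame(index=range(2)))
        with pytest.raises(ValidationError):
            cstat_censored(np.array([0.1, 0.2]), ds)


class TestCompare:
    def test_identical_predictors_null(self):
        ds = simulate_ph(seed=6, n=150, betas=[0.8])
        risk = ds.covariates["x0"].to_numpy()
        res = compare_cstats(risk, risk.copy(), ds, n_boot=200, seed=2)
        assert res.difference == 0.0
        assert res.p_value > 0.9

    def test_informative_beats_noise(self):
        detections = 0
        for s in range(4):
            ds = simulate_ph(seed=30 + s, n=300, betas=[1.2], censor_max=3.0)
            risk_a = ds.covariates["x0"].to_numpy()
            risk_b = np.random.default_rng(s).normal(size=300)
            res = compare_cstats(risk_a, risk_b, ds, n_boot=400, seed=s)
            detections += res.p_value < 0.01
        assert detections >= 3

    def test_small_heavily_censored_no_crash(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0.1, 2, 10)
        e = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 1])
        ds = SurvivalDataset(t, e, pd.DataFrame(index=range(10)))
        res = compare_cstats(rng.normal(size=10), rng.normal(size=10), ds,
                             n_boot=200, seed=3)
        assert np.isfinite(res.p_value)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survivor(self):
        t = np.arange(1.0, 11.0)
        ds = SurvivalDataset(t, np.ones(10, int), pd.DataFrame(index=range(10)))
        km = kaplan_meier(ds)
        for k, tt in enumerate(t):
            assert km.survival_at(tt) == pytest.approx(1 - (k + 1) / 10)

    def test_hand_worked_product_limit(self):
        # times 1, 2+, 3: S(1) = 2/3, censor at 2, S(3) = 2/3 * 0/1 = 0
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 0, 1], pd.DataFrame(index=range(3)))
        km = kaplan_meier(ds)
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [0, 0, 0], pd.DataFrame(index=range(3)))
        km = kaplan_meier(ds)
        assert km.survival_at(3.0) == 1.0

    def test_stratified_risk_table(self):
        ds = simulate_ph(seed=8, n=60, betas=[1.0])
        strata = (ds.covariates["x0"] > 0).to_numpy().astype(int)
        km = kaplan_meier(ds, strata=strata)
        assert set(km.table["stratum"]) == {0, 1}
        for lab in (0, 1):
            sub = km.table[km.table["stratum"] == lab]
            assert sub["events"].sum() == ds.event[strata == lab].sum()


class TestMortalityRate:
    def test_direct_arithmetic(self):
        ds = SurvivalDataset([1.0, 3.0], [1, 1], pd.DataFrame(index=range(2)))
        res = mortality_rate(ds)
        assert res.rate_per_100py == pytest.approx(50.0)
        assert res.events == 2 and res.person_years == 4.0

    def test_horizon_truncation(self):
        # event at 2y is censored by a 1y horizon and contributes 1 py
        ds = SurvivalDataset([2.0], [1], pd.DataFrame(index=range(1)))
        res = mortality_rate(ds, horizon=1.0)
        assert res.events == 0 and res.person_years == 1.0

    def test_one_year_rate_matches_weibull_person_time_integral(self):
        from scipy.integrate import quad

        lam, gam = 1.7376, 1.0769
        ds = simulate_ph(seed=9, n=20000, betas=[], lambda0=lam, gamma0=gam,
                         censor_max=1e9)
        res = mortality_rate(ds, horizon=1.0)
        surv = lambda t: np.exp(-((lam * t) ** gam))
        expected_events = 1.0 - surv(1.0)
        expected_py = quad(surv, 0, 1.0)[0]
        rate = 100 * expected_events / expected_py
        assert res.rate_per_100py == pytest.approx(rate, rel=0.03)

    def test_order_and_record_split_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0.2, 3, 50)
        e = rng.integers(0, 2, 50)
        ds = SurvivalDataset(t, e, pd.DataFrame(index=range(50)))
        perm = rng.permutation(50)
        shuffled = SurvivalDataset(t[perm], e[perm], pd.DataFrame(index=range(50)))
        assert mortality_rate(ds).rate_per_100py == pytest.approx(
            mortality_rate(shuffled).rate_per_100py)
        # splitting one record at an intermediate time conserves person-time
        t2 = np.r_[t, [t[0] / 2, t[0] / 2]][1:]
        e2 = np.r_[e, [0, e[0]]][1:]
        ds2 = SurvivalDataset(t2, e2, pd.DataFrame(index=range(51)))
        assert mortality_rate(ds2).events == mortality_rate(ds).events
        assert mortality_rate(ds2).person_years == pytest.approx(ds.time.sum())


class TestClinicalAssociations:
    def test_spearman_copula_calibration(self, study_cohort_large):
        from mrsurv.synthetic import inject_clinical

        full = inject_clinical(study_cohort_large, {"SDMA": 0.46}, seed=7)
        tab = clinical_associations(full, ["LDH"], ["SDMA"])
        row = tab.iloc[0]
        assert row["test"] == "spearman"
        assert abs(row["estimate"] - 0.46) < 0.03
        assert row["p"] < 1e-6

    def test_null_pairs_rarely_significant(self):
        rng = np.random.default_rng(4)
        n = 1000
        cov = pd.DataFrame(rng.normal(size=(n, 22)),
                           columns=[f"v{j}" for j in range(2)] + [f"m{j}" for j in range(20)])
        ds = SurvivalDataset(np.ones(n), np.ones(n, int), cov)
        tab = clinical_associations(ds, ["v0", "v1"], [f"m{j}" for j in range(20)])
        assert len(tab) == 40
        assert (tab["p"] < 0.05).mean() < 0.15

    def test_binary_and_multigroup_tests_chosen(self):
        rng = np.random.default_rng(5)
        n = 200
        cov = pd.DataFrame({
            "smoke": rng.integers(0, 2, n),
            "stage": rng.integers(1, 4, n),
            "met": rng.normal(size=n),
        })
        ds = SurvivalDataset(np.ones(n), np.ones(n, int), cov)
        tab = clinical_associations(ds, ["smoke", "stage"], ["met"])
        assert list(tab["test"]) == ["mann-whitney", "kruskal-wallis"]
        assert (tab["p"] > 0.001).all()

    def test_constant_column_flagged_undefined(self):
        cov = pd.DataFrame({"flat": np.ones(30), "met": np.arange(30.0)})
        ds = SurvivalDataset(np.ones(30), np.ones(30, int), cov)
        tab = clinical_associations(ds, ["flat"], ["met"])
        assert tab.iloc[0]["test"] == "undefined" and np.isnan(tab.iloc[0]["p"])

    def test_bh_adjustment_flag(self):
        rng = np.random.default_rng(6)
        cov = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        ds = SurvivalDataset(np.ones(100), np.ones(100, int), cov)
        tab = clinical_associations(ds, ["a"], ["b", "c", "d"], fdr=True)
        assert "p_bh" in tab.columns
        assert (tab["p_bh"] >= tab["p"] - 1e-12).all()
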