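import numpy as np
import pandas as pd
import pytest

from mrsurv.dataset import SurvivalDataset, ValidationError
from mrsurv.forest import (
    ForestConfig,
    VariableImportance,
    apply_importance_screen,
    grow_forest,
    impute_missing_in_forest,
    logrank_statistic,
    permutation_importance,
    screen_covariates,
)

from conftest import simulate_ph


def signal_cohort(seed, n=200, n_noise=9):
    """One strongly prognostic binary covariate plus pure noise."""
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, size=n).astype(float)
    lp = 1.5 * g
    tt = -np.log(rng.uniform(size=n)) * np.exp(-lp)
    cens = rng.uniform(0, 3.0, n)
    cov = pd.DataFrame({"signal": g})
    for j in range(n_noise):
        cov[f"noise{j}"] = rng.normal(size=n)
    return SurvivalDataset(np.minimum(tt, cens), (tt <= cens).astype(int), cov)


class TestScreen:
    def test_missingness_rule(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(rng.normal(size=(100, 10)),
                           columns=[f"c{j}" for j in range(10)])
        cov.loc[:29, "c0"] = np.nan                       # 30% missing -> out
        cov.loc[:24, "c1"] = np.nan                       # exactly 25% -> kept
        ds = SurvivalDataset(np.ones(100), np.ones(100, int), cov)
        res = screen_covariates(ds, 0.25)
        assert res.removed == ["c0"]
        assert "c1" in res.retained and len(res.retained) == 9

    def test_no_missingness_keeps_all(self, simple_cohort):
        assert screen_covariates(simple_cohort).removed == []


class TestLogrankSplitStatistic:
    def test_matches_lifelines_on_hand_built_node(self):
        from lifelines.statistics import logrank_test

        # 8-patient node with ties and censoring
        time = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1, 1, 0])
        group = np.array([True, True, False, True, False, False, True, False])
        mine = logrank_statistic(time, event, group)
        ref = logrank_test(time[group], time[~group],
                           event[group], event[~group]).test_statistic
        assert mine == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_on_random_nodes(self, seed):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(seed)
        n = 40
        time = np.round(rng.exponential(size=n), 2) + 0.01  # provoke ties
        event = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n).astype(bool)
        if event[group].sum() == 0 or event[~group].sum() == 0:
            pytest.skip("degenerate draw")
        mine = logrank_statistic(time, event, group)
        ref = logrank_test(time[group], time[~group],
                           event[group], event[~group]).test_statistic
        assert mine == pytest.approx(ref, abs=1e-8)


class TestGrowForest:
    def test_learnable_signal_beats_chance(self):
        ds = signal_cohort(seed=1)
        f = grow_forest(ds, ForestConfig(n_trees=500, seed=2))
        assert f.oob_error < 0.45

    def test_pure_noise_near_chance(self):
        ds = simulate_ph(seed=3, n=200, betas=np.zeros(10), censor_max=3.0)
        f = grow_forest(ds, ForestConfig(n_trees=500, seed=4))
        assert 0.45 <= f.oob_error <= 0.55

    def test_seeded_determinism(self):
        ds = signal_cohort(seed=5, n=100)
        cfg = ForestConfig(n_trees=100, seed=9)
        f1, f2 = grow_forest(ds, cfg), grow_forest(ds, cfg)
        assert f1.oob_error == f2.oob_error
        np.testing.assert_array_equal(f1.oob_mortality, f2.oob_mortality)
        v1, v2 = permutation_importance(f1), permutation_importance(f2)
        pd.testing.assert_frame_equal(v1.table, v2.table)

    def test_more_trees_do_not_hurt_oob(self):
        # ensemble error stabilises/improves with forest size (jitter allowed)
        errs = {m: [] for m in (50, 500)}
        for s in range(3):
            ds = signal_cohort(seed=20 + s)
            for m in errs:
                errs[m].append(grow_forest(ds, ForestConfig(n_trees=m, seed=s)).oob_error)
        assert np.mean(errs[500]) <= np.mean(errs[50]) + 0.02

    def test_missing_values_rejected(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 0],
                             pd.DataFrame({"a": [1.0, np.nan, 2.0]}))
        with pytest.raises(ValidationError, match="missing"):
            grow_forest(ds, ForestConfig(n_trees=10))

    def test_too_few_events_rejected(self):
        ds = SurvivalDataset([1.0, 2.0], [1, 0], pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValidationError):
            grow_forest(ds, ForestConfig(n_trees=10))


class TestImportance:
    def test_signal_ranked_first_with_unit_relative_importance(self):
        ds = signal_cohort(seed=6)
        f = grow_forest(ds, ForestConfig(n_trees=500, seed=7))
        v = permutation_importance(f)
        assert v.table.index[0] == "signal"
        assert v.table.loc["signal", "relative_importance"] == 1.0
        assert (v.table["relative_importance"] <= 1.0).all()

    def test_constant_covariate_zero_importance(self):
        ds = signal_cohort(seed=8, n=150, n_noise=3)
        cov = ds.covariates.copy()
        cov["flat"] = 1.0
        ds = SurvivalDataset(ds.time, ds.event, cov)
        f = grow_forest(ds, ForestConfig(n_trees=300, seed=1))
        v = permutation_importance(f)
        assert v.table.loc["flat", "score"] == 0.0

    def test_permuted_outcome_kills_importance(self):
        ds = signal_cohort(seed=9, n=200)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n)
        shuffled = SurvivalDataset(ds.time[perm], ds.event[perm], ds.covariates)
        f = grow_forest(shuffled, ForestConfig(n_trees=500, seed=2))
        v = permutation_importance(f)
        assert np.abs(v.table["score"]).max() < 0.02


class TestImportanceScreen:
    def test_at_least_20_percent_rule(self):
        v = VariableImportance.from_scores(["a", "b", "c"],
                                           np.array([1.0, 0.5, 0.19]))
        assert apply_importance_screen(v, 0.20) == ["a", "b"]

    def test_clinical_strictly_greater_rule(self):
        v = VariableImportance.from_scores(["a", "b", "c", "d"],
                                           np.array([1.0, 0.35, 0.34, 0.33]))
        assert apply_importance_screen(v, 0.34, strict=True) == ["a", "b"]

    def test_all_nonpositive_selects_nothing(self):
        v = VariableImportance.from_scores(["a", "b"], np.array([-0.1, -0.2]))
        assert apply_importance_screen(v, 0.20) == []


class TestImputation:
    def test_complete_data_returned_unchanged(self, simple_cohort):
        out = impute_missing_in_forest(simple_cohort, ForestConfig(n_trees=20, seed=0))
        assert out is simple_cohort

    def test_mcar_mean_recovered(self):
        ds = simulate_ph(seed=12, n=300, betas=[0.8, 0.0], censor_max=3.0)
        rng = np.random.default_rng(1)
        cov = ds.covariates.copy()
        holes = rng.uniform(size=300) < 0.10
        truth = cov.loc[holes, "x0"].to_numpy()
        cov.loc[holes, "x0"] = np.nan
        holed = SurvivalDataset(ds.time, ds.event, cov)
        out = impute_missing_in_forest(holed, ForestConfig(n_trees=100, seed=3))
        assert not out.covariates.isna().any().any()
        # observed entries untouched
        pd.testing.assert_series_equal(out.covariates.loc[~holes, "x0"],
                                       ds.covariates.loc[~holes, "x0"])
        imput = out.covariates.loc[holes, "x0"].to_numpy()
        se = ds.covariates["x0"].std() / np.sqrt(holes.sum())
        assert abs(imput.mean() - ds.covariates["x0"].mean()) < 3 * se
        assert truth.size == imput.size

    def test_structure_beats_marginal_draws(self):
        # a perfectly rank-correlated companion should sharpen imputation
        rng = np.random.default_rng(7)
        n = 250
        x = rng.normal(size=n)
        twin = np.exp(x)  # monotone in x
        lp = 1.2 * x
        tt = -np.log(rng.uniform(size=n)) * np.exp(-lp)
        cens = rng.uniform(0, 3, n)
        cov = pd.DataFrame({"x": x, "twin": twin})
        holes = rng.uniform(size=n) < 0.15
        truth = x[holes]
        cov.loc[holes, "x"] = np.nan
        ds = SurvivalDataset(np.minimum(tt, cens), (tt <= cens).astype(int), cov)
        out = impute_missing_in_forest(ds, ForestConfig(n_trees=150, seed=5))
        rmse = np.sqrt(np.mean((out.covariates.loc[holes, "x"] - truth) ** 2))
        marg_rng = np.random.default_rng(11)
        obs = x[~holes]
        marg = marg_rng.choice(obs, size=(200, holes.sum()), replace=True)
        rmse_marg = np.sqrt(np.mean((marg - truth) ** 2))
        assert rmse < rmse_marg

    def test_fully_missing_covariate_rejected(self):
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 0],
                             pd.DataFrame({"a": [np.nan] * 3}))
        with pytest.raises(ValidationError):
            impute_missing_in_forest(ds, ForestConfig(n_trees=10))

    def test_above_threshold_rejected(self):
        cov = pd.DataFrame({"a": [np.nan] * 40 + [1.0] * 60})
        ds = SurvivalDataset(np.ones(100), np.ones(100, int), cov)
        with pytest.raises(ValidationError, match="threshold"):
            impute_missing_in_forest(ds, ForestConfig(n_trees=10))
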