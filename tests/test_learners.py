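import numpy as np
import pandas as pd
import pytest

from ipwlearn.learners import (
    BootstrapScheme,
    ForestConfig,
    ForestLearner,
    GLMLearner,
    fit_forest,
    fit_glm,
    forest_score,
    glm_score,
    oob_auc,
    plan_bootstrap,
    tune_forest,
)
from ipwlearn.tables import OUTCOME_COL, WEIGHT_COL


def _fold(n_cases=20, n_controls=100):
    return np.array([1] * n_cases + [0] * n_controls)


def _separable_frame(n=80, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.permutation([1] * (n // 4) + [0] * (n - n // 4))
    x = y * 2.0 + rng.normal(0, 0.1, n)
    return pd.DataFrame({OUTCOME_COL: y, "x": x, "z": rng.normal(size=n)})


class TestPlanBootstrap:
    def test_under_sampling_draw_count_and_composition(self):
        y = _fold(20, 100)
        plans = plan_bootstrap(BootstrapScheme("under"), y, n_trees=400, seed=0)
        assert all(len(idx) == 40 for idx in plans)  # round(120 * 40/120)
        mean_cases = np.mean([(y[idx] == 1).sum() for idx in plans])
        assert mean_cases == pytest.approx(20, abs=1.0)

    def test_over_sampling_composition(self):
        y = _fold(20, 100)
        plans = plan_bootstrap(BootstrapScheme("over"), y, n_trees=400, seed=0)
        assert all(len(idx) == 200 for idx in plans)
        mean_cases = np.mean([(y[idx] == 1).sum() for idx in plans])
        assert mean_cases == pytest.approx(100, abs=2.5)

    def test_standard_bootstrap_expectation(self):
        y = _fold(20, 100)
        plans = plan_bootstrap(BootstrapScheme("standard"), y, n_trees=400, seed=1)
        assert all(len(idx) == 120 for idx in plans)
        mean_cases = np.mean([(y[idx] == 1).sum() for idx in plans])
        assert mean_cases == pytest.approx(20, rel=0.05)

    def test_ipw_scheme_oversamples_heavy_rows(self):
        y = _fold(5, 50)
        w = np.where(y == 1, 1.0, 10.0)
        plans = plan_bootstrap(BootstrapScheme("ipw"), y, n_trees=300, seed=2, ipw=w)
        mean_cases = np.mean([(y[idx] == 1).sum() for idx in plans])
        # case mass 5, control mass 500 -> expected cases 55 * 5/505
        assert mean_cases == pytest.approx(55 * 5 / 505, rel=0.15)

    def test_errors(self):
        with pytest.raises(ValueError):
            plan_bootstrap(BootstrapScheme("under"), np.zeros(10, dtype=int), 5, 0)
        with pytest.raises(ValueError):
            plan_bootstrap(BootstrapScheme("ipw"), _fold(2, 8), 5, 0)  # no weights
        with pytest.raises(ValueError):
            BootstrapScheme("smote")


class TestForest:
    def test_separating_feature_gives_perfect_training_auc(self):
        from ipwlearn.evaluation import PredictionSet, weighted_auc

        df = _separable_frame()
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=100, seed=0))
        s = forest_score(model, df)
        y = df[OUTCOME_COL].to_numpy()
        assert weighted_auc(PredictionSet(s[y == 1], s[y == 0])) == 1.0

    def test_scores_are_vote_fractions_in_unit_interval(self):
        df = _separable_frame(seed=1)
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=7, seed=0))
        s = forest_score(model, df)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.isin(np.round(s * 7), np.arange(8)))  # multiples of 1/n_trees

    def test_single_giant_leaf_predicts_majority(self):
        df = _separable_frame(n=40, seed=2)
        cfg = ForestConfig(n_trees=1, mtry=2, min_node_size=len(df), seed=0)
        model = fit_forest(df, ["x", "z"], cfg)
        s = forest_score(model, df)
        assert np.unique(s).size == 1
        assert s[0] == 0.0  # controls are the majority class

    def test_same_seed_reproduces_predictions(self):
        df = _separable_frame(seed=3)
        probe = _separable_frame(seed=4)
        a = forest_score(fit_forest(df, ["x", "z"], ForestConfig(n_trees=50, seed=9)), probe)
        b = forest_score(fit_forest(df, ["x", "z"], ForestConfig(n_trees=50, seed=9)), probe)
        c = forest_score(fit_forest(df, ["x", "z"], ForestConfig(n_trees=50, seed=10)), probe)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_inbag_membership_recorded(self):
        df = _separable_frame(seed=5)
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=30, seed=0))
        assert model.inbag.shape == (30, len(df))
        # full-size bootstrap leaves ~36.8% out per tree
        oob_frac = 1 - model.inbag.mean()
        assert 0.25 < oob_frac < 0.45

    def test_single_class_training_rejected(self):
        df = _separable_frame()
        df[OUTCOME_COL] = 0
        with pytest.raises(ValueError):
            fit_forest(df, ["x", "z"], ForestConfig(n_trees=5))

    def test_missing_feature_rejected(self):
        df = _separable_frame()
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=5, seed=0))
        with pytest.raises(ValueError, match="missing"):
            forest_score(model, df[[OUTCOME_COL, "x"]])


class TestOOB:
    def test_oob_auc_high_on_separable_data(self):
        df = _separable_frame(n=120, seed=6)
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=200, seed=0))
        assert oob_auc(model, df) > 0.9

    def test_always_inbag_observation_excluded(self):
        df = _separable_frame(n=30, seed=7)
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=3, seed=0))
        # force row 0 in-bag everywhere: the statistic must still be computable
        model.inbag[:, 0] = True
        auc_without = oob_auc(model, df)
        assert 0.0 <= auc_without <= 1.0

    def test_no_usable_observations_errors(self):
        df = _separable_frame(n=30, seed=8)
        model = fit_forest(df, ["x", "z"], ForestConfig(n_trees=2, seed=0))
        model.inbag[:] = True
        with pytest.raises(ValueError, match="out-of-bag"):
            oob_auc(model, df)


class TestTuneForest:
    def test_budget_respected_and_trace_complete(self):
        df = _separable_frame(n=100, seed=9)
        cfg, trace = tune_forest(
            df, ["x", "z"], budget=50, seed=0, n_trees=30, return_trace=True
        )
        assert len(trace) == 50
        assert all("oob_auc" in rec for rec in trace)
        assert cfg.mtry in (1, 2)
        assert 0.2 <= cfg.scheme.sample_fraction <= 1.0

    def test_budget_out_of_range_rejected(self):
        df = _separable_frame()
        with pytest.raises(ValueError):
            tune_forest(df, ["x"], budget=10)

    def test_returns_argmax_of_trace(self):
        df = _separable_frame(n=100, seed=10)
        cfg, trace = tune_forest(
            df, ["x", "z"], budget=50, seed=3, n_trees=30, return_trace=True
        )
        best = max(rec["oob_auc"] for rec in trace)
        chosen = [
            rec
            for rec in trace
            if rec["mtry"] == cfg.mtry
            and rec["min_node_size"] == cfg.min_node_size
            and rec["sample_fraction"] == cfg.scheme.sample_fraction
        ]
        assert any(rec["oob_auc"] == best for rec in chosen)


class TestGLM:
    def test_no_features_gives_intercept_only_constant_scores(self):
        df = _separable_frame(seed=11)
        model = fit_glm(df, [], use_ipw=False)
        s = glm_score(model, df)
        assert np.unique(s).size == 1

    def test_unit_weights_match_unweighted_fit(self):
        rng = np.random.default_rng(12)
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        df = pd.DataFrame({OUTCOME_COL: y, "x": x})
        df_w = df.copy()
        df_w[WEIGHT_COL] = 1.0
        a = fit_glm(df_w, ["x"], use_ipw=True)
        b = fit_glm(df, ["x"], use_ipw=False)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-8)
        assert a.coef == pytest.approx(b.coef, abs=1e-8)

    def test_ipw_weights_change_the_fit(self, small_phase_two):
        a = fit_glm(small_phase_two, ["age", "bmi"], use_ipw=True)
        b = fit_glm(small_phase_two, ["age", "bmi"], use_ipw=False)
        assert a.intercept != pytest.approx(b.intercept, abs=1e-6)

    def test_strong_feature_predicts_held_out(self):
        rng = np.random.default_rng(13)
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-5 * x))).astype(int)
        df = pd.DataFrame({OUTCOME_COL: y, "x": x})
        model = fit_glm(df.iloc[:400], ["x"], use_ipw=False)
        from ipwlearn.evaluation import PredictionSet, weighted_auc

        test = df.iloc[400:]
        s = glm_score(model, test)
        yt = test[OUTCOME_COL].to_numpy()
        assert weighted_auc(PredictionSet(s[yt == 1], s[yt == 0])) > 0.9

    def test_aliased_column_dropped_with_warning(self):
        df = _separable_frame(seed=14)
        df["x2"] = 2.0 * df["x"]
        with pytest.warns(UserWarning, match="aliased"):
            model = fit_glm(df, ["x", "x2"], use_ipw=False)
        assert len(model.dropped) == 1 and model.dropped[0] in ("x", "x2")

    def test_separation_falls_back_to_ridge(self):
        y = np.array([0] * 10 + [1] * 10)
        x = y.astype(float)  # perfectly separating
        df = pd.DataFrame({OUTCOME_COL: y, "x": x})
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_glm(df, ["x"], use_ipw=False)
        assert np.isfinite(model.coef).all()
        s = glm_score(model, df)
        assert s[y == 1].min() > s[y == 0].max()

    def test_monotone_in_linear_predictor(self):
        df = _separable_frame(seed=15)
        model = fit_glm(df, ["x"], use_ipw=False)
        grid = pd.DataFrame({"x": np.linspace(-3, 3, 11)})
        s = glm_score(model, grid)
        assert np.all(np.diff(s) > 0) or np.all(np.diff(s) < 0)


class TestLearnerWrappers:
    def test_screening_noop_on_marker_free_analysis(self, tiny_phase_two):
        """With no markers there is nothing to screen: toggling screening
        must not change the fitted forest at all."""
        from ipwlearn.screening import ScreenConfig

        a = ForestLearner(marker_set="none", screen=None, n_trees=30)
        b = ForestLearner(marker_set="none", screen=ScreenConfig(), n_trees=30)
        sa = a.fit(tiny_phase_two, seed=3, cache={}).score(tiny_phase_two)
        sb = b.fit(tiny_phase_two, seed=3, cache={}).score(tiny_phase_two)
        assert np.array_equal(sa, sb)

    def test_cache_shares_screening_between_variants(self, tiny_phase_two):
        from ipwlearn import screening as scr
        from ipwlearn.screening import ScreenConfig

        calls = []
        original = scr.lasso_screen

        def counting(*args, **kw):
            calls.append(1)
            return original(*args, **kw)

        cache = {}
        screen = ScreenConfig()
        a = ForestLearner(marker_set="all", screen=screen, n_trees=10)
        b = GLMLearner(marker_set="all", screen=screen)
        import ipwlearn.learners as lrn

        old = lrn.lasso_screen
        lrn.lasso_screen = counting
        try:
            a.fit(tiny_phase_two, seed=1, cache=cache)
            b.fit(tiny_phase_two, seed=1, cache=cache)
        finally:
            lrn.lasso_screen = old
        assert len(calls) == 1
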