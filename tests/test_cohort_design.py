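import numpy as np
import pandas as pd
import pytest

from ipwlearn.cohort import (
    SyntheticConfig,
    default_hvtn_like_config,
    generate_cohort,
    signal_marker_names,
    true_linear_predictor,
)
from ipwlearn.design import InsufficientControlsError, compute_ipw_weights, two_phase_sample
from ipwlearn.evaluation import PredictionSet, weighted_auc
from ipwlearn.tables import (
    COVARIATES,
    OUTCOME_COL,
    PHASE2_COL,
    STRATUM_COL,
    WEIGHT_COL,
    marker_columns,
)

from conftest import small_config


class TestDefaultConfig:
    def test_matches_reference_design(self):
        cfg = default_hvtn_like_config()
        assert cfg.p_tcell + cfg.p_antibody == 420
        assert cfg.controls_per_case == 5
        # expected phase-two composition: 25 cases, 125 controls
        assert cfg.cohort_size * cfg.case_rate == pytest.approx(25)
        assert default_hvtn_like_config() == default_hvtn_like_config()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(cohort_size=0).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(case_rate=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(n_signal_tcell=10**6).validate()
        with pytest.raises(ValueError):
            SyntheticConfig(stratum_mixing=(0.5, 0.6)).validate()


class TestGenerateCohort:
    def test_reproducible_and_seed_sensitive(self):
        cfg = small_config(seed=1)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(cfg.replace(seed=2))
        assert not a[OUTCOME_COL].equals(c[OUTCOME_COL])

    def test_unique_subjects_and_tagged_markers(self, small_cohort):
        assert small_cohort["subject_id"].is_unique
        cfg = small_config()
        assert len(marker_columns(small_cohort, "tcell")) == cfg.p_tcell
        assert len(marker_columns(small_cohort, "antibody")) == cfg.p_antibody
        assert set(COVARIATES) <= set(small_cohort.columns)

    def test_null_model_case_rate(self):
        cfg = small_config(
            seed=3,
            cohort_size=4000,
            case_rate=0.1,
            linear_effect_size=0.0,
            interaction_effect_size=0.0,
            covariate_effect_sizes=(0.0, 0.0, 0.0),
        )
        df = generate_cohort(cfg)
        sd = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(df[OUTCOME_COL].mean() - 0.1) < 3 * sd

    def test_case_rate_calibration_with_signal(self):
        cfg = small_config(seed=4, cohort_size=20000, case_rate=0.05)
        df = generate_cohort(cfg)
        sd = np.sqrt(0.05 * 0.95 / 20000)
        assert abs(df[OUTCOME_COL].mean() - 0.05) < 4 * sd

    def test_true_linear_predictor_is_discriminative(self):
        # Monte-Carlo oracle: with strong effects, the generating-model
        # linear predictor must rank cases above controls.
        cfg = small_config(seed=9, cohort_size=20000, case_rate=0.05, linear_effect_size=2.0)
        df = generate_cohort(cfg)
        covs = df[list(COVARIATES)].to_numpy()
        tc = df[marker_columns(df, "tcell")].to_numpy()
        ab = df[marker_columns(df, "antibody")].to_numpy()
        eta = true_linear_predictor(cfg, covs, tc, ab)
        y = df[OUTCOME_COL].to_numpy()
        auc = weighted_auc(PredictionSet(eta[y == 1], eta[y == 0]))
        assert auc > 0.8

    def test_marker_block_correlation_structure(self):
        cfg = small_config(seed=5, cohort_size=8000, marker_block_correlation=0.5)
        df = generate_cohort(cfg)
        tc = df[marker_columns(df, "tcell")].to_numpy()
        within = np.corrcoef(tc[:, 0], tc[:, 1])[0, 1]  # same block (size 6)
        across = np.corrcoef(tc[:, 0], tc[:, 7])[0, 1]  # different blocks
        assert within == pytest.approx(0.5, abs=0.05)
        assert across == pytest.approx(0.0, abs=0.05)

    def test_signal_marker_names_resolve(self, small_cohort):
        names = signal_marker_names(small_config())
        for cols in names.values():
            assert set(cols) <= set(small_cohort.columns)


class TestTwoPhaseSample:
    def test_all_cases_and_five_controls_per_case(self, small_cohort):
        out = two_phase_sample(small_cohort, controls_per_case=5, seed=0)
        y, p2 = out[OUTCOME_COL], out[PHASE2_COL]
        assert ((y == 1) <= (p2 == 1)).all()
        for s, grp in out.groupby(STRATUM_COL):
            k = int((grp[OUTCOME_COL] == 1).sum())
            n_ctrl_sampled = int(((grp[OUTCOME_COL] == 0) & (grp[PHASE2_COL] == 1)).sum())
            assert n_ctrl_sampled == 5 * k
        assert int(((y == 0) & (p2 == 1)).sum()) == 5 * int(y.sum())

    def test_caseless_stratum_contributes_no_controls(self):
        df = pd.DataFrame(
            {
                "subject_id": range(10),
                OUTCOME_COL: [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                STRATUM_COL: ["a"] * 6 + ["b"] * 4,
                "age": 0.0,
                "bmi": 0.0,
                "risk_score": 0.0,
            }
        )
        out = two_phase_sample(df, controls_per_case=5, seed=0)
        assert out.loc[out[STRATUM_COL] == "b", PHASE2_COL].sum() == 0

    def test_insufficient_controls_names_stratum(self):
        df = pd.DataFrame(
            {
                "subject_id": range(4),
                OUTCOME_COL: [1, 1, 0, 0],
                STRATUM_COL: ["s1"] * 4,
                "age": 0.0,
                "bmi": 0.0,
                "risk_score": 0.0,
            }
        )
        with pytest.raises(InsufficientControlsError, match="s1"):
            two_phase_sample(df, controls_per_case=5, seed=0)

    def test_reseeding_changes_selection_not_weights(self, small_cohort):
        a = compute_ipw_weights(two_phase_sample(small_cohort, 5, seed=1))
        b = compute_ipw_weights(two_phase_sample(small_cohort, 5, seed=2))
        assert set(a["subject_id"]) != set(b["subject_id"])
        wa = a.groupby(STRATUM_COL)[WEIGHT_COL].max().sort_index()
        wb = b.groupby(STRATUM_COL)[WEIGHT_COL].max().sort_index()
        pd.testing.assert_series_equal(wa, wb)


class TestIPWWeights:
    def test_case_weight_one_control_weight_ratio(self, small_phase_two, small_cohort):
        cases = small_phase_two[OUTCOME_COL] == 1
        assert (small_phase_two.loc[cases, WEIGHT_COL] == 1.0).all()
        assert (small_phase_two.loc[~cases, WEIGHT_COL] >= 1.0).all()

    def test_horvitz_thompson_totals_per_stratum(self, small_phase_two, small_cohort):
        cohort_ctrl = (
            small_cohort[small_cohort[OUTCOME_COL] == 0].groupby(STRATUM_COL).size()
        )
        sampled = small_phase_two[small_phase_two[OUTCOME_COL] == 0]
        ht = sampled.groupby(STRATUM_COL)[WEIGHT_COL].sum()
        for s, total in ht.items():
            assert total == pytest.approx(cohort_ctrl[s], abs=1e-9)

    def test_exhaustive_sampling_gives_unit_weights(self):
        df = pd.DataFrame(
            {
                "subject_id": range(6),
                OUTCOME_COL: [1, 0, 0, 0, 0, 0],
                STRATUM_COL: ["a"] * 6,
                "age": 0.0,
                "bmi": 0.0,
                "risk_score": 0.0,
            }
        )
        out = compute_ipw_weights(two_phase_sample(df, controls_per_case=5, seed=0))
        assert (out[WEIGHT_COL] == 1.0).all()

    def test_ratio_oracle(self):
        # 60 cohort controls, 12 sampled -> weight 5.0
        df = pd.DataFrame(
            {
                "subject_id": range(64),
                OUTCOME_COL: [1] * 4 + [0] * 60,
                STRATUM_COL: ["s"] * 64,
                "age": 0.0,
                "bmi": 0.0,
                "risk_score": 0.0,
            }
        )
        out = compute_ipw_weights(two_phase_sample(df, controls_per_case=3, seed=0))
        ctrl = out[out[OUTCOME_COL] == 0]
        assert len(ctrl) == 12
        assert (ctrl[WEIGHT_COL] == 5.0).all()

    def test_unsampled_case_rejected(self, small_cohort):
        bad = small_cohort.copy()
        bad[PHASE2_COL] = 0
        with pytest.raises(ValueError, match="phase2"):
            compute_ipw_weights(bad)
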