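"""Orchestration of the table-style experiments on synthetic (or supplied) data.

Each ``run_*`` function builds a dictionary of learner variants, evaluates
them jointly with :func:`ipwlearn.evaluation.cv_auc_multi` — so every
variant sees identical fold plans per replicate and paired signed-rank
comparisons are valid — and writes a tidy summary CSV plus a long
per-replicate CSV.

The experiment grids:

- screening x balancing grid: four bootstrap schemes (standard, under,
  over, IPW) with and without lasso screening;
- tuning: default forest vs OOB-AUC-tuned forest (screening on, no
  balancing or IPW);
- GLM vs forest: both learners on every marker set, with and without the
  clinical covariates (screening and IPW on for both);
- stacking: four forest+GLM stacks and two forest baselines, with the
  mean Pearson correlation between candidate out-of-sample scores
  reported per stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SyntheticConfig, default_hvtn_like_config, generate_cohort
from .design import compute_ipw_weights, two_phase_sample
from .evaluation import WeightedAUCResult, cv_auc_multi
from .learners import BootstrapScheme, ForestLearner, GLMLearner, tune_forest
from .screening import ScreenConfig
from .stacking import StackLearner, score_dissimilarity
from .tables import (
    ID_COL,
    OUTCOME_COL,
    PHASE2_COL,
    WEIGHT_COL,
    feature_columns,
    marker_columns,
    read_table,
)

__all__ = [
    "ExperimentConfig",
    "hvtn_like_phase_two",
    "screening_grid_scenario",
    "disjoint_signal_config",
    "disjoint_signal_dataset",
    "load_phase_two",
    "run_screening_balancing_grid",
    "run_tuning_experiment",
    "run_glm_vs_rf",
    "run_stacking_experiment",
    "export_scores",
]

MARKER_SET_LABELS = {
    "all": "All markers",
    "tcell": "T cell markers",
    "antibody": "Antibody markers",
    "none": "No markers",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared settings of one experiment run."""

    synthetic: SyntheticConfig | None = None
    data_path: str | None = None  # phase-two CSV with a weight column
    marker_sets: tuple[str, ...] = ("all", "tcell", "antibody", "none")
    K: int = 5
    n_replicates: int = 100
    base_seed: int = 0
    n_trees: int = 500
    tune_budget: int = 50
    inner_stack_folds: int = 10
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = [m for m in self.marker_sets if m not in MARKER_SET_LABELS]
        if unknown:
            raise ValueError(f"unknown marker sets: {unknown}")
        if self.synthetic is None and self.data_path is None:
            raise ValueError("either a synthetic config or a data path is required")


def hvtn_like_phase_two(seed: int = 0, cfg: SyntheticConfig | None = None) -> pd.DataFrame:
    """Synthetic phase-two dataset under the default study-like design."""
    cfg = (cfg or default_hvtn_like_config()).replace(seed=seed)
    cohort = generate_cohort(cfg)
    sampled = two_phase_sample(cohort, cfg.controls_per_case, seed=seed + 1)
    return compute_ipw_weights(sampled)


def screening_grid_scenario(seed: int = 0) -> SyntheticConfig:
    """High-noise screening/balancing scenario.

    Two strong antibody correlates (1.5 log-odds per SD) plus six weak
    T-cell markers (0.35 linear and interaction effects) among 412 noise
    columns.  Unscreened forests are diluted by noise (so screening and
    class balancing have room to help), while the screen can isolate the
    dominant markers.  Used with the sparser one-SE screening rule.
    """
    return default_hvtn_like_config().replace(
        n_signal_antibody=2,
        linear_effect_size=1.5,
        n_signal_tcell=6,
        tcell_linear_effect_size=0.35,
        interaction_effect_size=0.35,
        seed=seed,
    )


def disjoint_signal_config(seed: int = 0) -> SyntheticConfig:
    """Large-n scenario with disjoint signal types across marker sets.

    The antibody set carries purely linear signal; the T-cell set carries
    purely interaction (product) signal with its linear terms zeroed.  A
    linear model is therefore the right tool on the antibody set and a
    forest the right tool on the T-cell set — the regime in which stacking
    dissimilar learners is expected to pay off.  The cohort is analysed in
    full (no subsampling), so all weights are 1.
    """
    return SyntheticConfig(
        cohort_size=2000,
        case_rate=0.2,
        n_strata_bmi=1,
        n_strata_race=1,
        p_tcell=10,
        p_antibody=10,
        marker_block_correlation=0.2,
        marker_block_size=5,
        n_signal_tcell=4,
        n_signal_antibody=4,
        linear_effect_size=0.6,
        tcell_linear_effect_size=0.0,
        interaction_effect_size=1.2,
        covariate_effect_sizes=(0.1, 0.1, 0.1),
        seed=seed,
    )


def disjoint_signal_dataset(seed: int = 0, cfg: SyntheticConfig | None = None) -> pd.DataFrame:
    """Fully observed cohort under :func:`disjoint_signal_config` (weights all 1)."""
    cfg = (cfg or disjoint_signal_config()).replace(seed=seed)
    df = generate_cohort(cfg)
    df[PHASE2_COL] = 1
    df[WEIGHT_COL] = 1.0
    return df


def load_phase_two(config: ExperimentConfig) -> pd.DataFrame:
    config.validate()
    if config.data_path is not None:
        return read_table(config.data_path, require_weight=True)
    return hvtn_like_phase_two(config.base_seed, config.synthetic)


# ---------------------------------------------------------------------------


def _results_frame(results: dict[str, WeightedAUCResult], experiment: str) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        variant, marker_set = name.rsplit("@", 1)
        rows.append(
            {
                "experiment": experiment,
                "model": variant,
                "marker_set": marker_set,
                "mean_cv_auc": res.mean_cv_auc,
                "n_replicates": res.n_replicates,
                "K": res.K,
            }
        )
    return pd.DataFrame(rows)


def _replicate_frame(results: dict[str, WeightedAUCResult], experiment: str) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        variant, marker_set = name.rsplit("@", 1)
        for r, v in enumerate(res.per_replicate):
            rows.append(
                {
                    "experiment": experiment,
                    "model": variant,
                    "marker_set": marker_set,
                    "replicate": r,
                    "seed": res.seeds[r],
                    "cv_auc": v,
                }
            )
    return pd.DataFrame(rows)


def _write(config: ExperimentConfig, experiment: str, summary: pd.DataFrame, reps: pd.DataFrame) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / f"{experiment}_summary.csv", index=False)
    reps.to_csv(out / f"{experiment}_replicates.csv", index=False)


def _run(
    config: ExperimentConfig, learners: dict, experiment: str, data: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, WeightedAUCResult]]:
    data = load_phase_two(config) if data is None else data
    results = cv_auc_multi(
        learners, data, K=config.K, n_replicates=config.n_replicates, base_seed=config.base_seed
    )
    summary = _results_frame(results, experiment)
    _write(config, experiment, summary, _replicate_frame(results, experiment))
    return summary, results


class ConstantLearner:
    """Degenerate learner emitting a constant score (the theoretical-null row)."""

    def __init__(self, value: float = 0.5):
        self.value = value

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None):
        value = self.value

        class _Fitted:
            def score(self, data: pd.DataFrame) -> np.ndarray:
                return np.full(len(data), value)

        return _Fitted()


def run_screening_balancing_grid(
    config: ExperimentConfig, data: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, WeightedAUCResult]]:
    """Four bootstrap schemes x screening on/off, per marker set."""
    learners = {}
    for ms in config.marker_sets:
        for kind in ("standard", "under", "over", "ipw"):
            for screened in (False, True):
                name = f"RF_{kind}{'_screen' if screened else ''}@{ms}"
                learners[name] = ForestLearner(
                    marker_set=ms,
                    scheme=BootstrapScheme(kind),
                    screen=config.screen if screened else None,
                    n_trees=config.n_trees,
                )
    return _run(config, learners, "screening_balancing_grid", data)


def run_tuning_experiment(
    config: ExperimentConfig, data: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, WeightedAUCResult]]:
    """Default vs OOB-AUC-tuned forest (screening on; no balancing, no IPW).

    Also writes, per marker set, a tuning trace (one OOB-AUC per evaluated
    configuration) from a single tuning run on the full dataset.
    """
    data = load_phase_two(config) if data is None else data
    learners = {}
    for ms in config.marker_sets:
        common = dict(marker_set=ms, screen=config.screen, n_trees=config.n_trees)
        learners[f"RF@{ms}"] = ForestLearner(**common)
        learners[f"tRF@{ms}"] = ForestLearner(**common, tune_budget=config.tune_budget)
    summary, results = _run(config, learners, "tuning", data)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "tuning_trace.jsonl", "w") as fh:
            for ms in config.marker_sets:
                features = feature_columns(data, ms, include_covariates=True)
                _, trace = tune_forest(
                    data,
                    features,
                    budget=config.tune_budget,
                    seed=config.base_seed,
                    n_trees=config.n_trees,
                    return_trace=True,
                )
                for rec in trace:
                    fh.write(json.dumps({"marker_set": ms, **rec}) + "\n")
    return summary, results


def run_glm_vs_rf(
    config: ExperimentConfig, data: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, WeightedAUCResult]]:
    """GLM vs forest on every marker set, with and without clinical covariates.

    Screening and IPW are applied to both learners (the forest uses the
    IPW bootstrap scheme; the GLM weights its likelihood).  The
    marker-free, covariate-free cell is the theoretical null: a constant
    score whose weighted CV-AUC is exactly 0.5.
    """
    learners = {}
    for ms in config.marker_sets:
        for cov in (False, True):
            tag = "cov" if cov else "nocov"
            if ms == "none" and not cov:
                learners[f"GLM_{tag}@{ms}"] = ConstantLearner()
                learners[f"RF_{tag}@{ms}"] = ConstantLearner()
                continue
            learners[f"GLM_{tag}@{ms}"] = GLMLearner(
                marker_set=ms, include_covariates=cov, screen=config.screen, use_ipw=True
            )
            learners[f"RF_{tag}@{ms}"] = ForestLearner(
                marker_set=ms,
                include_covariates=cov,
                screen=config.screen,
                scheme=BootstrapScheme("ipw"),
                n_trees=config.n_trees,
            )
    return _run(config, learners, "glm_vs_rf", data)


class _CorrRecordingStack:
    """Wraps a StackLearner, recording candidate-score correlations per fit."""

    def __init__(self, stack: StackLearner):
        self.stack = stack
        self.correlations: list[float] = []

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None):
        model = self.stack.fit(train, seed, cache=cache)
        C = score_dissimilarity(model.oos_scores)
        self.correlations.append(float(C[0, 1]))
        return model


def stacking_learners(config: ExperimentConfig) -> dict:
    """The four stacks and two forest baselines of the stacking comparison."""
    screen = config.screen

    def rf(ms: str) -> ForestLearner:
        return ForestLearner(
            marker_set=ms, screen=screen, scheme=BootstrapScheme("ipw"), n_trees=config.n_trees
        )

    def glm(ms: str) -> GLMLearner:
        return GLMLearner(marker_set=ms, screen=screen, use_ipw=True)

    stacks = {
        "Stack_RFtcell_GLMab": (rf("tcell"), glm("antibody")),
        "Stack_RFtcell_GLMall": (rf("tcell"), glm("all")),
        "Stack_RFall_GLMab": (rf("all"), glm("antibody")),
        "Stack_RFall_GLMall": (rf("all"), glm("all")),
    }
    learners: dict = {
        f"{name}@all": _CorrRecordingStack(
            StackLearner(candidates=pair, inner_folds=config.inner_stack_folds)
        )
        for name, pair in stacks.items()
    }
    learners["RF@tcell"] = rf("tcell")
    learners["RF@all"] = rf("all")
    return learners


def run_stacking_experiment(
    config: ExperimentConfig, data: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, WeightedAUCResult], pd.DataFrame]:
    """Stacks vs forest baselines, plus the candidate-score correlation summary."""
    learners = stacking_learners(config)
    summary, results = _run(config, learners, "stacking", data)
    corr_rows = [
        {
            "model": name.rsplit("@", 1)[0],
            "mean_candidate_correlation": float(np.mean(l.correlations)),
        }
        for name, l in learners.items()
        if isinstance(l, _CorrRecordingStack)
    ]
    corr = pd.DataFrame(corr_rows)
    if config.out_dir is not None:
        corr.to_csv(Path(config.out_dir) / "stacking_correlations.csv", index=False)
    return summary, results, corr


def export_scores(
    config: ExperimentConfig,
    learners: dict,
    replicate: int = 0,
    data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Out-of-fold scores of selected models for one CV replicate.

    Returns one row per subject with the case/control label and one score
    column per model — the raw material for score boxplots and
    scatterplots.
    """
    data = load_phase_two(config) if data is None else data
    collected: dict[str, np.ndarray] = {}

    def sink(r: int, name: str, d: pd.DataFrame, scores: np.ndarray) -> None:
        if r == replicate:
            collected[name] = scores.copy()

    cv_auc_multi(
        learners,
        data,
        K=config.K,
        n_replicates=replicate + 1,
        base_seed=config.base_seed,
        score_sink=sink,
    )
    out = data[[ID_COL, OUTCOME_COL]].copy()
    out["replicate"] = replicate
    for name, scores in collected.items():
        out[name] = scores
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / "scores.csv", index=False)
    return out
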