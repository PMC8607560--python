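"""IPW-weighted AUC and repeated, stratified, K-fold cross-validation.

The headline statistic is the inverse-probability-weighted AUC

    AUC_w = sum_{i in D1} sum_{j in D0} w_i w_j [ I(P_i > P_j) + 1/2 I(P_i = P_j) ]
            / sum_{i in D1} sum_{j in D0} w_i w_j

where ``D1``/``D0`` index cases and controls, ``P`` are prediction scores
and ``w`` the subjects' inverse sampling probability weights.  Weighting
each case-control pair by ``w_i w_j`` makes an AUC computed on the
phase-two subsample estimate the full-cohort AUC.  Ties receive half
credit so that a constant-score model attains exactly 0.5, the theoretical
null value.

Cross-validation is stratified by case status (so every training split
has the same case/control composition), repeated ``n_replicates`` times
with per-replicate fold seeds, and scored by pooling each replicate's
out-of-fold scores into a single weighted AUC (per-fold averaging is
available behind a switch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.model_selection import StratifiedKFold

from .tables import OUTCOME_COL, WEIGHT_COL

__all__ = [
    "PredictionSet",
    "weighted_auc",
    "FoldPlan",
    "make_fold_plan",
    "WeightedAUCResult",
    "cv_auc",
    "cv_auc_multi",
    "compare_replicates",
]


@dataclass
class PredictionSet:
    """Scores and weights of cases (D1) and controls (D0) for one AUC evaluation."""

    case_scores: np.ndarray
    control_scores: np.ndarray
    case_weights: np.ndarray | None = None
    control_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.case_scores = np.asarray(self.case_scores, dtype=float)
        self.control_scores = np.asarray(self.control_scores, dtype=float)
        if self.case_weights is None:
            self.case_weights = np.ones_like(self.case_scores)
        if self.control_weights is None:
            self.control_weights = np.ones_like(self.control_scores)
        self.case_weights = np.asarray(self.case_weights, dtype=float)
        self.control_weights = np.asarray(self.control_weights, dtype=float)
        if self.case_scores.size == 0 or self.control_scores.size == 0:
            raise ValueError("both case and control sets must be non-empty")
        for arr in (self.case_scores, self.control_scores):
            if not np.all(np.isfinite(arr)):
                raise ValueError("scores must be finite")
        for arr in (self.case_weights, self.control_weights):
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError("weights must be positive and finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scores: np.ndarray) -> "PredictionSet":
        y = df[OUTCOME_COL].to_numpy()
        w = df[WEIGHT_COL].to_numpy() if WEIGHT_COL in df.columns else np.ones(len(df))
        scores = np.asarray(scores, dtype=float)
        case = y == 1
        return cls(scores[case], scores[~case], w[case], w[~case])


def weighted_auc(preds: PredictionSet) -> float:
    """Weighted pairwise AUC with half credit for tied scores."""
    p1, p0 = preds.case_scores, preds.control_scores
    w1, w0 = preds.case_weights, preds.control_weights
    # Sort-free broadcasting; pair counts here are small (n1*n0 <~ 1e6).
    diff = p1[:, None] - p0[None, :]
    wins = (diff > 0).astype(float) + 0.5 * (diff == 0)
    ww = w1[:, None] * w0[None, :]
    return float(np.sum(ww * wins) / np.sum(ww))


@dataclass(frozen=True)
class FoldPlan:
    """Outcome-stratified assignment of subjects to K cross-validation folds."""

    K: int
    assignment: np.ndarray  # fold index per row of the dataset
    seed: int

    def train_index(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != k)

    def test_index(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)


def make_fold_plan(data: pd.DataFrame, K: int, seed: int) -> FoldPlan:
    """Stratified K-fold plan: per-fold case and control counts differ by <= 1."""
    if K < 2:
        raise ValueError("K must be at least 2")
    y = data[OUTCOME_COL].to_numpy()
    n_case, n_ctrl = int((y == 1).sum()), int((y == 0).sum())
    if K > n_case or K > n_ctrl:
        raise ValueError(f"K={K} exceeds the number of cases ({n_case}) or controls ({n_ctrl})")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed % (2**32))
    assignment = np.empty(len(data), dtype=int)
    for k, (_, test) in enumerate(skf.split(np.zeros(len(data)), y)):
        assignment[test] = k
    return FoldPlan(K=K, assignment=assignment, seed=seed)


@dataclass
class WeightedAUCResult:
    """Repeated CV-AUC: one value per replicate plus their mean."""

    mean_cv_auc: float
    per_replicate: np.ndarray
    K: int
    n_replicates: int
    seeds: tuple[int, ...]

    @classmethod
    def from_replicates(cls, values: Sequence[float], K: int, seeds: Sequence[int]) -> "WeightedAUCResult":
        arr = np.asarray(values, dtype=float)
        return cls(
            mean_cv_auc=float(arr.mean()),
            per_replicate=arr,
            K=K,
            n_replicates=len(arr),
            seeds=tuple(int(s) for s in seeds),
        )


class Learner(Protocol):
    """Anything trainable per fold: returns a fitted object exposing ``score``."""

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None) -> "Fitted": ...


class Fitted(Protocol):
    def score(self, data: pd.DataFrame) -> np.ndarray: ...


def fit_seed(base_seed: int, replicate: int, fold: int) -> int:
    """Deterministic per-(replicate, fold) seed, shared by all learners in a fold."""
    ss = np.random.SeedSequence([int(base_seed) % (2**31), replicate, fold])
    return int(ss.generate_state(1)[0] % (2**31))


def cv_auc_multi(
    learners: Mapping[str, Learner],
    data: pd.DataFrame,
    K: int = 5,
    n_replicates: int = 100,
    base_seed: int = 0,
    pooling: str = "pooled",
    score_sink: Callable[[int, str, pd.DataFrame, np.ndarray], None] | None = None,
) -> dict[str, WeightedAUCResult]:
    """Repeated K-fold CV-AUC for several learners on shared fold plans.

    All learners see identical fold plans per replicate, so per-replicate
    differences are attributable to the method rather than the split and
    paired signed-rank comparisons are valid.  A per-(replicate, fold)
    cache dict is passed to every learner so that work shared between
    variants (screening, candidate fits inside stacking) is done once.

    ``pooling`` is ``"pooled"`` (one AUC per replicate on the pooled
    out-of-fold scores, the default) or ``"per-fold"`` (average of the K
    per-fold AUCs).  ``score_sink(replicate, name, data, scores)``, when
    given, receives every replicate's pooled out-of-fold score vector.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if pooling not in ("pooled", "per-fold"):
        raise ValueError("pooling must be 'pooled' or 'per-fold'")
    per_rep: dict[str, list[float]] = {name: [] for name in learners}
    seeds = [int(base_seed) + r for r in range(n_replicates)]
    for r, rep_seed in enumerate(seeds):
        plan = make_fold_plan(data, K, rep_seed)
        oof: dict[str, np.ndarray] = {name: np.full(len(data), np.nan) for name in learners}
        fold_aucs: dict[str, list[float]] = {name: [] for name in learners}
        for k in range(K):
            tr_idx, te_idx = plan.train_index(k), plan.test_index(k)
            train = data.iloc[tr_idx].reset_index(drop=True)
            test = data.iloc[te_idx].reset_index(drop=True)
            seed = fit_seed(base_seed, r, k)
            cache: dict = {}
            for name, learner in learners.items():
                try:
                    fitted = learner.fit(train, seed, cache=cache)
                    scores = np.asarray(fitted.score(test), dtype=float)
                except Exception as exc:
                    raise RuntimeError(
                        f"learner {name!r} failed in replicate {r}, fold {k}: {exc}"
                    ) from exc
                oof[name][te_idx] = scores
                if pooling == "per-fold":
                    fold_aucs[name].append(weighted_auc(PredictionSet.from_frame(test, scores)))
        for name in learners:
            if pooling == "pooled":
                per_rep[name].append(weighted_auc(PredictionSet.from_frame(data, oof[name])))
            else:
                per_rep[name].append(float(np.mean(fold_aucs[name])))
            if score_sink is not None:
                score_sink(r, name, data, oof[name])
    return {
        name: WeightedAUCResult.from_replicates(vals, K, seeds) for name, vals in per_rep.items()
    }


def cv_auc(
    learner: Learner,
    data: pd.DataFrame,
    K: int = 5,
    n_replicates: int = 100,
    base_seed: int = 0,
    pooling: str = "pooled",
) -> WeightedAUCResult:
    """Repeated K-fold CV-AUC of a single learner (see :func:`cv_auc_multi`)."""
    return cv_auc_multi({"learner": learner}, data, K, n_replicates, base_seed, pooling)["learner"]


def compare_replicates(a: WeightedAUCResult, b: WeightedAUCResult) -> dict[str, float]:
    """Paired two-sided Wilcoxon signed-rank test across CV replicates.

    Replicates must be paired: equal counts and identical fold-seed
    sequences.  When every paired difference is zero the test is degenerate
    and ``p = 1`` is reported by convention.
    """
    if a.n_replicates != b.n_replicates or a.seeds != b.seeds:
        raise ValueError("results are not paired (different replicate counts or seeds)")
    d = a.per_replicate - b.per_replicate
    n = int(d.size)
    if np.all(d == 0):
        return {"statistic": 0.0, "p_value": 1.0, "n_pairs": n}
    stat, p = wilcoxon(d, alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p), "n_pairs": n}
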