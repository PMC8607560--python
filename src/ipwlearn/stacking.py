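"""Stacked generalization with a nonnegative logistic meta-learner.

Stacking combines heterogeneous candidate learners (here: forests and
GLMs, possibly trained on different marker sets) in two steps: first,
every candidate is run through an inner stratified K-fold loop on the
training data so that each training subject receives an *out-of-sample*
prediction score from a model not trained on it; second, a logistic
regression of the outcome on those score columns — with slopes constrained
to be nonnegative — learns the combination weights.  For prediction, the
candidates are refit on the full training data and their scores are passed
through the meta model.

Stacking pays off when the candidates' score vectors are dissimilar
(low Pearson correlation); :func:`score_dissimilarity` reports exactly
that diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .evaluation import make_fold_plan
from .learners import ForestLearner, GLMLearner, _derived_seed
from .tables import OUTCOME_COL, WEIGHT_COL

__all__ = [
    "out_of_sample_scores",
    "fit_meta",
    "StackModel",
    "StackLearner",
    "stack_predict",
    "score_dissimilarity",
]

Candidate = ForestLearner | GLMLearner


def out_of_sample_scores(
    candidates: Sequence[Candidate],
    train: pd.DataFrame,
    inner_folds: int = 10,
    seed: int = 0,
    cache: dict | None = None,
) -> np.ndarray:
    """(n, m) matrix of inner out-of-fold scores, one column per candidate.

    The inner fold plan is stratified by outcome (with ~20 cases spread
    over 10 folds, unstratified splitting would regularly produce
    case-free inner folds).  Each candidate's full training procedure,
    screening included, runs on every inner training fold.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    plan = make_fold_plan(train, inner_folds, seed)
    scores = np.full((len(train), len(candidates)), np.nan)
    for k in range(inner_folds):
        tr_idx, te_idx = plan.train_index(k), plan.test_index(k)
        inner_train = train.iloc[tr_idx].reset_index(drop=True)
        inner_test = train.iloc[te_idx].reset_index(drop=True)
        inner_seed = _derived_seed(seed, "inner", k)
        inner_cache: dict = {} if cache is None else cache.setdefault(("inner", seed, k), {})
        for c, cand in enumerate(candidates):
            try:
                fitted = cand.fit(inner_train, inner_seed, cache=inner_cache)
                scores[te_idx, c] = fitted.score(inner_test)
            except Exception as exc:
                raise RuntimeError(f"candidate {c} failed in inner fold {k}: {exc}") from exc
    return scores


def fit_meta(
    scores: np.ndarray,
    outcome: np.ndarray,
    use_ipw: bool = False,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Logistic meta-fit: free intercept, slopes bound at zero.

    Maximizes the (optionally weighted) logistic log-likelihood by
    bound-constrained quasi-Newton (L-BFGS-B) with analytic gradients to a
    projected-gradient tolerance of ``tol``.  Returns
    ``(intercept, slopes)``; every slope is >= 0 by construction.
    """
    S = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("candidate scores must be finite")
    n, m = S.shape
    if use_ipw:
        if weights is None:
            raise ValueError("use_ipw requires a weight vector")
        w = np.asarray(weights, dtype=float)
    else:
        w = np.ones(n)
    X = np.column_stack([np.ones(n), S])

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ theta
        p = expit(eta)
        # stable log-likelihood
        ll = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
        grad = X.T @ (w * (p - y))
        return -ll, grad

    x0 = np.zeros(m + 1)
    bounds = [(None, None)] + [(0.0, None)] * m
    res = minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "gtol": tol, "ftol": 1e-14},
    )
    active_grad = np.abs(res.jac[1:][res.x[1:] > 0])
    if not res.success and np.max(active_grad, initial=0.0) > 1e-4:
        warnings.warn(f"meta-learner optimization did not fully converge: {res.message}")
    theta = res.x
    theta[1:] = np.maximum(theta[1:], 0.0)
    return float(theta[0]), theta[1:].copy()


@dataclass
class StackModel:
    """Fitted stack: refitted candidates plus the nonnegative meta model."""

    candidates: tuple[Candidate, ...]
    fitted_candidates: tuple
    intercept: float
    slopes: np.ndarray
    inner_folds: int
    seed: int
    oos_scores: np.ndarray | None = None  # inner out-of-sample score matrix

    def score(self, data: pd.DataFrame) -> np.ndarray:
        return stack_predict(self, data)


def stack_predict(model: StackModel, newdata: pd.DataFrame) -> np.ndarray:
    """Candidate scores from the full-training refits, mapped through the meta model."""
    cols = [fc.score(newdata) for fc in model.fitted_candidates]
    S = np.column_stack(cols)
    return expit(model.intercept + S @ model.slopes)


def score_dissimilarity(scores: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of candidate score columns.

    A zero-variance column makes its correlations undefined; those entries
    are reported as NaN with a warning.
    """
    S = np.asarray(scores, dtype=float)
    if S.shape[1] < 2:
        raise ValueError("need at least two candidates")
    sd = S.std(axis=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(S.mean(axis=0)))
    if degenerate.any():
        warnings.warn("zero-variance score column; correlations reported as NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(S, rowvar=False)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    np.fill_diagonal(C, np.where(degenerate, np.nan, 1.0))
    return C


@dataclass(frozen=True)
class StackLearner:
    """Two-level stack usable anywhere a plain learner is.

    ``fit`` runs the inner out-of-sample loop, fits the nonnegative meta
    model (unweighted by default; set ``use_ipw_meta`` to weight it), and
    refits every candidate on the full training data for prediction.
    """

    candidates: tuple[Candidate, ...]
    inner_folds: int = 10
    use_ipw_meta: bool = False

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None) -> StackModel:
        S = out_of_sample_scores(self.candidates, train, self.inner_folds, seed, cache=cache)
        y = train[OUTCOME_COL].to_numpy(dtype=float)
        w = train[WEIGHT_COL].to_numpy(dtype=float) if WEIGHT_COL in train.columns else None
        intercept, slopes = fit_meta(S, y, use_ipw=self.use_ipw_meta, weights=w)
        fitted = tuple(cand.fit(train, seed, cache=cache) for cand in self.candidates)
        return StackModel(
            candidates=tuple(self.candidates),
            fitted_candidates=fitted,
            intercept=intercept,
            slopes=slopes,
            inner_folds=self.inner_folds,
            seed=seed,
            oos_scores=S,
        )
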