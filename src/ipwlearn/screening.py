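"""Lasso-based supervised variable screening.

Screening fits an L1-penalized logistic regression of the outcome on the
candidate markers plus the clinical covariates and keeps only the markers
with nonzero coefficients; covariates are forced (effectively unpenalized)
and always retained.  The penalty is chosen by inner K-fold
cross-validation of the held-out weighted binomial deviance over a
geometric penalty grid, by default minimizing the deviance; the sparser
one-standard-error rule is available as ``penalty_rule="one-se"``.
The fit is IPW-weighted by default so that the screening criterion, like
every other training step, targets the full cohort.

Implementation notes: features are standardized to unit variance on the
training data inside the fit; the "forced" (unpenalized) status of the
clinical covariates is implemented by rescaling their standardized columns
by a large factor, which shrinks their effective L1 penalty by the same
factor — numerically indistinguishable from an unpenalized fit (checked in
the test suite against an exact per-parameter-penalty fit).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .tables import COVARIATES, OUTCOME_COL, WEIGHT_COL

__all__ = ["ScreenConfig", "lasso_screen", "lasso_path_support"]

_FORCE_SCALE = 1e4  # rescaling factor implementing the unpenalized status


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the in-fold lasso screen."""

    inner_folds: int = 5
    forced_features: tuple[str, ...] = COVARIATES
    penalty_grid: tuple[float, ...] | None = None  # None = automatic geometric grid
    n_penalties: int = 25
    penalty_rule: str = "min-deviance"  # or "one-se"
    use_ipw_in_screening: bool = True
    dfmax: int | None = None  # path truncation: stop once support exceeds this (None = max(50, n/2))
    seed: int = 0

    def validate(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.penalty_rule not in ("min-deviance", "one-se"):
            raise ValueError("penalty_rule must be 'min-deviance' or 'one-se'")
        if self.penalty_grid is not None:
            grid = np.asarray(self.penalty_grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValueError("penalty_grid must be positive and strictly decreasing")


def _design(
    train: pd.DataFrame, candidates: list[str], forced: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = list(forced) + [c for c in candidates if c not in forced]
    X = train[cols].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    scale = np.ones(len(cols))
    scale[: len(forced)] = _FORCE_SCALE
    return X * scale, mu, sd, cols


def _lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_forced: int) -> float:
    """Smallest penalty shrinking every penalized coefficient to zero (null-model score)."""
    wn = w / w.sum()
    r = y - np.sum(wn * y)
    grad = np.abs(X[:, n_forced:].T @ (wn * r))
    return float(max(grad.max(), 1e-6))


def _fit_l1(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    # liblinear minimizes C * sum_i w_i loss_i + ||beta||_1; glmnet-style
    # lambda on the mean loss corresponds to C = 1 / (lam * sum w).
    clf = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        C=1.0 / (lam * w.sum()),
        intercept_scaling=1e3,
        max_iter=200,
        tol=1e-5,
        random_state=seed % (2**32),
    )
    clf.fit(X, y, sample_weight=w)
    return clf


def _weighted_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))) / w.sum())


def lasso_screen(
    train: pd.DataFrame, candidate_features: list[str], config: ScreenConfig | None = None
) -> list[str]:
    """Select features: forced covariates plus markers surviving the lasso.

    Returns ``forced_features`` plus every candidate whose coefficient in
    the penalty-selected refit on the full training data is nonzero.
    Deterministic given ``config.seed``; consumes only ``train``.
    """
    config = config or ScreenConfig()
    config.validate()
    forced = [f for f in config.forced_features if f in train.columns]
    missing = [f for f in candidate_features if f not in train.columns]
    if missing:
        raise ValueError(f"candidate features missing from data: {missing[:5]}")
    if not candidate_features:
        return list(forced)
    y = train[OUTCOME_COL].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has no variation in the training data")
    if config.use_ipw_in_screening and WEIGHT_COL in train.columns:
        w = train[WEIGHT_COL].to_numpy(dtype=float)
    else:
        w = np.ones(len(train))

    X, _, _, cols = _design(train, list(candidate_features), forced)
    n_forced = len(forced)

    if config.penalty_grid is not None:
        grid = np.asarray(config.penalty_grid, dtype=float)
    else:
        lam_max = _lambda_max(X, y, w, n_forced)
        grid = np.geomspace(lam_max, lam_max * 1e-3, config.n_penalties)

    dfmax = config.dfmax if config.dfmax is not None else max(50, len(train) // 2)

    if len(grid) > 1:
        skf = StratifiedKFold(
            n_splits=config.inner_folds, shuffle=True, random_state=config.seed % (2**32)
        )
        splits = list(skf.split(X, y))
        # Penalty-major scan with early stop: once the CV deviance has risen
        # for three consecutive grid points past its running minimum, or the
        # fold supports have grown past dfmax, the remaining (denser,
        # costlier) end of the path cannot produce a useful screen.
        dev_cols: list[np.ndarray] = []
        best_dev, rises = np.inf, 0
        # evaluate at least 60% of the grid before allowing the rise-based
        # stop: small-sample deviance curves are noisy, and the savings only
        # matter at the dense end anyway.
        min_scan = max(10, int(0.6 * len(grid)))
        for g, lam in enumerate(grid):
            col = np.empty(config.inner_folds)
            nz = 0
            for f, (tr, te) in enumerate(splits):
                clf = _fit_l1(X[tr], y[tr], w[tr], lam, config.seed)
                p = clf.predict_proba(X[te])[:, 1]
                col[f] = _weighted_deviance(y[te], p, w[te])
                nz = max(nz, int(np.sum(clf.coef_.ravel()[n_forced:] != 0)))
            dev_cols.append(col)
            m = col.mean()
            if m < best_dev:
                best_dev, rises = m, 0
            else:
                rises += 1
            if (rises >= 3 and g + 1 >= min_scan) or nz > dfmax:
                break
        dev = np.column_stack(dev_cols)
        grid = grid[: dev.shape[1]]
        mean_dev = dev.mean(axis=0)
        best = int(np.argmin(mean_dev))
        if config.penalty_rule == "one-se":
            se = dev.std(axis=0, ddof=1) / np.sqrt(config.inner_folds)
            threshold = mean_dev[best] + se[best]
            # grid is decreasing; the largest acceptable penalty is the
            # earliest grid point within one SE of the minimum.
            best = int(np.flatnonzero(mean_dev <= threshold)[0])
    else:
        best = 0

    coef = _fit_l1(X, y, w, float(grid[best]), config.seed).coef_.ravel()
    selected = [cols[j] for j in range(n_forced, len(cols)) if coef[j] != 0.0]
    return list(forced) + selected


def lasso_path_support(
    train: pd.DataFrame,
    candidate_features: list[str],
    penalties: np.ndarray,
    config: ScreenConfig | None = None,
) -> list[list[str]]:
    """Selected marker sets along a fixed decreasing penalty path (diagnostics)."""
    config = config or ScreenConfig()
    forced = [f for f in config.forced_features if f in train.columns]
    y = train[OUTCOME_COL].to_numpy(dtype=float)
    if config.use_ipw_in_screening and WEIGHT_COL in train.columns:
        w = train[WEIGHT_COL].to_numpy(dtype=float)
    else:
        w = np.ones(len(train))
    X, _, _, cols = _design(train, list(candidate_features), forced)
    n_forced = len(forced)
    out = []
    for lam in penalties:
        clf = _fit_l1(X, y, w, float(lam), config.seed)
        coef = clf.coef_.ravel()
        out.append([cols[j] for j in range(n_forced, len(cols)) if coef[j] != 0.0])
    return out
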