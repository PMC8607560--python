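"""Random forests with ensemble-level bootstrap schemes, and weighted GLMs.

The forest is a bagged ensemble of Gini-split classification trees grown
to maximal depth without pruning, with ``mtry`` candidate features per
split.  What distinguishes it from an off-the-shelf forest is control of
the *ensemble-level bootstrap*: the per-tree resampling scheme is a
first-class object, because class balancing and design weighting enter a
forest precisely there.

Four schemes are supported, matching how an analyst rebalances a rare
outcome inside the ensemble rather than by pre-processing:

``standard``
    uniform bootstrap of ``round(sample_fraction * n)`` rows (fraction 1
    by default).
``under``
    cases get sampling weight ``n_controls / n_cases`` (5 for a 1:5 fold),
    controls weight 1, and the draw is shrunk to ``2 * n_cases`` rows, so
    each tree sees an expected 50:50 class mix at the minority-class size
    (a 20/100 fold yields trees trained on 40 draws, ~20 cases and ~20
    controls).
``over``
    cases are first duplicated (sampling with replacement) up to the
    control count, then each tree takes a uniform full-size bootstrap of
    the augmented set (a 20/100 fold yields 200-row trees, ~100 cases and
    ~100 controls in expectation).
``ipw``
    per-row sampling probability proportional to the inverse sampling
    probability weight, full-size draw.

Ensemble scores are vote fractions: the share of trees whose leaf-majority
prediction is "case".  Out-of-bag (OOB) AUC scores each training row using
only the trees whose bootstrap excluded it; it is computed *unweighted*,
which is exactly why tuning on OOB-AUC can disagree with the IPW-weighted
CV-AUC used for final evaluation.

Hyperparameter tuning is a budgeted search (50-100 configurations) over
``mtry``, ``min_node_size`` and ``sample_fraction``, maximizing OOB-AUC: a
seeded Latin-hypercube stage followed by a quadratic-surrogate refinement
stage within the same budget, with ties broken toward the simpler model.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import qmc
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .screening import ScreenConfig, lasso_screen
from .tables import OUTCOME_COL, WEIGHT_COL, feature_columns, marker_columns, stable_key

__all__ = [
    "BootstrapScheme",
    "ForestConfig",
    "ForestModel",
    "plan_bootstrap",
    "fit_forest",
    "forest_score",
    "oob_auc",
    "tune_forest",
    "GLMModel",
    "fit_glm",
    "glm_score",
    "ForestLearner",
    "GLMLearner",
]

SCHEME_KINDS = ("standard", "under", "over", "ipw")


@dataclass(frozen=True)
class BootstrapScheme:
    """Ensemble-level resampling scheme; ``sample_fraction`` None = scheme default."""

    kind: str = "standard"
    sample_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown bootstrap scheme {self.kind!r}")
        if self.sample_fraction is not None and not 0.0 < self.sample_fraction <= 2.0:
            raise ValueError("sample_fraction must lie in (0, 2]")


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; defaults mirror common classification-forest defaults."""

    n_trees: int = 500
    mtry: int | None = None  # None = floor(sqrt(p))
    min_node_size: int = 1
    scheme: BootstrapScheme = field(default_factory=BootstrapScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class ForestModel:
    trees: list
    features: list[str]
    inbag: np.ndarray  # (n_trees, n_train) bool, in original training-row space
    config: ForestConfig
    n_train: int


def plan_bootstrap(
    scheme: BootstrapScheme,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    ipw: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-tree bootstrap index multisets (indices into the original rows).

    ``y`` is the training outcome vector (1 = case).  All draws are with
    replacement.  For the ``over`` scheme the case set is first augmented
    (once, seeded) to the control count and trees draw uniformly from the
    augmented multiset; returned indices always refer to original rows.
    """
    y = np.asarray(y)
    n = y.size
    n_case = int((y == 1).sum())
    n_ctrl = n - n_case
    if n == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(seed)

    if scheme.kind == "over":
        if n_case == 0 or n_ctrl == 0:
            raise ValueError("over-sampling requires both classes present")
        case_idx = np.flatnonzero(y == 1)
        ctrl_idx = np.flatnonzero(y == 0)
        extra = rng.choice(case_idx, size=max(0, n_ctrl - n_case), replace=True)
        pool = np.concatenate([case_idx, extra, ctrl_idx])
        frac = 1.0 if scheme.sample_fraction is None else scheme.sample_fraction
        draw = int(round(frac * pool.size))
        return [rng.choice(pool, size=draw, replace=True) for _ in range(n_trees)]

    if scheme.kind == "standard":
        p = np.full(n, 1.0 / n)
        frac = 1.0 if scheme.sample_fraction is None else scheme.sample_fraction
    elif scheme.kind == "under":
        if n_case == 0 or n_ctrl == 0:
            raise ValueError("under-sampling requires both classes present")
        w = np.where(y == 1, n_ctrl / n_case, 1.0)
        p = w / w.sum()
        frac = (2.0 * n_case / n) if scheme.sample_fraction is None else scheme.sample_fraction
    elif scheme.kind == "ipw":
        if ipw is None:
            raise ValueError("ipw scheme requires the weight vector")
        w = np.asarray(ipw, dtype=float)
        if np.any(w <= 0):
            raise ValueError("ipw weights must be positive")
        p = w / w.sum()
        frac = 1.0 if scheme.sample_fraction is None else scheme.sample_fraction
    draw = int(round(frac * n))
    if draw < 1:
        raise ValueError("sample_fraction too small: empty bootstrap")
    return [rng.choice(n, size=draw, replace=True, p=p) for _ in range(n_trees)]


def fit_forest(
    train: pd.DataFrame, features: list[str], config: ForestConfig | None = None
) -> ForestModel:
    """Fit the ensemble on planned bootstraps; deterministic given ``config.seed``."""
    config = config or ForestConfig()
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise ValueError(f"features missing from data: {missing[:5]}")
    X = train[list(features)].to_numpy(dtype=float)
    y = train[OUTCOME_COL].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single outcome class")
    n, p = X.shape
    if p == 0:
        raise ValueError("no features to fit the forest on")
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds the number of features p={p}")
    ipw = train[WEIGHT_COL].to_numpy(dtype=float) if WEIGHT_COL in train.columns else None
    rng = np.random.default_rng(config.seed)
    plan_seed = int(rng.integers(2**31))
    plans = plan_bootstrap(config.scheme, y, config.n_trees, plan_seed, ipw=ipw)

    trees = []
    inbag = np.zeros((config.n_trees, n), dtype=bool)
    for t, idx in enumerate(plans):
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=config.min_node_size,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag[t, np.unique(idx)] = True
    return ForestModel(trees=trees, features=list(features), inbag=inbag, config=config, n_train=n)


def _vote_matrix(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """(n_trees, n) boolean matrix of per-tree case votes."""
    votes = np.empty((len(model.trees), X.shape[0]), dtype=bool)
    for t, tree in enumerate(model.trees):
        votes[t] = tree.predict(X) == 1
    return votes


def forest_score(model: ForestModel, newdata: pd.DataFrame) -> np.ndarray:
    """Prediction score = fraction of trees whose leaf-majority vote is 'case'."""
    missing = [f for f in model.features if f not in newdata.columns]
    if missing:
        raise ValueError(f"features missing from new data: {missing[:5]}")
    X = newdata[model.features].to_numpy(dtype=float)
    return _vote_matrix(model, X).mean(axis=0)


def oob_auc(model: ForestModel, train: pd.DataFrame) -> float:
    """Unweighted tie-corrected AUC of out-of-bag vote fractions.

    Each training row is scored by the trees whose bootstrap excluded it;
    rows that are in-bag for every tree are dropped.  No IPW enters here.
    """
    from .evaluation import PredictionSet, weighted_auc  # local import avoids a cycle

    X = train[model.features].to_numpy(dtype=float)
    y = train[OUTCOME_COL].to_numpy(dtype=int)
    votes = _vote_matrix(model, X)
    out = ~model.inbag
    n_out = out.sum(axis=0)
    usable = n_out > 0
    if not np.any(usable & (y == 1)) or not np.any(usable & (y == 0)):
        raise ValueError(
            f"too few out-of-bag observations ({int(usable.sum())} usable) to compute OOB AUC"
        )
    with np.errstate(invalid="ignore"):
        scores = np.where(usable, (votes & out).sum(axis=0) / np.maximum(n_out, 1), np.nan)
    keep = usable
    return weighted_auc(
        PredictionSet(scores[keep & (y == 1)], scores[keep & (y == 0)])
    )


def tune_forest(
    train: pd.DataFrame,
    features: list[str],
    budget: int = 50,
    seed: int = 0,
    scheme: BootstrapScheme | None = None,
    n_trees: int = 500,
    refine_fraction: float = 0.4,
    return_trace: bool = False,
):
    """Budgeted OOB-AUC-maximizing search over forest hyperparameters.

    Evaluates exactly ``budget`` configurations (budget must lie in
    [50, 100]) over ``mtry`` in [1, p], ``min_node_size`` in [1, n/2] and
    ``sample_fraction`` in [0.2, 1].  The first part of the budget is a
    seeded Latin-hypercube design; the remainder is chosen by a quadratic
    surrogate fitted to the evaluations so far.  Ties in the argmax go to
    the smaller ``mtry``, then the smaller ``min_node_size``.
    """
    if not 50 <= budget <= 100:
        raise ValueError("budget must lie in [50, 100]")
    scheme = scheme or BootstrapScheme()
    p = len(features)
    n = len(train)
    if p == 0 or n == 0:
        raise ValueError("empty feature list or training data")
    lo = np.array([1.0, 1.0, 0.2])
    hi = np.array([float(p), max(1.0, n / 2.0), 1.0])

    rng = np.random.default_rng(seed)
    n_initial = budget - int(round(refine_fraction * budget))
    sampler = qmc.LatinHypercube(d=3, seed=int(rng.integers(2**31)))
    unit = sampler.random(n=n_initial)

    def decode(u: np.ndarray) -> tuple[int, int, float]:
        v = lo + u * (hi - lo)
        return int(round(v[0])), int(round(v[1])), float(v[2])

    def evaluate(u: np.ndarray, eval_seed: int) -> tuple[dict, float]:
        mtry, mns, frac = decode(u)
        cfg = ForestConfig(
            n_trees=n_trees,
            mtry=mtry,
            min_node_size=mns,
            scheme=replace(scheme, sample_fraction=frac),
            seed=eval_seed,
        )
        model = fit_forest(train, features, cfg)
        auc = oob_auc(model, train)
        return {"mtry": mtry, "min_node_size": mns, "sample_fraction": frac, "oob_auc": auc}, auc

    trace: list[dict] = []
    evaluated: list[np.ndarray] = []
    aucs: list[float] = []
    fit_seed = int(rng.integers(2**31))  # shared so OOB differences reflect the config
    for u in unit:
        rec, auc = evaluate(u, fit_seed)
        trace.append(rec)
        evaluated.append(u)
        aucs.append(auc)

    n_refine = budget - n_initial
    if n_refine > 0:
        U = np.array(evaluated)
        a = np.array(aucs)
        # quadratic surrogate on the unit cube
        def quad_features(M: np.ndarray) -> np.ndarray:
            cols = [np.ones(len(M))]
            for i in range(3):
                cols.append(M[:, i])
            for i in range(3):
                for j in range(i, 3):
                    cols.append(M[:, i] * M[:, j])
            return np.column_stack(cols)

        coef, *_ = np.linalg.lstsq(quad_features(U), a, rcond=None)
        cand = rng.random((512, 3))
        pred = quad_features(cand) @ coef
        order = np.argsort(-pred)
        for u in cand[order[:n_refine]]:
            rec, auc = evaluate(u, fit_seed)
            trace.append(rec)
            evaluated.append(u)
            aucs.append(auc)

    # argmax with ties toward simpler models
    ranked = sorted(
        range(len(trace)),
        key=lambda i: (-trace[i]["oob_auc"], trace[i]["mtry"], trace[i]["min_node_size"]),
    )
    best = trace[ranked[0]]
    best_cfg = ForestConfig(
        n_trees=n_trees,
        mtry=best["mtry"],
        min_node_size=best["min_node_size"],
        scheme=replace(scheme, sample_fraction=best["sample_fraction"]),
        seed=fit_seed,
    )
    if return_trace:
        return best_cfg, trace
    return best_cfg


# ---------------------------------------------------------------------------
# Weighted logistic regression


@dataclass
class GLMModel:
    intercept: float
    coef: np.ndarray
    features: list[str]
    dropped: tuple[str, ...] = ()
    fallback: bool = False


def _drop_aliased(X: np.ndarray, features: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop linearly dependent columns (QR with pivoting)."""
    if X.shape[1] == 0:
        return X, [], []
    from scipy.linalg import qr

    _, R, piv = qr(X - X.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > max(tol, 1e-12)))
    keep = sorted(piv[:rank])
    dropped = [features[j] for j in range(len(features)) if j not in keep]
    return X[:, keep], [features[j] for j in keep], dropped


def fit_glm(
    train: pd.DataFrame, features: list[str], use_ipw: bool = True
) -> GLMModel:
    """Logistic regression maximizing the IPW-weighted log-likelihood.

    With ``use_ipw`` the subjects' design weights multiply the
    log-likelihood (prior weights, as in a weighted ``glm`` fit); without,
    all weights are 1.  Aliased (linearly dependent) columns are dropped
    with a warning; complete separation or non-convergence falls back to a
    barely-regularized ridge fit (penalty 1e-8) with a warning.
    """
    y = train[OUTCOME_COL].to_numpy(dtype=float)
    if use_ipw and WEIGHT_COL in train.columns:
        w = train[WEIGHT_COL].to_numpy(dtype=float)
    else:
        w = np.ones(len(train))
    X = train[list(features)].to_numpy(dtype=float) if features else np.empty((len(train), 0))
    X, kept, dropped = _drop_aliased(X, list(features))
    if dropped:
        warnings.warn(f"dropping aliased columns: {dropped}", stacklevel=2)

    if X.shape[1] == 0:
        # intercept-only: weighted mean on the logit scale
        mu = float(np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12))
        return GLMModel(float(np.log(mu / (1 - mu))), np.zeros(0), [], tuple(dropped))

    Xc = sm.add_constant(X, has_constant="add")
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w).fit(maxiter=100)
            if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 30:
                params = np.asarray(res.params)
        except Exception:
            params = None
    fallback = params is None
    if fallback:
        warnings.warn(
            "GLM did not converge cleanly (likely separation); using a ridge "
            "fallback with penalty 1e-8",
            stacklevel=2,
        )
        clf = LogisticRegression(
            l1_ratio=0.0, solver="lbfgs", C=1.0 / (1e-8 * w.sum()), max_iter=2000
        )
        clf.fit(X, y, sample_weight=w)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return GLMModel(float(params[0]), params[1:].copy(), kept, tuple(dropped), fallback)


def glm_score(model: GLMModel, newdata: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the linear predictor; scores lie strictly in (0, 1)."""
    missing = [f for f in model.features if f not in newdata.columns]
    if missing:
        raise ValueError(f"features missing from new data: {missing[:5]}")
    if model.features:
        eta = model.intercept + newdata[model.features].to_numpy(dtype=float) @ model.coef
    else:
        eta = np.full(len(newdata), model.intercept)
    return expit(eta)


# ---------------------------------------------------------------------------
# Learner wrappers (the objects the CV harness trains per fold)


def _derived_seed(*parts: object) -> int:
    """Stable 31-bit seed from structural parts (not Python's salted hash)."""
    return zlib.crc32(stable_key(*parts).encode()) & 0x7FFFFFFF


def _resolve_features(
    train: pd.DataFrame,
    marker_set: str,
    include_covariates: bool,
    screen: ScreenConfig | None,
    seed: int,
    cache: dict | None,
) -> list[str]:
    markers = marker_columns(train, marker_set)
    base = feature_columns(train, marker_set, include_covariates)
    if screen is None or not markers:
        return base
    key = ("screen", marker_set, screen, seed)
    if cache is not None and key in cache:
        selected = cache[key]
    else:
        cfg = replace(screen, seed=_derived_seed(seed, "screen", screen))
        selected = lasso_screen(train, markers, cfg)
        if cache is not None:
            cache[key] = selected
    if include_covariates:
        return selected
    return [f for f in selected if f in markers]


@dataclass
class _FittedForest:
    model: ForestModel

    def score(self, data: pd.DataFrame) -> np.ndarray:
        return forest_score(self.model, data)


@dataclass
class _FittedGLM:
    model: GLMModel

    def score(self, data: pd.DataFrame) -> np.ndarray:
        return glm_score(self.model, data)


@dataclass(frozen=True)
class ForestLearner:
    """Forest pipeline: optional lasso screen, optional tuning, ensemble fit.

    The per-fold fit seed is derived from the fold seed plus the *resolved*
    feature list and forest settings, so two variants whose effective
    configuration coincides (e.g. screening toggled on a marker-free
    analysis) produce bit-identical models and can share a cache entry.
    """

    marker_set: str = "all"
    include_covariates: bool = True
    screen: ScreenConfig | None = None
    scheme: BootstrapScheme = field(default_factory=BootstrapScheme)
    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 1
    tune_budget: int | None = None

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None):
        features = _resolve_features(
            train, self.marker_set, self.include_covariates, self.screen, seed, cache
        )
        key = (
            "forest",
            tuple(features),
            self.scheme,
            self.n_trees,
            self.mtry,
            self.min_node_size,
            self.tune_budget,
            seed,
        )
        if cache is not None and key in cache:
            return cache[key]
        fit_seed = _derived_seed(seed, key[:-1])
        if self.tune_budget is not None:
            cfg = tune_forest(
                train,
                features,
                budget=self.tune_budget,
                seed=fit_seed,
                scheme=self.scheme,
                n_trees=self.n_trees,
            )
        else:
            cfg = ForestConfig(
                n_trees=self.n_trees,
                mtry=self.mtry,
                min_node_size=self.min_node_size,
                scheme=self.scheme,
                seed=fit_seed,
            )
        fitted = _FittedForest(fit_forest(train, features, cfg))
        if cache is not None:
            cache[key] = fitted
        return fitted


@dataclass(frozen=True)
class GLMLearner:
    """Logistic-regression pipeline: optional lasso screen, IPW-weighted fit."""

    marker_set: str = "all"
    include_covariates: bool = True
    screen: ScreenConfig | None = None
    use_ipw: bool = True

    def fit(self, train: pd.DataFrame, seed: int, cache: dict | None = None):
        features = _resolve_features(
            train, self.marker_set, self.include_covariates, self.screen, seed, cache
        )
        key = ("glm", tuple(features), self.use_ipw)
        if cache is not None and key in cache:
            return cache[key]
        fitted = _FittedGLM(fit_glm(train, features, use_ipw=self.use_ipw))
        if cache is not None:
            cache[key] = fitted
        return fitted
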