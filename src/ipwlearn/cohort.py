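"""Synthetic cohorts for two-phase biomarker study designs.

The generator produces a full cohort whose structure mirrors a nested
case-control biomarker study inside a prevention trial: a rare binary
endpoint, sampling strata defined by BMI level crossed with race/ethnicity,
three clinical covariates (age, BMI, behaviour risk score), and a
high-dimensional panel of immunologic markers split into a T-cell set and
an antibody set.

The signal structure is deliberately asymmetric between the two marker
sets: antibody signal markers act linearly on the log-odds of the outcome,
while T-cell signal markers act through linear terms plus pairwise product
(interaction) terms.  Tree ensembles can exploit the product terms while
linear models cannot, which is the regime the downstream model-comparison
experiments are designed to probe.

Markers are multivariate normal with exchangeable correlation inside
blocks of ``marker_block_size`` consecutive columns; signal markers are
placed on the first column of successive blocks so that each informative
marker drags a block of correlated noise along with it — the situation
lasso screening has to cope with.

The marginal case rate is controlled exactly in expectation: the intercept
of the outcome model is calibrated by root finding so that the mean event
probability over the generated cohort equals ``case_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .tables import (
    ANTIBODY_PREFIX,
    COVARIATES,
    ID_COL,
    OUTCOME_COL,
    PHASE2_COL,
    STRATUM_COL,
    TCELL_PREFIX,
)

__all__ = [
    "SyntheticConfig",
    "default_hvtn_like_config",
    "generate_cohort",
    "true_linear_predictor",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are on the log-odds scale per standard deviation of the
    marker (or per SD-product for interactions).  ``tcell_linear_effect_size``
    defaults to ``linear_effect_size``; set it to 0 to make the T-cell signal
    purely interaction-driven.
    """

    cohort_size: int = 2500
    case_rate: float = 0.01
    n_strata_bmi: int = 3
    n_strata_race: int = 2
    stratum_mixing: tuple[float, ...] | None = None  # None = uniform over strata
    p_tcell: int = 120
    p_antibody: int = 300
    marker_block_correlation: float = 0.3
    marker_block_size: int = 20
    n_signal_tcell: int = 4
    n_signal_antibody: int = 4
    linear_effect_size: float = 0.7
    interaction_effect_size: float = 0.7
    tcell_linear_effect_size: float | None = None
    covariate_effect_sizes: tuple[float, float, float] = (0.25, 0.25, 0.4)
    controls_per_case: int = 5
    seed: int = 0

    @property
    def n_strata(self) -> int:
        return self.n_strata_bmi * self.n_strata_race

    @property
    def mixing(self) -> np.ndarray:
        if self.stratum_mixing is None:
            return np.full(self.n_strata, 1.0 / self.n_strata)
        return np.asarray(self.stratum_mixing, dtype=float)

    @property
    def tcell_linear(self) -> float:
        if self.tcell_linear_effect_size is None:
            return self.linear_effect_size
        return self.tcell_linear_effect_size

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if not 0.0 < self.case_rate < 1.0:
            raise ValueError("case_rate must lie in (0, 1)")
        if self.n_signal_tcell > self.p_tcell:
            raise ValueError("n_signal_tcell exceeds p_tcell")
        if self.n_signal_antibody > self.p_antibody:
            raise ValueError("n_signal_antibody exceeds p_antibody")
        if not 0.0 <= self.marker_block_correlation < 1.0:
            raise ValueError("marker_block_correlation must lie in [0, 1)")
        mix = self.mixing
        if mix.size != self.n_strata:
            raise ValueError("stratum_mixing length must equal n_strata_bmi * n_strata_race")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("stratum_mixing must sum to 1 within 1e-12")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def default_hvtn_like_config(seed: int = 0) -> SyntheticConfig:
    """Configuration matching the reference study design.

    A cohort of 2500 vaccine recipients with a 1% endpoint rate gives 25
    expected cases; with all cases and five per-stratum controls per case
    selected into phase two, the expected phase-two sample is 25 cases and
    125 controls.  The marker panel has 420 columns (120 T-cell +
    300 antibody) against those ~150 phase-two observations.
    """
    return SyntheticConfig(seed=seed)


def _signal_indices(p: int, n_signal: int, block_size: int) -> np.ndarray:
    """Spread signal markers across blocks (first column of successive blocks)."""
    n_blocks = max(1, p // block_size)
    idx = [(k % n_blocks) * block_size + (k // n_blocks) for k in range(n_signal)]
    return np.asarray(sorted(idx), dtype=int)


def _block_normal(rng: np.random.Generator, n: int, p: int, rho: float, block: int) -> np.ndarray:
    """n x p matrix, unit-variance normals, exchangeable corr rho in blocks."""
    x = rng.standard_normal((n, p))
    if rho <= 0.0:
        return x
    out = np.empty_like(x)
    for start in range(0, p, block):
        stop = min(start + block, p)
        z = rng.standard_normal((n, 1))
        out[:, start:stop] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * x[:, start:stop]
    return out


def true_linear_predictor(cfg: SyntheticConfig, covs: np.ndarray, tcell: np.ndarray, ab: np.ndarray) -> np.ndarray:
    """Linear predictor of the outcome model, excluding the intercept.

    ``covs`` is (n, 3) in the order age, bmi, risk_score; ``tcell`` and
    ``ab`` are the full marker matrices.  Interaction terms are products of
    disjoint consecutive pairs of the T-cell signal markers.
    """
    eta = covs @ np.asarray(cfg.covariate_effect_sizes, dtype=float)
    ab_idx = _signal_indices(cfg.p_antibody, cfg.n_signal_antibody, cfg.marker_block_size)
    tc_idx = _signal_indices(cfg.p_tcell, cfg.n_signal_tcell, cfg.marker_block_size)
    if ab_idx.size:
        eta = eta + cfg.linear_effect_size * ab[:, ab_idx].sum(axis=1)
    if tc_idx.size:
        eta = eta + cfg.tcell_linear * tcell[:, tc_idx].sum(axis=1)
        for a, b in zip(tc_idx[0::2], tc_idx[1::2]):
            eta = eta + cfg.interaction_effect_size * tcell[:, a] * tcell[:, b]
    return eta


def _calibrate_intercept(eta: np.ndarray, rate: float) -> float:
    """Solve mean(expit(b0 + eta)) = rate for b0."""

    def f(b0: float) -> float:
        return float(expit(b0 + eta).mean() - rate)

    lo, hi = logit(rate) - 30.0, logit(rate) + 30.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_cohort(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate a full cohort table; a pure function of the config (seed included).

    The returned frame has one row per subject with outcome, stratum,
    covariates, tagged marker columns and a ``phase2`` flag initialised to 0
    (phase-two selection is a separate, design-level step).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.cohort_size

    stratum_idx = rng.choice(cfg.n_strata, size=n, p=cfg.mixing)
    bmi_level = stratum_idx // cfg.n_strata_race
    race = stratum_idx % cfg.n_strata_race
    # BMI covariate is coherent with the BMI stratum level; age and risk
    # score are independent standardized covariates.
    centered = bmi_level - (cfg.n_strata_bmi - 1) / 2.0
    bmi = 0.8 * centered + 0.6 * rng.standard_normal(n)
    age = rng.standard_normal(n)
    risk = rng.standard_normal(n)
    covs = np.column_stack([age, bmi, risk])

    tcell = _block_normal(rng, n, cfg.p_tcell, cfg.marker_block_correlation, cfg.marker_block_size)
    ab = _block_normal(rng, n, cfg.p_antibody, cfg.marker_block_correlation, cfg.marker_block_size)

    eta = true_linear_predictor(cfg, covs, tcell, ab)
    b0 = _calibrate_intercept(eta, cfg.case_rate)
    outcome = (rng.random(n) < expit(b0 + eta)).astype(int)

    data = {
        ID_COL: np.arange(1, n + 1),
        OUTCOME_COL: outcome,
        STRATUM_COL: [f"bmi{b}.race{r}" for b, r in zip(bmi_level, race)],
        COVARIATES[0]: age,
        COVARIATES[1]: bmi,
        COVARIATES[2]: risk,
    }
    df = pd.DataFrame(data)
    tc_cols = [f"{TCELL_PREFIX}{j + 1:04d}" for j in range(cfg.p_tcell)]
    ab_cols = [f"{ANTIBODY_PREFIX}{j + 1:04d}" for j in range(cfg.p_antibody)]
    df = pd.concat(
        [df, pd.DataFrame(tcell, columns=tc_cols), pd.DataFrame(ab, columns=ab_cols)],
        axis=1,
    )
    df[PHASE2_COL] = 0
    return df


def signal_marker_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Names of the generating-model signal markers, per set (for audits/tests)."""
    tc_idx = _signal_indices(cfg.p_tcell, cfg.n_signal_tcell, cfg.marker_block_size)
    ab_idx = _signal_indices(cfg.p_antibody, cfg.n_signal_antibody, cfg.marker_block_size)
    return {
        "tcell": [f"{TCELL_PREFIX}{j + 1:04d}" for j in tc_idx],
        "antibody": [f"{ANTIBODY_PREFIX}{j + 1:04d}" for j in ab_idx],
    }
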