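"""Two-phase sampling and inverse sampling probability weights.

In a two-phase design the expensive biomarker panel is measured only on a
stratified subsample of the cohort: every case (cases are rare) plus, within
each stratum, ``controls_per_case`` controls per case, drawn by simple
random sampling without replacement.  The inverse of the realized sampling
probability is attached to each phase-two subject as its weight ``w``:
cases have weight 1; a control in stratum ``s`` has weight

    w = (# cohort controls in s) / (# sampled controls in s),

so Horvitz-Thompson weighted control counts reproduce the cohort control
counts exactly, per stratum and hence globally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import OUTCOME_COL, PHASE2_COL, STRATUM_COL, WEIGHT_COL, validate_cohort

__all__ = ["two_phase_sample", "compute_ipw_weights"]


class InsufficientControlsError(ValueError):
    """A stratum does not contain enough controls for the requested design."""


def two_phase_sample(
    cohort: pd.DataFrame, controls_per_case: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Set the ``phase2`` flag: all cases plus per-stratum sampled controls.

    Within each stratum containing ``k`` cases, ``k * controls_per_case``
    controls are sampled without replacement.  Strata without cases
    contribute no controls.  Returns a copy of the cohort with ``phase2``
    set; raises :class:`InsufficientControlsError` (naming the stratum) if a
    stratum has too few controls.
    """
    validate_cohort(cohort)
    if controls_per_case < 0:
        raise ValueError("controls_per_case must be nonnegative")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    phase2 = np.zeros(len(out), dtype=int)
    is_case = out[OUTCOME_COL].to_numpy() == 1
    phase2[is_case] = 1

    strata = out[STRATUM_COL].to_numpy()
    for s in pd.unique(strata):
        in_s = strata == s
        n_cases = int(np.sum(in_s & is_case))
        if n_cases == 0:
            continue
        need = n_cases * controls_per_case
        control_pos = np.flatnonzero(in_s & ~is_case)
        if control_pos.size < need:
            raise InsufficientControlsError(
                f"stratum {s!r} has {control_pos.size} controls but the design "
                f"requires {need} ({n_cases} cases x {controls_per_case})"
            )
        chosen = rng.choice(control_pos, size=need, replace=False)
        phase2[chosen] = 1

    out[PHASE2_COL] = phase2
    return out


def compute_ipw_weights(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach inverse sampling probability weights and keep the phase-two rows.

    Requires ``phase2`` flags with every case selected.  Case weight is 1.
    Control weights are computed per stratum from the realized sampling
    fraction.  A stratum with unsampled controls but no sampled ones has an
    undefined weight and raises ``ValueError``.
    """
    validate_cohort(cohort)
    if PHASE2_COL not in cohort.columns:
        raise ValueError("phase2 flags are not set; run two_phase_sample first")
    is_case = cohort[OUTCOME_COL].to_numpy() == 1
    phase2 = cohort[PHASE2_COL].to_numpy() == 1
    if np.any(is_case & ~phase2):
        raise ValueError("every case must have phase2 = 1")

    weights = np.full(len(cohort), np.nan)
    weights[is_case] = 1.0
    strata = cohort[STRATUM_COL].to_numpy()
    for s in pd.unique(strata):
        ctrl = (strata == s) & ~is_case
        n_total = int(ctrl.sum())
        n_sampled = int((ctrl & phase2).sum())
        if n_sampled == 0:
            if n_total > 0 and np.any(ctrl & phase2):  # pragma: no cover - defensive
                raise ValueError(f"stratum {s!r}: inconsistent sampling state")
            continue
        weights[ctrl & phase2] = n_total / n_sampled

    out = cohort.loc[phase2].copy()
    out[WEIGHT_COL] = weights[phase2]
    if out[WEIGHT_COL].isna().any():  # pragma: no cover - defensive
        raise ValueError("undefined weight for some phase-two subject")
    return out.reset_index(drop=True)
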