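"""Column conventions and CSV round-trip helpers for cohort tables.

A cohort (or phase-two) table is an ordinary :class:`pandas.DataFrame` with
one row per subject and the following reserved columns:

``subject_id``
    unique identifier (integer or string).
``outcome``
    binary endpoint, 1 = case, 0 = control.
``stratum``
    sampling stratum label (e.g. ``"bmi1.race0"``).
``age``, ``bmi``, ``risk_score``
    clinical covariates, always carried along.
``phase2``
    1 if the subject was selected into the biomarker subsample.
``weight``
    inverse sampling probability weight; present only on phase-two tables.

Marker columns are tagged by name prefix: ``tcell_0001 ...`` for the T-cell
set and ``ab_0001 ...`` for the antibody set.
"""

from __future__ import annotations

from pathlib import Path


import pandas as pd

ID_COL = "subject_id"
OUTCOME_COL = "outcome"
STRATUM_COL = "stratum"
PHASE2_COL = "phase2"
WEIGHT_COL = "weight"
COVARIATES: tuple[str, ...] = ("age", "bmi", "risk_score")

TCELL_PREFIX = "tcell_"
ANTIBODY_PREFIX = "ab_"

MARKER_SETS = ("all", "tcell", "antibody", "none")


def marker_columns(df: pd.DataFrame, marker_set: str = "all") -> list[str]:
    """Resolve a named marker set against a table's tagged columns.

    ``marker_set`` is one of ``"all"``, ``"tcell"``, ``"antibody"`` or
    ``"none"`` (the clinical-covariates-only analysis).
    """
    if marker_set not in MARKER_SETS:
        raise ValueError(f"unknown marker set {marker_set!r}; expected one of {MARKER_SETS}")
    tcell = [c for c in df.columns if c.startswith(TCELL_PREFIX)]
    antibody = [c for c in df.columns if c.startswith(ANTIBODY_PREFIX)]
    if marker_set == "all":
        return tcell + antibody
    if marker_set == "tcell":
        return tcell
    if marker_set == "antibody":
        return antibody
    return []


def feature_columns(
    df: pd.DataFrame, marker_set: str = "all", include_covariates: bool = True
) -> list[str]:
    """Marker columns for ``marker_set`` plus (optionally) the clinical covariates."""
    cols = marker_columns(df, marker_set)
    if include_covariates:
        cols = list(COVARIATES) + cols
    return cols


def validate_cohort(df: pd.DataFrame, require_weight: bool = False) -> None:
    """Raise ``ValueError`` if a table violates the cohort-table contract."""
    required: list[str] = [ID_COL, OUTCOME_COL, STRATUM_COL, *COVARIATES]
    if require_weight:
        required.append(WEIGHT_COL)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df[ID_COL].duplicated().any():
        raise ValueError("subject_id values are not unique")
    if not df[OUTCOME_COL].isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    if require_weight and (df[WEIGHT_COL] <= 0).any():
        raise ValueError("weights must be positive")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path, require_weight: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_cohort(df, require_weight=require_weight)
    return df


def stable_key(*parts: object) -> str:
    """Deterministic string key for caching/seeding derived from repr()s."""
    return "|".join(repr(p) for p in parts)
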