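"""Design-matrix construction and table validation helpers."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import DataError, ModelError

#: canonical column names expected after any CLI-level renaming
PERSON_COL = "person_id"
DAY_COL = "day"
INTAKE_COL = "intake"
WEIGHT_COL = "weight"


def validate_recall_table(table: pd.DataFrame, require_weight: bool = False) -> pd.DataFrame:
    """Check a person-day recall table and return a normalized copy.

    Requires ``person_id`` and ``intake`` columns; ``day`` defaults to 1 and
    ``weight`` to 1.0 when absent.  Intakes must be finite and >= 0, weights
    finite and >= 0, and (person_id, day) pairs unique.
    """
    if not isinstance(table, pd.DataFrame):
        raise DataError("recall table must be a pandas DataFrame")
    df = table.copy()
    for col in (PERSON_COL, INTAKE_COL):
        if col not in df.columns:
            raise DataError(f"recall table is missing required column {col!r}")
    if DAY_COL not in df.columns:
        df[DAY_COL] = 1
    if WEIGHT_COL not in df.columns:
        if require_weight:
            raise DataError("recall table is missing required column 'weight'")
        df[WEIGHT_COL] = 1.0
    intake = df[INTAKE_COL].to_numpy(dtype=float)
    if not np.all(np.isfinite(intake)):
        bad = df.index[~np.isfinite(intake)].tolist()[:5]
        raise DataError(f"non-finite intakes at rows {bad}")
    if np.any(intake < 0):
        bad = df.index[intake < 0].tolist()[:5]
        raise DataError(f"negative intakes at rows {bad}")
    w = df[WEIGHT_COL].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise DataError("survey weights must be finite and nonnegative")
    dup = df.duplicated(subset=[PERSON_COL, DAY_COL])
    if dup.any():
        raise DataError(
            f"duplicate (person_id, day) pairs at rows {df.index[dup].tolist()[:5]}"
        )
    return df


def first_recall_per_person(df: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    """Keep only each person's earliest recall day (one row per person)."""
    if df.groupby(PERSON_COL, sort=False)[DAY_COL].size().max() > 1:
        if warn:
            warnings.warn(
                "table contains repeated recalls; the single-recall model uses "
                "only the first recall per person",
                UserWarning,
                stacklevel=3,
            )
        df = df.sort_values([PERSON_COL, DAY_COL], kind="stable")
        df = df.drop_duplicates(subset=PERSON_COL, keep="first")
    return df.reset_index(drop=True)


def build_design(
    df: pd.DataFrame,
    person_covariates=(),
    temporal_covariates=(),
) -> tuple[np.ndarray, list[str]]:
    """Assemble [1 | person covariates | temporal covariates] as an ndarray."""
    names = ["const", *person_covariates, *temporal_covariates]
    cols = [np.ones(len(df))]
    for c in (*person_covariates, *temporal_covariates):
        if c not in df.columns:
            raise DataError(f"covariate column {c!r} not found in table")
        v = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise DataError(f"covariate {c!r} contains non-finite values")
        cols.append(v)
    return np.column_stack(cols), names


def check_full_rank(Xw: np.ndarray, names: list[str]) -> None:
    """Raise :class:`ModelError` naming the redundant columns if Xw is rank deficient."""
    _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < Xw.shape[1]:
        offenders = [names[j] for j in piv[rank:]]
        raise ModelError(f"collinear covariates: {offenders}")


def linear_predictor_at_daytype(
    df: pd.DataFrame,
    coef: "pd.Series",
    person_covariates,
    temporal_covariates,
    temporal_value: float,
) -> np.ndarray:
    """Linear predictor with every temporal covariate set to ``temporal_value``.

    Temporal covariates are assumed to be 0/1 indicators (e.g. a weekend
    flag), so 0 selects the weekday level and 1 the weekend level.
    """
    lp = np.full(len(df), coef["const"], dtype=float)
    for c in person_covariates:
        lp += coef[c] * df[c].to_numpy(dtype=float)
    for c in temporal_covariates:
        lp += coef[c] * temporal_value
    return lp
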