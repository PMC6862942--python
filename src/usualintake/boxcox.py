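"""Box-Cox utilities and normal-probability-plot selection of the power.

Twenty-four-hour recall amounts are right skewed, so both fitters model
them after a Box-Cox transformation ``g(x; lambda) = (x**lambda - 1)/lambda``
(natural log at ``lambda = 0``).  For single-recall data the power is
chosen by a formalized normal probability plot: for each candidate lambda
on a grid the survey-weighted regression of transformed intake on the
covariates is refit, the 1st-99th survey-weighted percentiles of the
residuals are plotted against standard-normal quantiles, and the lambda
whose plot is most linear (largest R^2) wins.  This extends the usual
graphical normality check to complex-survey data, which classical
normality tests do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from ._design import (
    INTAKE_COL,
    WEIGHT_COL,
    build_design,
    check_full_rank,
    validate_recall_table,
)
from ._stats import weighted_quantile
from .exceptions import ConfigError, DataError, ModelError

__all__ = [
    "LambdaGrid",
    "LambdaSelection",
    "transform",
    "inverse_transform",
    "normal_plot_r2",
    "select_lambda",
    "shift_zero_intakes",
]


def transform(x, lam: float):
    """Box-Cox transform ``(x**lam - 1)/lam`` with ``lam = 0`` meaning log.

    Computed as ``expm1(lam * log x)/lam`` so the map is numerically
    continuous in lam at 0.  Raises :class:`DataError` identifying the
    offending records if any input is nonpositive.
    """
    scalar = np.ndim(x) == 0
    xa = np.asarray(x, dtype=float)
    bad = ~(xa > 0)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise DataError(
            f"Box-Cox transform requires positive amounts; "
            f"{idx.size} nonpositive record(s), first indices {idx[:5].tolist()}"
        )
    logx = np.log(xa)
    out = logx if lam == 0 else np.expm1(lam * logx) / lam
    return float(out) if scalar else out


def inverse_transform(y, lam: float):
    """Inverse Box-Cox ``(lam*y + 1)**(1/lam)`` (``exp`` at lam = 0).

    Arguments with ``lam*y + 1 <= 0`` have no positive preimage; they are
    clipped to 0 (intake cannot be negative).  Callers that need the clip
    count should test ``lam*y + 1 <= 0`` themselves before calling.
    """
    scalar = np.ndim(y) == 0
    ya = np.asarray(y, dtype=float)
    if lam == 0:
        out = np.exp(ya)
    else:
        base = lam * ya
        ok = base > -1.0
        safe = np.where(ok, base, 0.0)  # placeholder in the clipped branch
        out = np.where(ok, np.exp(np.log1p(safe) / lam), 0.0)
    return float(out) if scalar else out


def shift_zero_intakes(intake: np.ndarray, policy: str = "shift") -> tuple[np.ndarray, np.ndarray, int]:
    """Handle zero intakes before a Box-Cox fit.

    A nearly-daily consumed component has < 5% zero values; the transform
    still requires strict positivity.  ``policy="shift"`` (default) replaces
    zeros by half the smallest positive observed intake, ``"drop"`` removes
    those records, ``"error"`` refuses.

    Returns ``(adjusted intakes, keep mask, number of zeros handled)``.
    """
    x = np.asarray(intake, dtype=float)
    zeros = x == 0
    n_zero = int(zeros.sum())
    keep = np.ones(x.size, dtype=bool)
    if n_zero == 0:
        return x, keep, 0
    if policy == "error":
        raise DataError(f"{n_zero} zero intakes present and zero_handling='error'")
    if policy == "drop":
        return x, ~zeros, n_zero
    if policy != "shift":
        raise ConfigError(f"unknown zero_handling policy {policy!r}")
    positive = x[x > 0]
    if positive.size == 0:
        raise DataError("all intakes are zero; nothing to model")
    out = x.copy()
    out[zeros] = 0.5 * positive.min()
    return out, keep, n_zero


def normal_plot_r2(residuals, weights=None) -> float:
    """R^2 of the normal probability plot built from percentiles 1..99.

    Survey-weighted empirical percentiles ``p = 1..99`` of the residuals
    are paired with standard-normal quantiles ``Phi^{-1}(p/100)``; the
    squared Pearson correlation of the 99 pairs measures linearity, i.e.
    how normal the residual distribution looks.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 100:
        warnings.warn(
            f"normal_plot_r2 with only {r.size} residuals: percentiles are "
            "heavily interpolated",
            UserWarning,
            stacklevel=2,
        )
    if np.ptp(r) == 0:
        raise DataError("residuals have zero variance; normal plot R^2 undefined")
    p = np.arange(1, 100) / 100.0
    emp = weighted_quantile(r, p, weights)
    if np.ptp(emp) == 0:
        raise DataError("residual percentiles are constant; R^2 undefined")
    z = stats.norm.ppf(p)
    corr = np.corrcoef(z, emp)[0, 1]
    return float(corr**2)


@dataclass(frozen=True)
class LambdaGrid:
    """Candidate Box-Cox powers: ``lo`` to ``hi`` in steps of ``step``.

    The default grid 0, 0.01, ..., 1 contains the log case exactly.
    """

    lo: float = 0.0
    hi: float = 1.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError("lambda grid step must be > 0")
        if self.lo < 0:
            raise ConfigError("lambda grid must start at >= 0")
        if self.hi < self.lo:
            raise ConfigError("lambda grid upper end below lower end")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        vals = self.lo + self.step * np.arange(n + 1)
        return np.round(vals, 12)


@dataclass
class LambdaSelection:
    """Result of the grid search: the winning power and the full profile."""

    lambda_hat: float
    r_squared: float
    lambdas: np.ndarray = field(repr=False)
    r2: np.ndarray = field(repr=False)

    @property
    def profile(self) -> list[tuple[float, float]]:
        return list(zip(self.lambdas.tolist(), self.r2.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "r2": self.r2})


def select_lambda(
    table: pd.DataFrame,
    person_covariates=(),
    temporal_covariates=(),
    grid: LambdaGrid | None = None,
    zero_handling: str = "shift",
) -> LambdaSelection:
    """Choose the Box-Cox power maximizing normal-plot linearity.

    For every lambda on the grid the survey-weighted least-squares
    regression of transformed intake on the covariates is refit and
    :func:`normal_plot_r2` scored on its residuals.  Ties (equal R^2 to
    machine precision) resolve to the smaller lambda.  The profile is
    deterministic given the data; a lambda whose fit or score fails is
    recorded as NaN and skipped with a warning.
    """
    grid = grid if grid is not None else LambdaGrid()
    df = validate_recall_table(table)
    intake = df[INTAKE_COL].to_numpy(dtype=float)
    intake, keep, _ = shift_zero_intakes(intake, zero_handling)
    df = df[keep].reset_index(drop=True)
    intake = intake[keep]

    X, names = build_design(df, person_covariates, temporal_covariates)
    w = df[WEIGHT_COL].to_numpy(dtype=float)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    check_full_rank(Xw, names)
    Q, R = np.linalg.qr(Xw)

    lambdas = grid.values
    r2 = np.full(lambdas.size, np.nan)
    for i, lam in enumerate(lambdas):
        try:
            y = transform(intake, lam)
            beta = scipy.linalg.solve_triangular(R, Q.T @ (y * sw))
            resid = y - X @ beta
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                r2[i] = normal_plot_r2(resid, w)
        except (DataError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"lambda={lam:g} skipped: {exc}", UserWarning, stacklevel=2)
    if np.all(np.isnan(r2)):
        raise ModelError("normal-plot R^2 could not be computed for any lambda")
    best = int(np.nanargmax(r2))  # first max -> smallest lambda on ties
    return LambdaSelection(
        lambda_hat=float(lambdas[best]),
        r_squared=float(r2[best]),
        lambdas=lambdas,
        r2=r2,
    )
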