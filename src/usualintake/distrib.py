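"""From fitted parameters to the population usual-intake distribution.

A person's usual intake is their long-run average daily intake on the
original scale.  Under the fitted model the recall on a type-t day is
``g^{-1}(lp_t + u + e; lambda)`` with ``e ~ N(0, sigma^2_e)``, so the
usual intake of a person with effect u is

    T(u) = sum_t pi_t * E_e[ g^{-1}(lp_t + u + e; lambda) ],

the day-type-weighted expectation over the within-person error — this is
the analytic correction for within-person variation.  The inner
expectation is computed by Gauss-Hermite quadrature (default 9 nodes).
The population distribution is represented by a pseudo-population: each
sampled person i contributes M independent draws of ``u ~ N(0, sigma^2_u)``,
each carrying weight ``w_i / M``; means, percentiles and the proportion
below a cutoff (the EAR cut-point prevalence of inadequate intake) are
survey-weighted summaries of the pseudo-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boxcox
from ._stats import weighted_mean, weighted_quantile
from .exceptions import ConfigError, DataError, ModelError

__all__ = [
    "DayTypeWeights",
    "UsualIntakeDistribution",
    "usual_intake_of_person",
    "estimate_distribution",
    "prevalence_below",
]


@dataclass(frozen=True)
class DayTypeWeights:
    """Calendar shares of the two day types.

    Defaults follow a Friday-Sunday weekend definition: 4/7 weekday,
    3/7 weekend.
    """

    weekday: float = 4.0 / 7.0
    weekend: float = 3.0 / 7.0

    def __post_init__(self) -> None:
        if self.weekday < 0 or self.weekend < 0:
            raise ConfigError("day-type weights must be nonnegative")
        if abs(self.weekday + self.weekend - 1.0) > 1e-9:
            raise ConfigError("day-type weights must sum to 1")


def _gh_nodes(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite abscissae/probabilities for a standard normal."""
    if nodes < 3 or nodes % 2 == 0:
        raise ConfigError("quadrature nodes must be an odd integer >= 3")
    x, w = np.polynomial.hermite.hermgauss(nodes)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def _daytype_mean(lp, lam, sigma_e, z, pz):
    """E_e[g^{-1}(lp + e)] by quadrature; also returns clip count."""
    y = np.asarray(lp, dtype=float)[..., None] + sigma_e * z
    if lam != 0:
        n_clip = int(np.count_nonzero(lam * y <= -1.0))
    else:
        n_clip = 0
    vals = boxcox.inverse_transform(y, lam)
    return vals @ pz, n_clip, y.size


def usual_intake_of_person(
    lp_weekday: float,
    lp_weekend: float,
    u: float,
    lam: float,
    var_within: float,
    daytype: DayTypeWeights | None = None,
    nodes: int = 9,
) -> float:
    """Usual intake (original units/day) of one person with effect ``u``.

    Averages the back-transformed expectation over the within-person error
    at each day type, then over day types.  Quadrature handles the inner
    expectation; back-transform arguments with no positive preimage clip
    to zero intake.
    """
    daytype = daytype if daytype is not None else DayTypeWeights()
    z, pz = _gh_nodes(nodes)
    sigma_e = float(np.sqrt(var_within))
    e_wd, _, _ = _daytype_mean(lp_weekday + u, lam, sigma_e, z, pz)
    e_we, _, _ = _daytype_mean(lp_weekend + u, lam, sigma_e, z, pz)
    return float(daytype.weekday * e_wd + daytype.weekend * e_we)


@dataclass
class UsualIntakeDistribution:
    """Weighted pseudo-population of usual intakes plus its summaries."""

    pseudo_values: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    mean: float
    percentile_levels: np.ndarray
    percentile_values: np.ndarray
    clipped_fraction: float
    cutoff: float | None
    prevalence: float | None
    settings: dict

    def percentile(self, p: float) -> float:
        """Weighted percentile of usual intake at level p (percent)."""
        return weighted_quantile(self.pseudo_values, p / 100.0, self.weights)

    def prevalence_below(self, cutoff: float) -> float:
        """Weighted proportion of the population with usual intake < cutoff."""
        if not cutoff > 0:
            raise ConfigError("cutoff must be positive")
        below = self.pseudo_values < cutoff
        return float(np.sum(self.weights[below]) / np.sum(self.weights))

    def to_frame(self) -> pd.DataFrame:
        """Percentile table: one row per requested percentile."""
        return pd.DataFrame(
            {"percentile": self.percentile_levels, "intake": self.percentile_values}
        )


def estimate_distribution(
    fit,
    table: pd.DataFrame | None = None,
    M: int = 100,
    daytype: DayTypeWeights | None = None,
    nodes: int = 9,
    seed: int = 0,
    percentiles=None,
    cutoff: float | None = None,
) -> UsualIntakeDistribution:
    """Estimate the population usual-intake distribution from a fitted model.

    Parameters
    ----------
    fit : OneDayModel or AmountOnlyModel (fitted)
        Supplies lambda, variance components and per-person linear
        predictors.  Either fitter's parameters work interchangeably.
    table : DataFrame, optional
        Recall table to (re)compute linear predictors from, for models
        reloaded from a parameter file.
    M : int
        Pseudo-persons (person-effect draws) per sampled person.
    daytype : DayTypeWeights
        Day-type shares; default 4/7 weekday, 3/7 weekend.
    nodes : int
        Gauss-Hermite nodes for the within-person expectation (odd, >= 3).
    seed : int
        Seed for the person-effect draws; results are deterministic given it.
    percentiles : sequence, optional
        Percentile levels to tabulate (default 1..99).
    cutoff : float, optional
        EAR-type cutoff; when given, the prevalence of usual intake below
        it is included in the summaries.
    """
    daytype = daytype if daytype is not None else DayTypeWeights()
    if table is not None:
        fit.attach_table(table)
    lp = getattr(fit, "linear_predictors_", None)
    if lp is None:
        raise ModelError(
            "fit has no linear predictors; pass the recall table to recompute them"
        )
    if not fit.var_between_ >= 0:
        raise DataError("between-person variance must be nonnegative")
    if M < 1:
        raise ConfigError("M must be >= 1")
    percentiles = np.asarray(
        list(percentiles) if percentiles is not None else np.arange(1, 100), dtype=float
    )

    sigma_u = float(np.sqrt(fit.var_between_))
    sigma_e = float(np.sqrt(fit.var_within_))
    lam = float(fit.lambda_)
    z, pz = _gh_nodes(nodes)

    rng = np.random.default_rng(seed)
    n = len(lp)
    u = sigma_u * rng.standard_normal((n, M))
    lp_wd = lp["lp_weekday"].to_numpy(dtype=float)[:, None] + u
    lp_we = lp["lp_weekend"].to_numpy(dtype=float)[:, None] + u
    e_wd, c1, t1 = _daytype_mean(lp_wd, lam, sigma_e, z, pz)
    e_we, c2, t2 = _daytype_mean(lp_we, lam, sigma_e, z, pz)
    pseudo = (daytype.weekday * e_wd + daytype.weekend * e_we).ravel()
    weights = np.repeat(lp["weight"].to_numpy(dtype=float) / M, M)

    mean = weighted_mean(pseudo, weights)
    pct_values = weighted_quantile(pseudo, percentiles / 100.0, weights)
    settings = {"M": M, "nodes": nodes, "seed": seed,
                "daytype": (daytype.weekday, daytype.weekend)}
    dist = UsualIntakeDistribution(
        pseudo_values=pseudo,
        weights=weights,
        mean=mean,
        percentile_levels=percentiles,
        percentile_values=np.asarray(pct_values, dtype=float),
        clipped_fraction=(c1 + c2) / (t1 + t2),
        cutoff=cutoff,
        prevalence=None,
        settings=settings,
    )
    if cutoff is not None:
        dist.prevalence = dist.prevalence_below(cutoff)
    return dist


def prevalence_below(dist: UsualIntakeDistribution, cutoff: float) -> float:
    """Weighted proportion of the pseudo-population strictly below ``cutoff``."""
    return dist.prevalence_below(cutoff)
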