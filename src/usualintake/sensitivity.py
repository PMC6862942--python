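"""Variance-ratio mis-specification sweep.

The external variance ratio is the one input of the single-recall method
that cannot be checked against the data, so its effect is probed by
rerunning the distribution stage with the ratio scaled to 25%, 50%, 75%,
90%, 110%, 125%, 150%, 175% and 200% of the nominal value (plus the
nominal run itself).  Only the variance split is recomputed per
multiplier — the Box-Cox power and regression coefficients stay fixed at
the nominal fit, because the external ratio enters the workflow after
transformation and regression — and the same person-effect seed is reused
so that differences between rows reflect the ratio, not Monte-Carlo
noise.  Underestimating the ratio inflates the between-person component
and spreads the distribution; overestimating concentrates it.  The mean
is unaffected either way.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .distrib import DayTypeWeights, estimate_distribution
from .exceptions import ConfigError
from .oneday import OneDayModel
from .variance import WITHIN_TO_BETWEEN, VarianceRatio, split_variance

__all__ = ["DEFAULT_MULTIPLIERS", "SweepResult", "run_sweep", "density_curves"]

#: the nine published sweep fractions; run_sweep appends the nominal 1.0
DEFAULT_MULTIPLIERS = (0.25, 0.50, 0.75, 0.90, 1.10, 1.25, 1.50, 1.75, 2.00)


@dataclass
class SweepResult:
    """Per-multiplier usual-intake summaries.

    ``table`` has one row per multiplier with columns multiplier, mean,
    p25/p50/p75 (or the requested percentiles) and, when a cutoff was
    supplied, prevalence_below.
    """

    table: pd.DataFrame
    nominal_ratio: VarianceRatio
    settings: dict = field(default_factory=dict)
    distributions: dict = field(default_factory=dict, repr=False)


def run_sweep(
    table: pd.DataFrame | None = None,
    *,
    fit: OneDayModel | None = None,
    ratio: VarianceRatio | float | None = None,
    person_covariates=(),
    temporal_covariates=(),
    multipliers=None,
    cutoff: float | None = None,
    percentiles=(25, 50, 75),
    M: int = 100,
    nodes: int = 9,
    seed: int = 0,
    daytype: DayTypeWeights | None = None,
    grid=None,
    keep_distributions: bool = False,
) -> SweepResult:
    """Sweep the external variance ratio and summarize the response.

    Either pass a fitted :class:`OneDayModel` as ``fit`` or a recall table
    plus ``ratio``/covariates to fit the nominal model here.  For each
    multiplier m the total variance is re-split with the nominal
    within:between ratio scaled by m (converted to the within:between
    convention first, which stays valid for any m > 0), the distribution
    stage reruns with the identical seed, and mean, percentiles and
    optional prevalence are recorded.  The nominal multiplier 1.0 is
    always included.
    """
    if fit is None:
        if table is None or ratio is None:
            raise ConfigError("run_sweep needs either a fitted model or table + ratio")
        fit = OneDayModel(
            ratio=ratio,
            person_covariates=person_covariates,
            temporal_covariates=temporal_covariates,
            grid=grid,
        ).fit(table)

    mults = list(multipliers) if multipliers is not None else list(DEFAULT_MULTIPLIERS)
    if any(m <= 0 for m in mults):
        raise ConfigError("multipliers must be positive")
    if 1.0 not in mults:
        mults.append(1.0)
    mults = sorted(mults)

    alpha = fit.ratio_.alpha
    V = fit.total_variance_
    rows = []
    dists = {}
    for m in mults:
        scaled = VarianceRatio(alpha * m, WITHIN_TO_BETWEEN)
        between, within = split_variance(V, scaled)
        variant = copy.copy(fit)
        variant.var_between_ = between
        variant.var_within_ = within
        variant.ratio_ = scaled
        dist = estimate_distribution(
            variant, M=M, daytype=daytype, nodes=nodes, seed=seed,
            percentiles=percentiles, cutoff=cutoff,
        )
        row = {"multiplier": m, "mean": dist.mean}
        for p, v in zip(dist.percentile_levels, dist.percentile_values):
            row[f"p{p:g}"] = v
        if cutoff is not None:
            row["prevalence_below"] = dist.prevalence
        rows.append(row)
        if keep_distributions:
            dists[m] = dist

    settings = {"M": M, "nodes": nodes, "seed": seed, "cutoff": cutoff,
                "lambda": fit.lambda_, "total_variance": V}
    return SweepResult(
        table=pd.DataFrame(rows),
        nominal_ratio=fit.ratio_,
        settings=settings,
        distributions=dists,
    )


def density_curves(sweep: SweepResult, grid_points: int = 200) -> pd.DataFrame:
    """Weighted kernel-density curves per multiplier for sweep figures.

    Requires ``run_sweep(..., keep_distributions=True)``.  Returns a long
    DataFrame with columns multiplier, intake, density.
    """
    if not sweep.distributions:
        raise ConfigError("sweep was run without keep_distributions=True")
    lo = min(d.pseudo_values.min() for d in sweep.distributions.values())
    hi = max(d.pseudo_values.max() for d in sweep.distributions.values())
    xs = np.linspace(lo, hi, grid_points)
    frames = []
    for m, dist in sweep.distributions.items():
        kde = gaussian_kde(dist.pseudo_values, weights=dist.weights)
        frames.append(
            pd.DataFrame({"multiplier": m, "intake": xs, "density": kde(xs)})
        )
    return pd.concat(frames, ignore_index=True)
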