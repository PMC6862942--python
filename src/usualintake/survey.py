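"""Balanced repeated replication (BRR) standard errors and equivalence tests.

Complex-survey point estimates get their standard errors by recomputing
the statistic under each of R half-sample replicate weight sets:

    SE = sqrt( 1 / (R (1-F)^2) * sum_r (theta_r - theta_full)^2 )

with Fay coefficient F (F = 0 is classical BRR; NHANES releases typically
use Fay weights).  Whether two methods' estimates of the same quantity
agree within a practical margin is judged by two one-sided z-tests
(TOST): equivalence is declared when both one-sided tests of
H0: |a - b| >= margin reject at level 0.05.  Margins follow the
convention of 5% of the reference estimate for means and percentiles and
an absolute 0.5 percentage points for prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import WEIGHT_COL
from .amount_only import AmountOnlyModel, extract_ratio
from .distrib import DayTypeWeights, estimate_distribution
from .exceptions import ConfigError, DataError
from .oneday import OneDayModel

__all__ = [
    "ReplicateEstimates",
    "EquivalenceResult",
    "brr_se",
    "tost_equivalence",
    "margin_for",
    "replicate_weight_columns",
    "compare_methods",
]


@dataclass
class ReplicateEstimates:
    """A full-sample estimate plus its R replicate-weight re-estimates."""

    full_sample_estimate: float
    replicate_estimates: np.ndarray
    fay_coefficient: float = 0.0

    def __post_init__(self) -> None:
        self.replicate_estimates = np.asarray(self.replicate_estimates, dtype=float)
        if self.replicate_estimates.size < 1:
            raise ConfigError("need at least one replicate estimate")
        if not 0 <= self.fay_coefficient < 1:
            raise ConfigError("Fay coefficient must lie in [0, 1)")
        if not np.all(np.isfinite(self.replicate_estimates)) or not np.isfinite(
            self.full_sample_estimate
        ):
            raise DataError("replicate estimates must be finite")


def brr_se(rep: ReplicateEstimates) -> float:
    """BRR standard error of the full-sample estimate."""
    dev = rep.replicate_estimates - rep.full_sample_estimate
    R = rep.replicate_estimates.size
    return float(np.sqrt(np.sum(dev**2) / (R * (1.0 - rep.fay_coefficient) ** 2)))


@dataclass
class EquivalenceResult:
    """Outcome of a TOST comparison of two estimates of the same quantity."""

    estimate_a: float
    estimate_b: float
    difference: float
    se_difference: float
    margin: float
    p_value: float
    equivalent: bool
    statistic: str = ""


def tost_equivalence(
    a: float, b: float, se_diff: float, margin: float, alpha: float = 0.05
) -> EquivalenceResult:
    """Two one-sided z-tests of H0: |a - b| >= margin.

    The reported p-value is the larger of the two one-sided p-values;
    equivalence is declared when it falls below ``alpha``.
    """
    if not margin > 0:
        raise ConfigError("equivalence margin must be positive")
    if not se_diff > 0:
        raise ConfigError("standard error of the difference must be positive")
    d = a - b
    p_lower = stats.norm.sf((d + margin) / se_diff)   # H0: d <= -margin
    p_upper = stats.norm.cdf((d - margin) / se_diff)  # H0: d >= +margin
    p = float(max(p_lower, p_upper))
    return EquivalenceResult(
        estimate_a=float(a),
        estimate_b=float(b),
        difference=float(d),
        se_difference=float(se_diff),
        margin=float(margin),
        p_value=p,
        equivalent=bool(p < alpha),
    )


def margin_for(statistic_kind: str, reference_value: float | None = None) -> float:
    """Equivalence margin for a statistic kind.

    Means and percentiles use a relative 5% of the reference estimate;
    prevalences use an absolute 0.5 percentage points (0.005 as a
    proportion).
    """
    kind = statistic_kind.lower()
    if kind in ("mean", "percentile", "median"):
        if reference_value is None or not reference_value > 0:
            raise ConfigError("relative margins need a positive reference value")
        return 0.05 * float(reference_value)
    if kind == "prevalence":
        return 0.005
    raise ConfigError(f"unknown statistic kind {statistic_kind!r}")


def replicate_weight_columns(table: pd.DataFrame, prefix: str = "repwt_") -> list[str]:
    """Replicate-weight columns matching ``prefix``, in numeric suffix order."""
    cols = [c for c in table.columns if c.startswith(prefix)]

    def _key(c):
        tail = c[len(prefix):]
        return (0, int(tail)) if tail.isdigit() else (1, tail)

    return sorted(cols, key=_key)


def _summaries(dist, percentiles, cutoff):
    out = {"mean": dist.mean}
    for p in percentiles:
        out[f"p{p:g}"] = dist.percentile(p)
    if cutoff is not None:
        out["prevalence"] = dist.prevalence_below(cutoff)
    return out


def _stat_kind(name: str) -> str:
    if name == "mean":
        return "mean"
    if name == "prevalence":
        return "prevalence"
    return "percentile"


def compare_methods(
    table: pd.DataFrame,
    person_covariates=(),
    temporal_covariates=(),
    cutoff: float | None = None,
    percentiles=(25, 50, 75),
    repwt_prefix: str = "repwt_",
    fay: float = 0.0,
    M: int = 100,
    nodes: int = 9,
    seed: int = 0,
    daytype: DayTypeWeights | None = None,
    grid=None,
    reselect_lambda: bool = False,
) -> pd.DataFrame:
    """Head-to-head comparison of the two fitters on one replicate-recall table.

    Fits the replicate-recall mixed model on all recalls, extracts its
    within:between ratio, fits the single-recall model on the first recall
    per person with that ratio, and tests the equivalence of means,
    percentiles and (if ``cutoff`` given) prevalence.  Standard errors of
    the between-method differences come from rerunning *both* methods
    under each replicate weight set and differencing per replicate, which
    respects the correlation induced by the shared sample.  Replicate
    reruns keep each method's full-sample Box-Cox power unless
    ``reselect_lambda`` is set.

    Returns a DataFrame with one row per statistic.
    """

    from ._design import first_recall_per_person, validate_recall_table

    day1 = first_recall_per_person(validate_recall_table(table), warn=False)

    def run_pair(df, df1, lam_a=None, lam_o=None):
        am = AmountOnlyModel(
            person_covariates, temporal_covariates, grid=grid, lam=lam_a
        ).fit(df)
        ratio = extract_ratio(am)
        od = OneDayModel(
            ratio=ratio,
            person_covariates=person_covariates,
            temporal_covariates=temporal_covariates,
            grid=grid,
            lam=lam_o,
        ).fit(df1)
        kw = dict(M=M, nodes=nodes, seed=seed, daytype=daytype, cutoff=cutoff,
                  percentiles=percentiles)
        stats_a = _summaries(estimate_distribution(am, **kw), percentiles, cutoff)
        stats_o = _summaries(estimate_distribution(od, **kw), percentiles, cutoff)
        return am, od, stats_a, stats_o

    am, od, full_a, full_o = run_pair(table, day1)
    lam_a = None if reselect_lambda else am.lambda_
    lam_o = None if reselect_lambda else od.lambda_

    rep_cols = replicate_weight_columns(table, repwt_prefix)
    if not rep_cols:
        raise DataError(
            f"no replicate weight columns with prefix {repwt_prefix!r}; "
            "cannot compute BRR standard errors"
        )
    diffs = {k: [] for k in full_a}
    for col in rep_cols:
        rep_table = table.copy()
        rep_table[WEIGHT_COL] = rep_table[col]
        rep_day1 = day1.copy()
        rep_day1[WEIGHT_COL] = rep_day1[col]
        _, _, rep_a, rep_o = run_pair(rep_table, rep_day1, lam_a=lam_a, lam_o=lam_o)
        for k in diffs:
            diffs[k].append(rep_a[k] - rep_o[k])

    rows = []
    for k in full_a:
        rep = ReplicateEstimates(full_a[k] - full_o[k], np.asarray(diffs[k]), fay)
        se = brr_se(rep)
        margin = margin_for(_stat_kind(k), full_a[k] if _stat_kind(k) != "prevalence" else None)
        result = tost_equivalence(full_a[k], full_o[k], max(se, 1e-12), margin)
        result.statistic = k
        rows.append(
            {
                "statistic": k,
                "amount_only": result.estimate_a,
                "oneday": result.estimate_b,
                "difference": result.difference,
                "se_difference": result.se_difference,
                "margin": result.margin,
                "p_value": result.p_value,
                "equivalent": result.equivalent,
            }
        )
    return pd.DataFrame(rows)
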