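"""Single-recall ("1-d") fitter: transform, regress, split by external ratio.

The model for a single recall per person is, on the Box-Cox scale,

    g(R_i; lambda) = beta0 + sum_k beta_k X_ki + sum_l beta_l Z_li + d_i,
    d_i = u_i + e_i,  u_i ~ N(0, sigma^2_u),  e_i ~ N(0, sigma^2_e),

where X are person-level covariates (age, race/ethnicity indicators) and
Z temporal covariates (weekend indicator).  One recall per person only
identifies var(d_i) = V; an external within:between variance ratio from a
replicate-recall study supplies the split into sigma^2_u and sigma^2_e.

Fitting proceeds in three steps: choose lambda by the weighted
normal-probability-plot criterion, estimate coefficients by
survey-weighted least squares, then split the weighted residual variance
with the external ratio.  Linear predictors are stored per person at both
the weekday and weekend level of the temporal covariates so the
distribution stage can average over day types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from . import boxcox
from ._design import (
    INTAKE_COL,
    PERSON_COL,
    WEIGHT_COL,
    build_design,
    check_full_rank,
    first_recall_per_person,
    linear_predictor_at_daytype,
    validate_recall_table,
)
from ._stats import effective_sample_size
from .exceptions import ConfigError, ModelError
from .variance import VarianceRatio, split_variance

__all__ = ["OneDayModel", "fit_oneday"]


class OneDayModel(BaseEstimator):
    """Usual-intake model for data with a single 24-h recall per person.

    Parameters
    ----------
    ratio : VarianceRatio or float
        External variance ratio; a bare float is read in the convention
        given by ``ratio_type``.  Required.
    ratio_type : str
        Convention for a float ``ratio``: ``within_to_between`` (default),
        ``within_to_total`` or ``between_to_total``.
    person_covariates, temporal_covariates : sequence of str
        Column names; temporal covariates must be 0/1 day-type indicators.
    grid : LambdaGrid, optional
        Candidate Box-Cox powers (default 0..1 step 0.01).
    lam : float, optional
        Force this Box-Cox power instead of selecting one (used by
        replicate reruns, which keep the full-sample lambda).
    zero_handling : str
        "shift" (half minimum positive), "drop" or "error" for zero intakes.

    Attributes
    ----------
    lambda_ : float
        Selected (or forced) Box-Cox power.
    selection_ : LambdaSelection or None
        Grid-search profile (None when ``lam`` was forced).
    coef_ : pandas.Series
        Regression coefficients on the transformed scale, indexed by name.
    total_variance_ : float
        Weighted residual variance V of d_i with the (n_eff - p) correction.
    var_between_, var_within_ : float
        The external-ratio split of ``total_variance_``; they sum to V.
    ratio_ : VarianceRatio
        The ratio actually applied.
    linear_predictors_ : pandas.DataFrame
        One row per person: person_id, weight, lp_weekday, lp_weekend.
    n_zero_shifted_ : int
        Zero intakes adjusted before transformation.
    """

    def __init__(
        self,
        ratio=None,
        ratio_type="within_to_between",
        person_covariates=(),
        temporal_covariates=(),
        grid=None,
        lam=None,
        zero_handling="shift",
    ):
        self.ratio = ratio
        self.ratio_type = ratio_type
        self.person_covariates = person_covariates
        self.temporal_covariates = temporal_covariates
        self.grid = grid
        self.lam = lam
        self.zero_handling = zero_handling

    # ------------------------------------------------------------------
    def fit(self, table: pd.DataFrame, y=None) -> "OneDayModel":
        """Fit to a recall table (uses only the first recall per person)."""
        if self.ratio is None:
            raise ConfigError("the single-recall model requires an external variance ratio")
        ratio = (
            self.ratio
            if isinstance(self.ratio, VarianceRatio)
            else VarianceRatio(float(self.ratio), self.ratio_type)
        )
        pc = tuple(self.person_covariates)
        tc = tuple(self.temporal_covariates)

        df = validate_recall_table(table)
        df = first_recall_per_person(df)
        intake = df[INTAKE_COL].to_numpy(dtype=float)
        intake, keep, n_shift = boxcox.shift_zero_intakes(intake, self.zero_handling)
        df = df[keep].reset_index(drop=True)
        intake = intake[keep]

        X, names = build_design(df, pc, tc)
        n, p = X.shape
        if n < p + 2:
            raise ModelError(
                f"need at least {p + 2} persons to fit {p} coefficients; got {n}"
            )
        w = df[WEIGHT_COL].to_numpy(dtype=float)
        check_full_rank(X * np.sqrt(w)[:, None], names)

        if self.lam is not None:
            lam = float(self.lam)
            selection = None
        else:
            work = df.copy()
            work[INTAKE_COL] = intake  # zeros already shifted
            selection = boxcox.select_lambda(
                work, pc, tc, grid=self.grid, zero_handling="error"
            )
            lam = selection.lambda_hat

        yt = boxcox.transform(intake, lam)
        res = sm.WLS(yt, X, weights=w).fit()
        coef = pd.Series(res.params, index=names)
        resid = yt - X @ coef.to_numpy()

        n_eff = effective_sample_size(w)
        if n_eff <= p:
            raise ModelError("effective sample size does not exceed coefficient count")
        V = float(np.sum(w * resid**2) / np.sum(w) * n_eff / (n_eff - p))
        between, within = split_variance(V, ratio)

        self.lambda_ = lam
        self.selection_ = selection
        self.coef_ = coef
        self.total_variance_ = V
        self.var_between_ = between
        self.var_within_ = within
        self.ratio_ = ratio
        self.n_obs_ = n
        self.n_zero_shifted_ = n_shift
        self.feature_names_ = names
        self.linear_predictors_ = pd.DataFrame(
            {
                PERSON_COL: df[PERSON_COL].to_numpy(),
                WEIGHT_COL: w,
                "lp_weekday": linear_predictor_at_daytype(df, coef, pc, tc, 0.0),
                "lp_weekend": linear_predictor_at_daytype(df, coef, pc, tc, 1.0),
            }
        )
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        """Serializable parameter record (the TRAN1-style output file)."""
        return {
            "method": "oneday",
            "lambda": self.lambda_,
            "coefficients": {k: float(v) for k, v in self.coef_.items()},
            "V": self.total_variance_,
            "var_between": self.var_between_,
            "var_within": self.var_within_,
            "ratio_type": self.ratio_.ratio_type,
            "ratio_value": self.ratio_.value,
            "person_covariates": list(self.person_covariates),
            "temporal_covariates": list(self.temporal_covariates),
            "n_obs": self.n_obs_,
            "n_zero_shifted": self.n_zero_shifted_,
        }

    @classmethod
    def from_dict(cls, params: dict) -> "OneDayModel":
        """Rebuild a fitted model from :meth:`to_dict` output.

        ``linear_predictors_`` is not stored in the parameter file; call
        :meth:`attach_table` with the original data before estimating a
        distribution.
        """
        model = cls(
            ratio=params["ratio_value"],
            ratio_type=params["ratio_type"],
            person_covariates=tuple(params["person_covariates"]),
            temporal_covariates=tuple(params["temporal_covariates"]),
            lam=params["lambda"],
        )
        model.lambda_ = float(params["lambda"])
        model.selection_ = None
        model.coef_ = pd.Series(params["coefficients"])
        model.total_variance_ = float(params["V"])
        model.var_between_ = float(params["var_between"])
        model.var_within_ = float(params["var_within"])
        model.ratio_ = VarianceRatio(params["ratio_value"], params["ratio_type"])
        model.n_obs_ = int(params.get("n_obs", 0))
        model.n_zero_shifted_ = int(params.get("n_zero_shifted", 0))
        model.feature_names_ = list(model.coef_.index)
        return model

    def attach_table(self, table: pd.DataFrame) -> "OneDayModel":
        """Recompute per-person linear predictors from a recall table."""
        df = first_recall_per_person(validate_recall_table(table), warn=False)
        pc, tc = tuple(self.person_covariates), tuple(self.temporal_covariates)
        self.linear_predictors_ = pd.DataFrame(
            {
                PERSON_COL: df[PERSON_COL].to_numpy(),
                WEIGHT_COL: df[WEIGHT_COL].to_numpy(dtype=float),
                "lp_weekday": linear_predictor_at_daytype(df, self.coef_, pc, tc, 0.0),
                "lp_weekend": linear_predictor_at_daytype(df, self.coef_, pc, tc, 1.0),
            }
        )
        return self


def fit_oneday(table, ratio, ratio_type="within_to_between", **kwargs) -> OneDayModel:
    """Functional wrapper: fit an :class:`OneDayModel` and return it."""
    return OneDayModel(ratio=ratio, ratio_type=ratio_type, **kwargs).fit(table)
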