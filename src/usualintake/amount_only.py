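"""Replicate-recall ("amount-only") mixed-model fitter.

With two or more nonconsecutive recalls on at least a subset of persons
the model

    g(R_ij; lambda) = beta0 + sum_k beta_k X_ki + sum_l beta_l Z_lij
                      + u_i + e_ij

identifies both variance components directly: u_i ~ N(0, sigma^2_u) is
the person effect and e_ij ~ N(0, sigma^2_e) the within-person day-to-day
error.  The Box-Cox power, coefficients and components are estimated by
maximum likelihood; lambda is profiled over the same 0..1 grid used by
the single-recall fitter, with the Box-Cox Jacobian term included so
likelihoods are comparable across powers.  The fitted within:between
ratio alpha = sigma^2_e / sigma^2_u is the natural "external" ratio to
feed the single-recall model.

The random-intercept Gaussian likelihood is profiled analytically: for a
given theta = sigma^2_u / sigma^2_e the GLS coefficients and the residual
scale have closed forms, leaving a one-dimensional search over theta.
Survey weights enter as person-level frequency-style weights on each
person's likelihood contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from . import boxcox
from ._design import (
    DAY_COL,
    INTAKE_COL,
    PERSON_COL,
    WEIGHT_COL,
    build_design,
    check_full_rank,
    linear_predictor_at_daytype,
    validate_recall_table,
)
from .exceptions import ConfigError, ModelError
from .variance import WITHIN_TO_BETWEEN, VarianceRatio, convert_ratio

__all__ = ["AmountOnlyModel", "fit_amount_only", "extract_ratio"]

_BOUNDARY_THETA = 1e-7


@dataclass
class _PersonBlocks:
    """Per-person sufficient statistics for the random-intercept model."""

    X: np.ndarray          # (N, p) stacked design, sorted by person
    starts: np.ndarray     # first row index of each person
    J: np.ndarray          # (n,) recalls per person
    w: np.ndarray          # (n,) person weights
    XtX: np.ndarray        # (n, p, p) per-person X'X
    Xsum: np.ndarray       # (n, p) per-person column sums
    A: np.ndarray          # (p, p) sum_i w_i XtX_i
    Nw: float              # sum_i w_i J_i


def _person_blocks(X: np.ndarray, person: np.ndarray, w_row: np.ndarray) -> _PersonBlocks:
    # assumes rows already sorted by person
    starts = np.flatnonzero(np.r_[True, person[1:] != person[:-1]])
    J = np.diff(np.r_[starts, person.size]).astype(float)
    w = np.add.reduceat(w_row, starts) / J  # person weight = mean row weight
    if not np.allclose(np.add.reduceat((w_row - np.repeat(w, J.astype(int))) ** 2, starts), 0):
        warnings.warn(
            "survey weights differ across a person's recalls; using the mean",
            UserWarning,
            stacklevel=3,
        )
    outer = X[:, :, None] * X[:, None, :]
    XtX = np.add.reduceat(outer, starts, axis=0)
    Xsum = np.add.reduceat(X, starts, axis=0)
    A = np.einsum("i,ipq->pq", w, XtX)
    return _PersonBlocks(X, starts, J, w, XtX, Xsum, A, float(np.sum(w * J)))


def _profile_theta(blocks: _PersonBlocks, ysum, y2sum, Xy, theta: float):
    """GLS coefficients, ML residual scale and core log-likelihood at theta."""
    c = theta / (1.0 + blocks.J * theta)
    wc = blocks.w * c
    M = blocks.A - np.einsum("i,ip,iq->pq", wc, blocks.Xsum, blocks.Xsum)
    v = np.einsum("i,ip->p", blocks.w, Xy) - np.einsum("i,ip,i->p", wc, blocks.Xsum, ysum)
    beta = np.linalg.solve(M, v)
    S2 = y2sum - 2.0 * Xy @ beta + np.einsum("ipq,p,q->i", blocks.XtX, beta, beta)
    Sr = ysum - blocks.Xsum @ beta
    Q = float(np.sum(blocks.w * (S2 - c * Sr**2)))
    Q = max(Q, 1e-300)
    sigma2_e = Q / blocks.Nw
    ll = -0.5 * (
        blocks.Nw * np.log(2.0 * np.pi * sigma2_e)
        + float(np.sum(blocks.w * np.log1p(blocks.J * theta)))
        + blocks.Nw
    )
    return beta, sigma2_e, ll


def _fit_lambda(blocks: _PersonBlocks, y: np.ndarray):
    """Maximize the profiled likelihood over theta for fixed lambda."""
    ysum = np.add.reduceat(y, blocks.starts)
    y2sum = np.add.reduceat(y**2, blocks.starts)
    Xy = np.add.reduceat(blocks.X * y[:, None], blocks.starts, axis=0)

    def negll(log10_theta):
        return -_profile_theta(blocks, ysum, y2sum, Xy, 10.0**log10_theta)[2]

    opt = minimize_scalar(negll, bounds=(-8.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    theta = 10.0 ** float(opt.x)
    beta, sigma2_e, ll = _profile_theta(blocks, ysum, y2sum, Xy, theta)
    beta0, s0, ll0 = _profile_theta(blocks, ysum, y2sum, Xy, 0.0)
    if ll0 >= ll:
        return beta0, s0, 0.0, ll0
    return beta, sigma2_e, theta, ll


class AmountOnlyModel(BaseEstimator):
    """Mixed-model usual-intake fitter for replicate-recall data.

    Parameters mirror :class:`~usualintake.oneday.OneDayModel` minus the
    external ratio, which this model estimates instead.

    Attributes
    ----------
    lambda_ : float
        Profile-ML Box-Cox power (ties resolve to the smaller grid value).
    coef_ : pandas.Series
        GLS coefficients at the selected power.
    var_between_, var_within_ : float
        ML estimates of sigma^2_u and sigma^2_e.
    total_variance_ : float
        Their sum (the variance of d_ij).
    alpha_ : float
        Estimated within:between ratio sigma^2_e / sigma^2_u; ``inf`` when
        the between-person component hits the zero boundary.
    boundary_ : bool
        True when sigma^2_u was estimated at 0 (a warning is emitted).
    loglik_profile_ : pandas.DataFrame
        Columns ``lambda`` and ``loglik`` (Jacobian-adjusted) over the grid.
    linear_predictors_ : pandas.DataFrame
        Per person: person_id, weight, lp_weekday, lp_weekend.
    """

    def __init__(
        self,
        person_covariates=(),
        temporal_covariates=(),
        grid=None,
        lam=None,
        zero_handling="shift",
    ):
        self.person_covariates = person_covariates
        self.temporal_covariates = temporal_covariates
        self.grid = grid
        self.lam = lam
        self.zero_handling = zero_handling

    # ------------------------------------------------------------------
    def fit(self, table: pd.DataFrame, y=None) -> "AmountOnlyModel":
        pc = tuple(self.person_covariates)
        tc = tuple(self.temporal_covariates)
        df = validate_recall_table(table)
        df = df.sort_values([PERSON_COL, DAY_COL], kind="stable").reset_index(drop=True)

        intake = df[INTAKE_COL].to_numpy(dtype=float)
        intake, keep, n_shift = boxcox.shift_zero_intakes(intake, self.zero_handling)
        df = df[keep].reset_index(drop=True)
        intake = intake[keep]

        person = df[PERSON_COL].to_numpy()
        counts = df.groupby(PERSON_COL, sort=False).size()
        if (counts < 2).all():
            raise ModelError(
                "cannot separate variance components: no person has >= 2 recalls"
            )

        X, names = build_design(df, pc, tc)
        w_row = df[WEIGHT_COL].to_numpy(dtype=float)
        check_full_rank(X * np.sqrt(w_row)[:, None], names)
        blocks = _person_blocks(X, person, w_row)
        w_obs = np.repeat(blocks.w, blocks.J.astype(int))
        sum_wlog = float(np.sum(w_obs * np.log(intake)))

        if self.lam is not None:
            lambdas = np.array([float(self.lam)])
        else:
            grid = self.grid if self.grid is not None else boxcox.LambdaGrid()
            lambdas = grid.values

        loglik = np.full(lambdas.size, -np.inf)
        fits = []
        for i, lam in enumerate(lambdas):
            yt = boxcox.transform(intake, lam)
            beta, sigma2_e, theta, ll_core = _fit_lambda(blocks, yt)
            loglik[i] = ll_core + (lam - 1.0) * sum_wlog
            fits.append((beta, sigma2_e, theta))
        best = int(np.argmax(loglik))  # first max -> smaller lambda on ties
        beta, sigma2_e, theta = fits[best]
        lam = float(lambdas[best])
        sigma2_u = theta * sigma2_e

        boundary = theta <= _BOUNDARY_THETA
        if boundary:
            warnings.warn(
                "between-person variance estimated at the zero boundary; "
                "the within:between ratio is reported as +inf",
                UserWarning,
                stacklevel=2,
            )

        coef = pd.Series(beta, index=names)
        first = df.iloc[blocks.starts]
        self.lambda_ = lam
        self.coef_ = coef
        self.var_between_ = float(sigma2_u)
        self.var_within_ = float(sigma2_e)
        self.total_variance_ = float(sigma2_u + sigma2_e)
        self.alpha_ = float("inf") if boundary else float(sigma2_e / sigma2_u)
        self.boundary_ = bool(boundary)
        self.theta_ = float(theta)
        self.loglik_profile_ = pd.DataFrame({"lambda": lambdas, "loglik": loglik})
        self.n_obs_ = len(df)
        self.n_persons_ = blocks.J.size
        self.n_zero_shifted_ = n_shift
        self.feature_names_ = names
        self.linear_predictors_ = pd.DataFrame(
            {
                PERSON_COL: first[PERSON_COL].to_numpy(),
                WEIGHT_COL: blocks.w,
                "lp_weekday": linear_predictor_at_daytype(first, coef, pc, tc, 0.0),
                "lp_weekend": linear_predictor_at_daytype(first, coef, pc, tc, 1.0),
            }
        )
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "method": "amount_only",
            "lambda": self.lambda_,
            "coefficients": {k: float(v) for k, v in self.coef_.items()},
            "V": self.total_variance_,
            "var_between": self.var_between_,
            "var_within": self.var_within_,
            "ratio_type": WITHIN_TO_BETWEEN,
            "ratio_value": self.alpha_,
            "person_covariates": list(self.person_covariates),
            "temporal_covariates": list(self.temporal_covariates),
            "n_obs": self.n_obs_,
            "n_zero_shifted": self.n_zero_shifted_,
        }

    @classmethod
    def from_dict(cls, params: dict) -> "AmountOnlyModel":
        model = cls(
            person_covariates=tuple(params["person_covariates"]),
            temporal_covariates=tuple(params["temporal_covariates"]),
            lam=params["lambda"],
        )
        model.lambda_ = float(params["lambda"])
        model.coef_ = pd.Series(params["coefficients"])
        model.total_variance_ = float(params["V"])
        model.var_between_ = float(params["var_between"])
        model.var_within_ = float(params["var_within"])
        model.alpha_ = float(params["ratio_value"])
        model.boundary_ = not np.isfinite(model.alpha_)
        model.feature_names_ = list(model.coef_.index)
        model.n_obs_ = int(params.get("n_obs", 0))
        model.n_zero_shifted_ = int(params.get("n_zero_shifted", 0))
        return model

    def attach_table(self, table: pd.DataFrame) -> "AmountOnlyModel":
        """Recompute per-person linear predictors from a recall table."""
        df = validate_recall_table(table)
        df = df.sort_values([PERSON_COL, DAY_COL], kind="stable")
        first = df.drop_duplicates(subset=PERSON_COL, keep="first").reset_index(drop=True)
        weight = df.groupby(PERSON_COL, sort=False)[WEIGHT_COL].mean().to_numpy()
        pc, tc = tuple(self.person_covariates), tuple(self.temporal_covariates)
        self.linear_predictors_ = pd.DataFrame(
            {
                PERSON_COL: first[PERSON_COL].to_numpy(),
                WEIGHT_COL: weight,
                "lp_weekday": linear_predictor_at_daytype(first, self.coef_, pc, tc, 0.0),
                "lp_weekend": linear_predictor_at_daytype(first, self.coef_, pc, tc, 1.0),
            }
        )
        return self


def fit_amount_only(table, **kwargs) -> AmountOnlyModel:
    """Functional wrapper: fit an :class:`AmountOnlyModel` and return it."""
    return AmountOnlyModel(**kwargs).fit(table)


def extract_ratio(fit: AmountOnlyModel, ratio_type: str = WITHIN_TO_BETWEEN) -> VarianceRatio:
    """The fitted variance ratio in the requested convention.

    Raises :class:`ModelError` for a boundary fit (sigma^2_u = 0), where no
    finite within:between ratio exists.
    """
    if getattr(fit, "boundary_", False) or not np.isfinite(fit.alpha_):
        raise ModelError(
            "between-person variance was estimated at the boundary; "
            "no finite variance ratio can be extracted"
        )
    if fit.var_between_ <= 0:
        raise ModelError("variance ratio requires sigma^2_u > 0")
    alpha = VarianceRatio(fit.var_within_ / fit.var_between_, WITHIN_TO_BETWEEN)
    return convert_ratio(alpha, ratio_type)
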