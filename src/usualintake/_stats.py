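"""Survey-weighted summary statistics shared across the package."""

from __future__ import annotations

import numpy as np

from .exceptions import DataError


def weighted_mean(values, weights=None) -> float:
    v = np.asarray(values, dtype=float)
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * v) / np.sum(w))


def weighted_quantile(values, q, weights=None):
    """Weighted empirical quantile(s) with linear interpolation.

    Uses midpoint plotting positions on the weighted empirical CDF,
    ``p_i = (C_i - w_i/2) / W`` with ``C_i`` the cumulative weight through
    the i-th order statistic, and interpolates linearly between order
    statistics (clamping at the extremes).  Reduces to the standard
    midpoint rule for equal weights; invariant to rescaling all weights
    by a positive constant.

    Parameters
    ----------
    values : array-like
    q : float or array-like
        Quantile level(s) in [0, 1].
    weights : array-like, optional
        Nonnegative weights; equal weights if omitted.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("weighted_quantile: empty input")
    scalar = np.ndim(q) == 0
    qa = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((qa < 0) | (qa > 1)):
        raise DataError("quantile levels must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != v.shape:
            raise DataError("weights must match values in shape")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise DataError("weights must be finite and nonnegative")
    keep = w > 0
    v, w = v[keep], w[keep]
    if v.size == 0:
        raise DataError("weighted_quantile: all weights are zero")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    out = np.interp(qa, positions, v)
    return float(out[0]) if scalar else out


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w) ** 2 / np.sum(w**2))
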