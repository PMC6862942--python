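"""Variance-ratio conventions and the external-ratio variance split.

With only one 24-h recall per person the total residual variance ``V`` of
the transformed intakes cannot be separated into its between-person
(``sigma^2_u``, variation of usual intakes among individuals) and
within-person (``sigma^2_e``, day-to-day fluctuation) components.  An
external ratio taken from a study with replicate recalls supplies the
split.  Three conventions for the ratio circulate in the literature:

========================  =======================================  =============
ratio_type                definition                               symbol
========================  =======================================  =============
``within_to_between``     sigma^2_e / sigma^2_u                    alpha > 0
``within_to_total``       sigma^2_e / V                            beta in (0,1)
``between_to_total``      sigma^2_u / V                            gamma in (0,1)
========================  =======================================  =============

The split formulas are::

    alpha: between = V / (1 + alpha),  within = V * alpha / (1 + alpha)
    beta:  between = V * (1 - beta),   within = V * beta
    gamma: between = V * gamma,        within = V * (1 - gamma)

and always conserve ``between + within = V``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigError

WITHIN_TO_BETWEEN = "within_to_between"
WITHIN_TO_TOTAL = "within_to_total"
BETWEEN_TO_TOTAL = "between_to_total"

RATIO_TYPES = (WITHIN_TO_BETWEEN, WITHIN_TO_TOTAL, BETWEEN_TO_TOTAL)

_ALIASES = {
    "alpha": WITHIN_TO_BETWEEN,
    "beta": WITHIN_TO_TOTAL,
    "gamma": BETWEEN_TO_TOTAL,
    WITHIN_TO_BETWEEN: WITHIN_TO_BETWEEN,
    WITHIN_TO_TOTAL: WITHIN_TO_TOTAL,
    BETWEEN_TO_TOTAL: BETWEEN_TO_TOTAL,
}


def _canonical_type(ratio_type: str) -> str:
    try:
        return _ALIASES[str(ratio_type).lower()]
    except KeyError:
        raise ConfigError(
            f"unknown ratio_type {ratio_type!r}; expected one of {RATIO_TYPES} "
            "(aliases: alpha, beta, gamma)"
        ) from None


@dataclass(frozen=True)
class VarianceRatio:
    """A scalar variance ratio plus the convention it uses.

    Parameters
    ----------
    value : float
        The ratio itself; > 0 for ``within_to_between``, strictly inside
        (0, 1) for the two total-denominator conventions.
    ratio_type : str
        One of ``within_to_between`` (alpha), ``within_to_total`` (beta),
        ``between_to_total`` (gamma); greek aliases accepted.
    """

    value: float
    ratio_type: str = WITHIN_TO_BETWEEN

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio_type", _canonical_type(self.ratio_type))
        v = float(self.value)
        object.__setattr__(self, "value", v)
        if self.ratio_type == WITHIN_TO_BETWEEN:
            if not v > 0:
                raise ConfigError("within:between ratio (alpha) must be > 0")
        elif not 0 < v < 1:
            raise ConfigError(
                f"{self.ratio_type} ratio must lie strictly in (0, 1); got {v}"
            )

    @property
    def alpha(self) -> float:
        """The ratio expressed in the within:between convention."""
        if self.ratio_type == WITHIN_TO_BETWEEN:
            return self.value
        if self.ratio_type == WITHIN_TO_TOTAL:
            return self.value / (1.0 - self.value)
        return (1.0 - self.value) / self.value

    def to(self, target_type: str) -> "VarianceRatio":
        return convert_ratio(self, target_type)


def convert_ratio(ratio: VarianceRatio, target_type: str) -> VarianceRatio:
    """Convert a :class:`VarianceRatio` between the three conventions.

    Conversions go through alpha: ``alpha = beta/(1-beta) = (1-gamma)/gamma``,
    ``beta = alpha/(1+alpha)``, ``gamma = 1/(1+alpha)``; round-trips are
    exact up to floating point.
    """
    target = _canonical_type(target_type)
    a = ratio.alpha
    if target == WITHIN_TO_BETWEEN:
        return VarianceRatio(a, target)
    if target == WITHIN_TO_TOTAL:
        return VarianceRatio(a / (1.0 + a), target)
    return VarianceRatio(1.0 / (1.0 + a), target)


def split_variance(total_variance: float, ratio: VarianceRatio) -> tuple[float, float]:
    """Split total residual variance into (between-person, within-person).

    For example, total variance 20 with a within:between ratio of 2 gives
    between = 20/(1+2) = 6.67 and within = 20*2/(1+2) = 13.3.

    Parameters
    ----------
    total_variance : float
        Variance of the transformed-scale residual d; must be >= 0.
    ratio : VarianceRatio or float
        A float is interpreted as a within:between (alpha) ratio.

    Returns
    -------
    (var_between, var_within) : tuple of float
        Components summing to ``total_variance``.
    """
    if isinstance(ratio, (int, float)):
        ratio = VarianceRatio(ratio, WITHIN_TO_BETWEEN)
    V = float(total_variance)
    if not V >= 0:
        raise ConfigError(f"total variance must be >= 0, got {V}")
    if ratio.ratio_type == WITHIN_TO_BETWEEN:
        between = V / (1.0 + ratio.value)
        within = V * ratio.value / (1.0 + ratio.value)
    elif ratio.ratio_type == WITHIN_TO_TOTAL:
        between = V * (1.0 - ratio.value)
        within = V * ratio.value
    else:  # between_to_total
        between = V * ratio.value
        within = V * (1.0 - ratio.value)
    return between, within
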