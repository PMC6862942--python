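"""Synthetic recall data with known truth.

Generates person-day recall tables from the same data-generating process
both fitters assume: on the Box-Cox scale, a linear predictor in person
covariates (continuous age, a 3-level group playing the role of
race/ethnicity indicators) and a weekend indicator, plus a normal person
effect and normal day-to-day error, back-transformed to the original
scale.  Because the generating parameters are known, each person's true
usual intake has a closed form (day-type-weighted quadrature over the
within-person error with the generator's own parameters), so parameter
and distribution recovery can be tested end to end without any external
data.

Generated intakes whose back-transform argument has no positive preimage
are clipped to zero and counted against the < 5% budget that defines a
nearly-daily consumed component; a specification implying 5% or more
zeros is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from . import boxcox
from ._design import DAY_COL, INTAKE_COL, PERSON_COL, WEIGHT_COL
from .distrib import DayTypeWeights, _gh_nodes
from .exceptions import ConfigError, DataError

__all__ = ["GeneratorSpec", "generate", "make_replicate_weights"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic recall generator.

    Defaults describe a vitamin-A-like nutrient in a single-sex adult
    population: Box-Cox power 0.25, transformed-scale intercept 16 (about
    625 ug/d at the median), between-person variance 0.5 and within-person
    variance 1.0 (within:between ratio 2), age 19-80 with a small positive
    transformed-scale slope, three population groups, weekend probability
    3/7 and mildly variable survey weights.
    """

    n_persons: int = 5000
    days_per_person: int = 2
    lam: float = 0.25
    beta0: float = 16.0
    beta_age: float = 0.01
    beta_group: tuple[float, ...] = (0.0, 0.3, -0.2)
    beta_weekend: float = 0.2
    sigma2_u: float = 0.5
    sigma2_e: float = 1.0
    age_range: tuple[float, float] = (19.0, 80.0)
    group_proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    p_weekend: float = 3.0 / 7.0
    weight_scheme: str = "gamma"  # or "equal"
    weight_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.days_per_person < 1:
            raise ConfigError("n_persons and days_per_person must be >= 1")
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ConfigError("variance components must be nonnegative")
        if not 0 <= self.p_weekend <= 1:
            raise ConfigError("p_weekend must lie in [0, 1]")
        if len(self.beta_group) != len(self.group_proportions):
            raise ConfigError("beta_group and group_proportions lengths differ")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ConfigError("group proportions must sum to 1")
        if self.weight_scheme not in ("gamma", "equal"):
            raise ConfigError("weight_scheme must be 'gamma' or 'equal'")

    #: column names of the person covariates the generator emits
    @property
    def person_covariates(self) -> tuple[str, ...]:
        return ("age",) + tuple(f"group_{g}" for g in range(2, len(self.beta_group) + 1))

    @property
    def temporal_covariates(self) -> tuple[str, ...]:
        return ("weekend",)


def _person_frame(spec: GeneratorSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_persons
    age = rng.uniform(*spec.age_range, size=n)
    group = rng.choice(len(spec.beta_group), size=n, p=spec.group_proportions)
    if spec.weight_scheme == "gamma":
        weight = rng.gamma(spec.weight_shape, 1.0 / spec.weight_shape, size=n)
    else:
        weight = np.ones(n)
    persons = pd.DataFrame({PERSON_COL: np.arange(1, n + 1), "age": age, WEIGHT_COL: weight})
    for g in range(2, len(spec.beta_group) + 1):
        persons[f"group_{g}"] = (group == g - 1).astype(float)
    lp = spec.beta0 + spec.beta_age * age + np.asarray(spec.beta_group)[group]
    persons["_lp_person"] = lp
    return persons


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (recall table, truth table); deterministic given the seed.

    The truth table has one row per person with the drawn person effect
    ``u``, both day-type linear predictors and the closed-form true usual
    intake (41-node quadrature over the within-person error, day types
    weighted 4/7 weekday and 3/7 weekend).
    """
    rng = np.random.default_rng(spec.seed)
    persons = _person_frame(spec, rng)
    n, J = spec.n_persons, spec.days_per_person
    u = rng.normal(0.0, np.sqrt(spec.sigma2_u), size=n)

    rows = persons.loc[persons.index.repeat(J)].reset_index(drop=True)
    rows[DAY_COL] = np.tile(np.arange(1, J + 1), n)
    weekend = rng.random(n * J) < spec.p_weekend
    e = rng.normal(0.0, np.sqrt(spec.sigma2_e), size=n * J)
    y = (
        rows["_lp_person"].to_numpy()
        + spec.beta_weekend * weekend
        + np.repeat(u, J)
        + e
    )
    intake = boxcox.inverse_transform(y, spec.lam)
    n_zero = int(np.count_nonzero(intake == 0))
    if n_zero / intake.size >= 0.05:
        raise DataError(
            f"specification implies {100 * n_zero / intake.size:.1f}% zero intakes; "
            "a nearly-daily consumed component requires < 5%"
        )
    rows[INTAKE_COL] = intake
    rows["weekend"] = weekend.astype(float)
    table = rows.drop(columns="_lp_person")
    cols = [PERSON_COL, DAY_COL, INTAKE_COL, WEIGHT_COL, "age",
            *[c for c in table.columns if c.startswith("group_")], "weekend"]
    table = table[cols]

    daytype = DayTypeWeights()
    z, pz = _gh_nodes(41)
    sigma_e = float(np.sqrt(spec.sigma2_e))
    lp_wd = persons["_lp_person"].to_numpy() + u
    lp_we = lp_wd + spec.beta_weekend
    e_wd = boxcox.inverse_transform(lp_wd[:, None] + sigma_e * z, spec.lam) @ pz
    e_we = boxcox.inverse_transform(lp_we[:, None] + sigma_e * z, spec.lam) @ pz
    truth = pd.DataFrame(
        {
            PERSON_COL: persons[PERSON_COL].to_numpy(),
            WEIGHT_COL: persons[WEIGHT_COL].to_numpy(),
            "u": u,
            "lp_weekday": lp_wd - u,
            "lp_weekend": lp_we - u,
            "usual_intake": daytype.weekday * e_wd + daytype.weekend * e_we,
        }
    )
    return table, truth


def make_replicate_weights(
    table: pd.DataFrame,
    n_sets: int = 32,
    seed: int = 0,
    fay: float = 0.0,
    prefix: str = "repwt_",
) -> pd.DataFrame:
    """Append classical (or Fay-adjusted) BRR half-sample replicate weights.

    Persons are paired into pseudo-strata of two (sorted by weight so pair
    members are comparable, with seeded tie-breaking); a Hadamard design
    of order ``n_sets`` assigns each stratum's first or second member to
    the half-sample.  The selected member's weight is multiplied by
    ``2 - F`` and the other's by ``F`` (classical BRR at F = 0).

    ``n_sets`` must be a power of two >= 4 (the Hadamard orders available
    here) and the number of persons must be even.
    """
    if n_sets < 4 or (n_sets & (n_sets - 1)) != 0:
        raise ConfigError("n_sets must be a power of two >= 4")
    if not 0 <= fay < 1:
        raise ConfigError("Fay coefficient must lie in [0, 1)")
    persons = (
        table.groupby(PERSON_COL, sort=False)[WEIGHT_COL].first().reset_index()
    )
    n = len(persons)
    if n % 2 != 0:
        raise DataError("BRR pairing needs an even number of persons")
    rng = np.random.default_rng(seed)
    persons = persons.assign(_jitter=rng.random(n)).sort_values(
        [WEIGHT_COL, "_jitter"], kind="stable"
    )
    pid = persons[PERSON_COL].to_numpy()
    stratum = np.repeat(np.arange(n // 2), 2)
    member = np.tile([0, 1], n // 2)

    H = scipy.linalg.hadamard(n_sets)
    out = table.copy()
    base_w = out[WEIGHT_COL].to_numpy(dtype=float)
    person_pos = pd.Series(np.arange(n), index=pid)
    row_pos = person_pos.loc[out[PERSON_COL]].to_numpy()
    for r in range(n_sets):
        sign = H[r, stratum % n_sets]
        selected = (sign == 1) == (member == 0)
        factor = np.where(selected, 2.0 - fay, fay)
        out[f"{prefix}{r + 1}"] = base_w * factor[row_pos]
    return out
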