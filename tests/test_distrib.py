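import numpy as np
import pandas as pd
import pytest

from usualintake.amount_only import fit_amount_only, extract_ratio
from usualintake.distrib import (
    DayTypeWeights,
    estimate_distribution,
    prevalence_below,
    usual_intake_of_person,
)
from usualintake.exceptions import ConfigError, DataError
from usualintake.oneday import OneDayModel, fit_oneday
from usualintake._stats import weighted_quantile
from usualintake.synthetic import GeneratorSpec, generate


def _toy_fit(lam, s2u, s2e, lp, n=400, weights=None):
    """A minimal fitted-model stand-in with constant linear predictors."""
    model = OneDayModel.from_dict(
        {
            "method": "oneday",
            "lambda": lam,
            "coefficients": {"const": lp},
            "V": s2u + s2e,
            "var_between": s2u,
            "var_within": s2e,
            "ratio_type": "within_to_between",
            "ratio_value": s2e / s2u if (s2u > 0 and s2e > 0) else 1.0,
            "person_covariates": [],
            "temporal_covariates": [],
        }
    )
    model.linear_predictors_ = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "weight": weights if weights is not None else np.ones(n),
            "lp_weekday": np.full(n, lp),
            "lp_weekend": np.full(n, lp),
        }
    )
    return model


def test_linear_transform_integrates_within_person_error_exactly():
    # g^-1(y; 1) = y + 1 is linear, so the day-to-day error averages out
    assert usual_intake_of_person(9.0, 9.0, 0.0, 1.0, 4.0) == pytest.approx(10.0)


def test_log_case_matches_lognormal_mean():
    got = usual_intake_of_person(0.0, 0.0, 0.0, 0.0, 1.0)
    assert got == pytest.approx(np.exp(0.5), rel=1e-6)


def test_quadrature_matches_monte_carlo():
    rng = np.random.default_rng(99)
    e = rng.normal(0.0, np.sqrt(0.6), size=200_000)
    mc = np.mean(np.power(0.4 * (3.0 + e) + 1.0, 1.0 / 0.4))
    got = usual_intake_of_person(3.0, 3.0, 0.0, 0.4, 0.6, nodes=9)
    assert got == pytest.approx(mc, rel=5e-3)


def test_node_count_refines_but_does_not_move_the_answer():
    a = usual_intake_of_person(2.5, 2.7, 0.3, 0.25, 0.8, nodes=9)
    b = usual_intake_of_person(2.5, 2.7, 0.3, 0.25, 0.8, nodes=41)
    assert a == pytest.approx(b, rel=1e-4)
    with pytest.raises(ConfigError):
        usual_intake_of_person(1.0, 1.0, 0.0, 0.5, 1.0, nodes=4)


def test_symmetric_population_centres_on_back_transformed_predictor():
    fit = _toy_fit(lam=1.0, s2u=1.0, s2e=0.0, lp=9.0)
    dist = estimate_distribution(fit, M=200, seed=3)
    assert dist.percentile(50) == pytest.approx(10.0, rel=0.02)
    below = np.sum(dist.weights[dist.pseudo_values < 10.0]) / np.sum(dist.weights)
    assert below == pytest.approx(0.5, abs=0.02)


def test_same_seed_is_bit_identical_and_percentiles_monotone():
    fit = _toy_fit(lam=0.25, s2u=0.5, s2e=1.0, lp=3.0)
    a = estimate_distribution(fit, M=50, seed=11, cutoff=10.0)
    b = estimate_distribution(fit, M=50, seed=11, cutoff=10.0)
    np.testing.assert_array_equal(a.pseudo_values, b.pseudo_values)
    assert a.mean == b.mean and a.prevalence == b.prevalence
    assert np.all(np.diff(a.percentile_values) >= 0)
    c = estimate_distribution(fit, M=50, seed=12)
    assert c.mean != a.mean


def test_more_pseudo_persons_refine_but_do_not_shift():
    fit = _toy_fit(lam=0.25, s2u=0.5, s2e=1.0, lp=3.0, n=2000)
    m50 = estimate_distribution(fit, M=50, seed=4)
    m500 = estimate_distribution(fit, M=500, seed=4)
    assert m50.mean == pytest.approx(m500.mean, rel=5e-3)


def test_recovers_true_usual_intake_quantiles(default_two_day):
    """End to end on synthetic truth: single-recall fit + distribution stage
    reproduce the generator's closed-form usual-intake quartiles within 2%."""
    spec, table, truth = default_two_day
    day1 = table[table["day"] == 1]
    fit = fit_oneday(
        day1,
        ratio=spec.sigma2_e / spec.sigma2_u,
        person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
    )
    dist = estimate_distribution(fit, M=100, seed=21)
    for q in (0.25, 0.50, 0.75):
        true_q = weighted_quantile(truth["usual_intake"], q, truth["weight"])
        assert dist.percentile(100 * q) == pytest.approx(true_q, rel=0.02)


def test_either_fitter_feeds_the_distribution_stage(vitaminE_two_day):
    spec, table, truth = vitaminE_two_day
    am = fit_amount_only(
        table,
        person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
    )
    dist = estimate_distribution(am, M=50, seed=2)
    true_med = weighted_quantile(truth["usual_intake"], 0.5, truth["weight"])
    assert dist.percentile(50) == pytest.approx(true_med, rel=0.05)


def test_prevalence_edge_cases():
    fit = _toy_fit(lam=0.25, s2u=0.5, s2e=1.0, lp=3.0)
    dist = estimate_distribution(fit, M=50, seed=8)
    assert prevalence_below(dist, dist.pseudo_values.min() * 0.5) == 0.0
    assert prevalence_below(dist, dist.pseudo_values.max() * 2.0) == 1.0
    med = dist.percentile(50)
    assert prevalence_below(dist, med) == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ConfigError):
        prevalence_below(dist, -1.0)


def test_clipping_is_counted_and_values_stay_nonnegative():
    fit = _toy_fit(lam=0.5, s2u=1.0, s2e=4.0, lp=-1.0)
    dist = estimate_distribution(fit, M=50, seed=5)
    assert dist.clipped_fraction > 0
    assert np.all(dist.pseudo_values >= 0)


def test_negative_between_variance_rejected():
    fit = _toy_fit(lam=0.25, s2u=0.5, s2e=1.0, lp=3.0)
    fit.var_between_ = -0.1
    with pytest.raises(DataError):
        estimate_distribution(fit, M=10, seed=0)


def test_daytype_weights_validate():
    with pytest.raises(ConfigError):
        DayTypeWeights(0.9, 0.3)
    dt = DayTypeWeights()
    assert dt.weekday + dt.weekend == pytest.approx(1.0)
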