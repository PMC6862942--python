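import numpy as np
import pandas as pd
import pytest

from usualintake.amount_only import (
    AmountOnlyModel,
    _person_blocks,
    _profile_theta,
    extract_ratio,
    fit_amount_only,
)
from usualintake.boxcox import inverse_transform
from usualintake.exceptions import ModelError
from usualintake.synthetic import GeneratorSpec, generate


def test_parameter_recovery_pooled_over_seeds():
    """ML recovers the generating power and variance ratio (mean of 3 seeds)."""
    lams, alphas, slopes = [], [], []
    for seed in (42, 43, 44):
        spec = GeneratorSpec(n_persons=2000, beta0=3.0, seed=seed)
        table, _ = generate(spec)
        fit = fit_amount_only(
            table,
            person_covariates=spec.person_covariates,
            temporal_covariates=spec.temporal_covariates,
        )
        lams.append(fit.lambda_)
        alphas.append(fit.alpha_)
        slopes.append(fit.coef_["age"])
    assert abs(np.mean(lams) - 0.25) <= 0.05
    assert np.mean(alphas) == pytest.approx(2.0, rel=0.15)
    assert np.mean(slopes) == pytest.approx(0.01, abs=0.01)


def test_identical_recalls_imply_zero_within_person_variance():
    rng = np.random.default_rng(5)
    n = 200
    y = 4.0 + rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "person_id": np.repeat(np.arange(n), 2),
            "day": np.tile([1, 2], n),
            "intake": np.repeat(inverse_transform(y, 0.5), 2),
        }
    )
    fit = fit_amount_only(df, lam=0.5)
    # the likelihood is unbounded in this degenerate case; the within-person
    # component collapses to zero while the person effect absorbs everything
    assert fit.var_within_ <= 1e-4
    assert fit.var_between_ > 0.1


def test_equal_person_means_hit_between_boundary():
    n = 300
    delta = np.linspace(0.5, 1.5, n)
    df = pd.DataFrame(
        {
            "person_id": np.repeat(np.arange(n), 2),
            "day": np.tile([1, 2], n),
            "intake": np.column_stack([5.0 + delta, 5.0 - delta]).ravel(),
        }
    )
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_amount_only(df, lam=1.0)
    assert fit.boundary_
    assert fit.alpha_ == np.inf
    with pytest.raises(ModelError, match="boundary"):
        extract_ratio(fit)


@pytest.mark.parametrize(
    "s2u,s2e,expected",
    [
        (5.220, 10.450, 2.002),  # vitamin-A-like components
        (3.044, 3.262, 1.072),   # magnesium-like components
        (1.0, 1.0, 1.0),
    ],
)
def test_extract_ratio_from_components(s2u, s2e, expected):
    fit = AmountOnlyModel.from_dict(
        {
            "method": "amount_only",
            "lambda": 0.25,
            "coefficients": {"const": 0.0},
            "V": s2u + s2e,
            "var_between": s2u,
            "var_within": s2e,
            "ratio_type": "within_to_between",
            "ratio_value": s2e / s2u,
            "person_covariates": [],
            "temporal_covariates": [],
        }
    )
    assert round(extract_ratio(fit).value, 3) == expected
    gamma = extract_ratio(fit, "between_to_total")
    assert gamma.value == pytest.approx(s2u / (s2u + s2e))


def test_single_recall_data_cannot_separate_components():
    df = pd.DataFrame({"person_id": range(50), "intake": np.arange(50) + 1.0})
    with pytest.raises(ModelError, match="cannot separate"):
        fit_amount_only(df)


def test_ml_within_variance_matches_moment_estimator(vitaminE_two_day):
    """Balanced 2-day design: ML sigma2_e agrees with half the mean squared
    within-person difference of transformed residuals."""
    spec, table, _ = vitaminE_two_day
    eq = table.copy()
    eq["weight"] = 1.0
    fit = fit_amount_only(
        eq,
        person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
        lam=0.25,
    )
    from usualintake.boxcox import transform
    from usualintake._design import build_design

    df = eq.sort_values(["person_id", "day"]).reset_index(drop=True)
    X, _ = build_design(df, spec.person_covariates, spec.temporal_covariates)
    resid = transform(df["intake"].to_numpy(), 0.25) - X @ fit.coef_.to_numpy()
    r = resid.reshape(-1, 2)
    moment = 0.5 * np.mean((r[:, 0] - r[:, 1]) ** 2)
    assert fit.var_within_ == pytest.approx(moment, rel=0.05)


def test_profile_likelihood_peaks_at_selected_lambda(vitaminE_two_day):
    spec, table, _ = vitaminE_two_day
    fit = fit_amount_only(
        table,
        person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
    )
    prof = fit.loglik_profile_
    assert prof.loc[prof["loglik"].idxmax(), "lambda"] == fit.lambda_


def test_gls_at_theta_zero_degenerates_to_weighted_least_squares(rng):
    """The mixed model's internal GLS with no person effect is plain WLS."""
    import statsmodels.api as sm

    n = 120
    person = np.arange(n)  # single day per person
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = 1.0 + 0.5 * X[:, 1] + rng.normal(size=n)
    w = rng.gamma(4.0, 0.25, size=n)
    blocks = _person_blocks(X, person, w)
    ysum = y.copy()
    beta, sigma2, _ = _profile_theta(blocks, ysum, y**2, X * y[:, None], 0.0)
    wls = sm.WLS(y, X, weights=w).fit()
    np.testing.assert_allclose(beta, wls.params, rtol=1e-10)
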