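import numpy as np
import pandas as pd
import pytest

from usualintake.exceptions import ConfigError, ModelError
from usualintake.oneday import OneDayModel, fit_oneday
from usualintake.synthetic import GeneratorSpec, generate
from usualintake.variance import VarianceRatio, convert_ratio


def test_total_variance_and_split_on_known_process():
    """At the generating power, V ~= sigma2_u + sigma2_e and the external
    ratio splits it exactly in the supplied proportion."""
    spec = GeneratorSpec(
        n_persons=5000, days_per_person=1, lam=0.3, beta0=3.0,
        beta_age=0.0, beta_group=(0.0,), group_proportions=(1.0,),
        beta_weekend=0.0, seed=42,
    )
    table, _ = generate(spec)
    fit = fit_oneday(table, ratio=2.0, lam=0.3)
    assert fit.total_variance_ == pytest.approx(1.5, rel=0.10)
    assert fit.var_within_ / fit.var_between_ == pytest.approx(2.0, rel=1e-12)
    assert fit.var_between_ + fit.var_within_ == pytest.approx(
        fit.total_variance_, abs=1e-9
    )


def test_lambda_one_intercept_is_shifted_mean():
    df = pd.DataFrame(
        {"person_id": range(1, 9), "intake": [2.0, 3, 5, 7, 11, 13, 17, 19]}
    )
    fit = fit_oneday(df, ratio=1.0, lam=1.0)
    assert fit.coef_["const"] == pytest.approx(np.mean(df["intake"]) - 1.0)


def test_duplication_with_half_weight_leaves_fit_unchanged(default_one_day):
    spec, day1, _ = default_one_day
    doubled = pd.concat(
        [day1, day1.assign(person_id=day1["person_id"] + 10_000_000)],
        ignore_index=True,
    )
    doubled["weight"] = doubled["weight"] / 2.0
    kw = dict(ratio=2.0, person_covariates=("age",), temporal_covariates=("weekend",))
    a = fit_oneday(day1, **kw)
    b = fit_oneday(doubled, **kw)
    assert b.lambda_ == a.lambda_
    pd.testing.assert_series_equal(a.coef_, b.coef_, rtol=1e-9)
    # V differs only through the (n_eff - p) correction, an O(p/n) effect
    assert b.total_variance_ == pytest.approx(a.total_variance_, rel=5e-3)


def test_collinear_covariates_named(default_one_day):
    _, day1, _ = default_one_day
    df = day1.assign(age_twin=day1["age"] * 2.0)
    with pytest.raises(ModelError, match="age_twin|age"):
        fit_oneday(df, ratio=2.0, person_covariates=("age", "age_twin"))


def test_too_few_persons_rejected():
    df = pd.DataFrame({"person_id": [1, 2], "intake": [1.0, 2.0], "age": [30, 40.0]})
    with pytest.raises(ModelError, match="at least"):
        fit_oneday(df, ratio=1.0, person_covariates=("age",))


def test_repeated_recalls_use_first_day_with_warning(default_two_day):
    spec, table, _ = default_two_day
    day1 = table[table["day"] == 1].reset_index(drop=True)
    kw = dict(ratio=2.0, person_covariates=spec.person_covariates,
              temporal_covariates=spec.temporal_covariates)
    with pytest.warns(UserWarning, match="first recall"):
        both = fit_oneday(table, **kw)
    only = fit_oneday(day1, **kw)
    assert both.lambda_ == only.lambda_
    pd.testing.assert_series_equal(both.coef_, only.coef_)


def test_missing_ratio_is_config_error(default_one_day):
    _, day1, _ = default_one_day
    with pytest.raises(ConfigError, match="ratio"):
        OneDayModel().fit(day1)


def test_equivalent_ratio_conventions_give_identical_split(default_one_day):
    _, day1, _ = default_one_day
    alpha = VarianceRatio(2.0)
    a = fit_oneday(day1, ratio=alpha, lam=0.25)
    b = fit_oneday(day1, ratio=convert_ratio(alpha, "within_to_total"), lam=0.25)
    assert (a.var_between_, a.var_within_) == pytest.approx(
        (b.var_between_, b.var_within_), rel=1e-12
    )


def test_parameter_file_round_trip(default_one_day):
    spec, day1, _ = default_one_day
    fit = fit_oneday(
        day1, ratio=1.8, person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
    )
    reloaded = OneDayModel.from_dict(fit.to_dict()).attach_table(day1)
    assert reloaded.lambda_ == fit.lambda_
    assert reloaded.total_variance_ == pytest.approx(fit.total_variance_)
    pd.testing.assert_frame_equal(
        reloaded.linear_predictors_, fit.linear_predictors_, rtol=1e-12
    )


def test_linear_predictors_cover_both_day_types(default_one_day):
    spec, day1, _ = default_one_day
    fit = fit_oneday(
        day1, ratio=2.0, person_covariates=spec.person_covariates,
        temporal_covariates=spec.temporal_covariates,
    )
    lp = fit.linear_predictors_
    assert len(lp) == day1["person_id"].nunique()
    # weekend shift applies uniformly: difference equals the weekend coefficient
    np.testing.assert_allclose(
        lp["lp_weekend"] - lp["lp_weekday"], fit.coef_["weekend"], rtol=1e-12
    )
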