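"""The log1p regression: fitting, diagnostics, back-transform, prediction."""

import numpy as np
import pandas as pd
import pytest

from eurdtool.registry import RegistryError
from eurdtool.screening import SurveyAggregate, aggregate_survey
from eurdtool.model import (
    ModelFit,
    back_transform,
    breusch_pagan,
    breusch_pagan_arrays,
    cases_for_equivalent_reduction,
    fit_log1p_model,
    predict_cycle,
    round_half_up,
)
from eurdtool.synthetic import GeneratorConfig, generate_features, generate_survey


def _design_frame(rng, n, names):
    frame = pd.DataFrame({"substance_id": [f"S{i:03d}" for i in range(n)]})
    for name in names:
        frame[name] = rng.lognormal(1.0, 0.8, size=n)
    return frame


def _aggregates_from_y(y):
    return [SurveyAggregate(f"S{i:03d}", float(v), 1) for i, v in enumerate(y)]


class TestFit:
    def test_noiseless_data_recovered_exactly(self, rng):
        frame = _design_frame(rng, 30, ["x1"])
        y = np.expm1(0.5 + 0.4 * np.log1p(frame["x1"].to_numpy()))
        fit = fit_log1p_model(_aggregates_from_y(y), frame, ["x1"])
        assert fit.intercept_log_scale.estimate == pytest.approx(0.5, abs=1e-10)
        assert fit.coefficients_log_scale["x1"].estimate == pytest.approx(0.4, abs=1e-10)
        assert fit.adjusted_r_squared == pytest.approx(1.0, abs=1e-10)

    def test_against_normal_equations_oracle(self, rng):
        frame = _design_frame(rng, 10, ["x1", "x2"])
        y = np.expm1(
            0.3 + 0.5 * np.log1p(frame["x1"]) - 0.2 * np.log1p(frame["x2"])
            + rng.normal(0, 0.1, 10)
        )
        fit = fit_log1p_model(_aggregates_from_y(y), frame, ["x1", "x2"])

        X = np.column_stack(
            [np.ones(10), np.log1p(frame["x1"]), np.log1p(frame["x2"])]
        )
        beta = np.linalg.inv(X.T @ X) @ X.T @ np.log1p(y)
        assert fit.intercept_log_scale.estimate == pytest.approx(beta[0], abs=1e-10)
        assert fit.coefficients_log_scale["x1"].estimate == pytest.approx(beta[1], abs=1e-10)
        assert fit.coefficients_log_scale["x2"].estimate == pytest.approx(beta[2], abs=1e-10)
        # classical standard errors from the same normal equations
        resid = np.log1p(y) - X @ beta
        sigma2 = resid @ resid / (10 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert fit.coefficients_log_scale["x1"].std_error == pytest.approx(se[1], abs=1e-10)

    def test_row_permutation_leaves_outputs_unchanged(self, rng):
        frame = _design_frame(rng, 25, ["x1", "x2"])
        y = rng.lognormal(1.5, 0.3, 25)
        fit_a = fit_log1p_model(_aggregates_from_y(y), frame, ["x1", "x2"])
        perm = rng.permutation(25)
        fit_b = fit_log1p_model(
            [_aggregates_from_y(y)[i] for i in perm], frame, ["x1", "x2"]
        )
        for v in ("x1", "x2"):
            assert fit_b.coefficients_log_scale[v].estimate == pytest.approx(
                fit_a.coefficients_log_scale[v].estimate, abs=1e-10)
        assert fit_b.adjusted_r_squared == pytest.approx(
            fit_a.adjusted_r_squared, abs=1e-10)
        assert fit_b.bp_statistic == pytest.approx(fit_a.bp_statistic, abs=1e-8)

    def test_adjusted_r2_below_unadjusted_and_ci_brackets(self, fitted_model):
        assert fitted_model.adjusted_r_squared <= fitted_model.r_squared
        for coef in fitted_model.coefficients_log_scale.values():
            assert coef.ci_low <= coef.estimate <= coef.ci_high
        assert len(fitted_model.residuals) == fitted_model.n_obs

    def test_rank_deficient_design_raises(self, rng):
        frame = _design_frame(rng, 20, ["x1"])
        frame["x2"] = frame["x1"]
        y = rng.lognormal(1.0, 0.2, 20)
        with pytest.raises(RegistryError, match="rank-deficient|aliased"):
            fit_log1p_model(_aggregates_from_y(y), frame, ["x1", "x2"])

    def test_too_few_observations_raises(self, rng):
        frame = _design_frame(rng, 3, ["x1", "x2"])
        y = [2.0, 3.0, 4.0]
        with pytest.raises(RegistryError, match="observations"):
            fit_log1p_model(_aggregates_from_y(y), frame, ["x1", "x2"])


class TestBreuschPagan:
    def test_constant_squared_residuals_give_zero_statistic(self):
        resid = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        exog = np.column_stack([np.ones(6), np.arange(6.0)])
        stat, p = breusch_pagan_arrays(resid, exog)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["classic", "studentized"])
    def test_against_auxiliary_regression_oracle(self, rng, variant):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 0.5, -0.3]) + rng.normal(size=n) * (
            1 + 0.8 * np.abs(X[:, 1])
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta

        stat, p = breusch_pagan_arrays(resid, X, variant=variant)

        # independent auxiliary-regression computation
        e2 = resid**2
        g, *_ = np.linalg.lstsq(X, e2, rcond=None)
        fitted = X @ g
        ess = np.sum((fitted - e2.mean()) ** 2)
        tss = np.sum((e2 - e2.mean()) ** 2)
        if variant == "studentized":
            expected = n * ess / tss                       # n * R^2 of aux fit
        else:
            sigma2 = e2.mean()
            expected = ess / (2 * sigma2**2)               # ESS/2 on e^2/sigma^2
        assert stat == pytest.approx(expected, rel=1e-8)
        from scipy import stats as sps
        assert p == pytest.approx(sps.chi2.sf(expected, 2), rel=1e-8)

    def test_power_against_planted_heteroscedasticity(self):
        n, reps, alpha = 200, 500, 0.05
        rng = np.random.default_rng(77)
        X = np.column_stack([np.ones(n), rng.lognormal(0, 1, n)])
        rejections = 0
        for _ in range(reps):
            y = X @ np.array([1.0, 0.5]) + rng.normal(size=n) * np.sqrt(X[:, 1])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            _, p = breusch_pagan_arrays(y - X @ beta, X)
            rejections += p < alpha
        assert rejections / reps >= 0.80

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            breusch_pagan_arrays(np.ones(5) * [1, -1, 2, -2, 1],
                                 np.ones((5, 1)), variant="bogus")

    def test_fit_level_wrapper_matches_arrays(self, fitted_model):
        stat, p = breusch_pagan(fitted_model, variant="studentized")
        assert stat == pytest.approx(fitted_model.bp_statistic, abs=1e-10)
        assert p == pytest.approx(fitted_model.bp_p_value, abs=1e-10)


class TestBackTransform:
    def _single_fit(self, b0, b1, rng):
        frame = _design_frame(rng, 40, ["x1"])
        y = np.expm1(b0 + b1 * np.log1p(frame["x1"].to_numpy()))
        return fit_log1p_model(_aggregates_from_y(y), frame, ["x1"])

    def test_zero_coefficient_gives_zero_effect_both_modes(self, rng):
        fit = self._single_fit(0.9, 0.0, rng)
        assert back_transform(fit, "exponentiated")["x1"][0] == pytest.approx(0, abs=1e-9)
        assert back_transform(fit, "marginal_effect")["x1"][0] == pytest.approx(0, abs=1e-9)

    def test_identity_model_marginal_effect_is_one_at_zero(self, rng):
        fit = self._single_fit(0.0, 1.0, rng)
        effects = back_transform(fit, "marginal_effect", reference_point={"x1": 0.0})
        assert effects["x1"][0] == pytest.approx(1.0, abs=1e-8)

    def test_marginal_effect_matches_finite_differences(self, fitted_model):
        ref = dict(fitted_model.regressor_means)
        effects = back_transform(fitted_model, "marginal_effect", reference_point=ref)

        beta = fitted_model.coef_vector
        def predict(point):
            x = np.array([point[v] for v in fitted_model.regressors])
            return np.expm1(beta[0] + beta[1:] @ np.log1p(x))

        for var in fitted_model.regressors:
            h = 1e-4 * (1 + abs(ref[var]))   # central-difference step
            up = dict(ref); up[var] += h
            dn = dict(ref); dn[var] -= h
            numeric = (predict(up) - predict(dn)) / (2 * h)
            assert effects[var][0] == pytest.approx(numeric, rel=1e-6)

    def test_exponentiated_intercept(self, rng):
        fit = self._single_fit(0.7, 0.3, rng)
        assert back_transform(fit, "exponentiated")["intercept"][0] == pytest.approx(
            np.exp(0.7), rel=1e-8)

    def test_unknown_mode_rejected(self, fitted_model):
        with pytest.raises(RegistryError, match="mode"):
            back_transform(fitted_model, "bogus")


class TestPredictCycle:
    def test_exact_nine_is_not_clamped(self, rng):
        fit = TestBackTransform()._single_fit(0.0, 1.0, rng)
        preds = predict_cycle(fit, pd.DataFrame({"x1": [9.0]}))
        assert preds[0].continuous_frequency_years == pytest.approx(9.0, abs=1e-9)
        assert preds[0].rounded_cycle_years == 9
        assert not preds[0].clamped

    def test_floor_clamp_flags_prediction(self, rng):
        fit = TestBackTransform()._single_fit(0.0, 1.0, rng)
        preds = predict_cycle(fit, pd.DataFrame({"x1": [3.2]}), floor_years=5)
        assert preds[0].rounded_cycle_years == 5
        assert preds[0].clamped

    def test_matches_round_clamp_oracle_elementwise(self, fitted_model):
        config = GeneratorConfig(n_substances=200, seed=21)
        frame = generate_features(config)
        preds = predict_cycle(fitted_model, frame)
        for p in preds:
            unclamped = round_half_up(p.continuous_frequency_years)
            expected = min(max(unclamped, 5), 13)
            assert p.rounded_cycle_years == expected
            assert p.clamped == (expected != unclamped)

    def test_monotone_in_age_and_counts(self, rng):
        # with the expected coefficient signs (age +, safety counts -)
        # the predicted cycle is monotone in each input
        config = GeneratorConfig(n_substances=400, seed=31, noise_sd=0.01,
                                 rater_noise_sd=0.01)
        frame = generate_features(config)
        survey = generate_survey(frame, config)
        fit = fit_log1p_model(aggregate_survey(survey), frame)
        assert fit.coefficients_log_scale["years_in_eurd"].estimate > 0
        for var in fit.regressors[1:]:
            assert fit.coefficients_log_scale[var].estimate < 0

        base = {v: 10.0 for v in fit.regressors}
        def cont(point):
            return predict_cycle(
                fit, pd.DataFrame([point]), floor_years=0, ceiling_years=None
            )[0].continuous_frequency_years
        f0 = cont(base)
        up_age = dict(base); up_age["years_in_eurd"] += 5
        assert cont(up_age) >= f0
        for var in fit.regressors:
            if var == "years_in_eurd":
                continue
            up = dict(base); up[var] += 5
            assert cont(up) <= f0

    def test_noiseless_self_generated_roundtrip(self, rng):
        frame = _design_frame(rng, 50, ["x1", "x2"])
        y = np.expm1(0.4 + 0.3 * np.log1p(frame["x1"]) + 0.2 * np.log1p(frame["x2"]))
        fit = fit_log1p_model(_aggregates_from_y(y), frame, ["x1", "x2"])
        preds = predict_cycle(fit, frame, floor_years=0, ceiling_years=None)
        got = np.array([p.continuous_frequency_years for p in preds])
        assert np.allclose(got, y, atol=1e-8)

    def test_negative_count_rejected(self, fitted_model):
        bad = pd.DataFrame([{v: -1.0 for v in fitted_model.regressors}])
        with pytest.raises(RegistryError, match="negative"):
            predict_cycle(fitted_model, bad)


class TestWorkedArithmetic:
    @pytest.mark.parametrize(
        "per_case_years, months, expected",
        [(0.02, 5.0, 21), (1.0, 12.0, 1), (0.05, 6.0, 10)],
    )
    def test_cases_for_equivalent_reduction(self, per_case_years, months, expected):
        assert cases_for_equivalent_reduction(per_case_years, months) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(RegistryError):
            cases_for_equivalent_reduction(0.0, 5.0)
        with pytest.raises(RegistryError):
            cases_for_equivalent_reduction(0.02, -5.0)


def test_fit_json_roundtrip_supports_prediction(tmp_path, fitted_model, feature_frame):
    fitted_model.to_json(tmp_path / "fit.json")
    loaded = ModelFit.from_json(tmp_path / "fit.json")
    original = predict_cycle(fitted_model, feature_frame)
    rehydrated = predict_cycle(loaded, feature_frame)
    assert [p.rounded_cycle_years for p in original] == [
        p.rounded_cycle_years for p in rehydrated
    ]
    assert np.allclose(
        [p.continuous_frequency_years for p in original],
        [p.continuous_frequency_years for p in rehydrated],
    )


def test_model_recovers_generator_coefficients(small_config, feature_frame, survey_table):
    fit = fit_log1p_model(aggregate_survey(survey_table), feature_frame)
    true = small_config.true_coefficients
    # n = 60 training substances: estimates land near the truth
    assert fit.coefficients_log_scale["years_in_eurd"].estimate == pytest.approx(
        true["years_in_eurd"], abs=0.15)
    assert fit.adjusted_r_squared > 0.4
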