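"""The log1p linear regression for PSUR frequency prediction.

The aggregated proposed frequency ``F`` (years) is modelled on the
log1p scale::

    log(1 + F) = b0 + sum_i b_i * log(1 + x_i) + e,   e ~ N(0, s^2)

with five regressors: years since first authorisation, signal
procedures requiring regulatory action (trailing 3 years), safety
referrals, total adverse-event cases (trailing 3 years), and pregnancy
cases. log1p handles the many zero counts; on the natural scale the
model is the power law ``(1 + F) = exp(b0) * prod_i (1 + x_i)^{b_i}``.

Fitting is ordinary least squares with classical standard errors.
Goodness of fit is judged by the adjusted R-squared, and
homoscedasticity by the Breusch-Pagan test on the fitted residuals.
Predicted frequencies are back-transformed with expm1, rounded to
integer-year cycles, and clamped to an operational window (minimum
cycle 5 years by policy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .registry import RegistryError, SafetyFeatures
from .screening import MODEL_REGRESSORS, SurveyAggregate, aggregates_to_frame, _feature_frame

__all__ = [
    "CoefficientEstimate",
    "ModelFit",
    "Prediction",
    "fit_log1p_model",
    "breusch_pagan",
    "breusch_pagan_arrays",
    "back_transform",
    "predict_cycle",
    "cases_for_equivalent_reduction",
    "round_half_up",
    "DEFAULT_FLOOR_YEARS",
    "DEFAULT_CEILING_YEARS",
]

#: Operational minimum predicted cycle: entries being re-assigned come
#: off a long deferral, so cycles below five years are floored.
DEFAULT_FLOOR_YEARS = 5
#: Default ceiling: the historical deferral cycle length.
DEFAULT_CEILING_YEARS = 13


@dataclass(frozen=True)
class CoefficientEstimate:
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class ModelFit:
    """A fitted log1p-scale OLS model with diagnostics.

    ``coefficients_log_scale`` maps regressor name to its estimate on
    the log1p-log1p scale; ``residuals`` are paired element-wise with
    ``fitted_values`` and with the rows of ``design`` (which includes
    the leading intercept column of ones).
    """

    regressors: tuple[str, ...]
    intercept_log_scale: CoefficientEstimate
    coefficients_log_scale: dict[str, CoefficientEstimate]
    adjusted_r_squared: float
    r_squared: float
    bp_statistic: float
    bp_p_value: float
    n_obs: int
    residuals: np.ndarray
    fitted_values: np.ndarray
    design: np.ndarray
    substance_ids: tuple[str, ...] = ()
    regressor_means: dict[str, float] = field(default_factory=dict)

    @property
    def coef_vector(self) -> np.ndarray:
        """Intercept followed by regressor coefficients, design order."""
        return np.array(
            [self.intercept_log_scale.estimate]
            + [self.coefficients_log_scale[v].estimate for v in self.regressors]
        )

    def to_json(self, path: str | Path | None = None) -> str:
        def coef(c: CoefficientEstimate) -> dict:
            return {
                "estimate": c.estimate, "std_error": c.std_error,
                "ci_low": c.ci_low, "ci_high": c.ci_high, "p_value": c.p_value,
            }

        payload = {
            "regressors": list(self.regressors),
            "intercept_log_scale": coef(self.intercept_log_scale),
            "coefficients_log_scale": {
                v: coef(c) for v, c in self.coefficients_log_scale.items()
            },
            "back_transformed_marginal_effects": {
                v: {"estimate": e, "ci_low": lo, "ci_high": hi}
                for v, (e, lo, hi) in back_transform(self, mode="marginal_effect").items()
            },
            "adjusted_r_squared": self.adjusted_r_squared,
            "r_squared": self.r_squared,
            "breusch_pagan": {
                "statistic": self.bp_statistic, "p_value": self.bp_p_value,
            },
            "n_obs": self.n_obs,
            "regressor_means": self.regressor_means,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelFit":
        """Rehydrate coefficients for prediction; residual-level
        diagnostics are not round-tripped."""
        payload = json.loads(Path(path).read_text())

        def coef(d: dict) -> CoefficientEstimate:
            return CoefficientEstimate(
                d["estimate"], d["std_error"], d["ci_low"], d["ci_high"], d["p_value"]
            )

        n = payload["n_obs"]
        return cls(
            regressors=tuple(payload["regressors"]),
            intercept_log_scale=coef(payload["intercept_log_scale"]),
            coefficients_log_scale={
                v: coef(c) for v, c in payload["coefficients_log_scale"].items()
            },
            adjusted_r_squared=payload["adjusted_r_squared"],
            r_squared=payload["r_squared"],
            bp_statistic=payload["breusch_pagan"]["statistic"],
            bp_p_value=payload["breusch_pagan"]["p_value"],
            n_obs=n,
            residuals=np.empty(0),
            fitted_values=np.empty(0),
            design=np.empty((0, len(payload["regressors"]) + 1)),
            regressor_means=dict(payload.get("regressor_means", {})),
        )


@dataclass(frozen=True)
class Prediction:
    substance_id: str
    continuous_frequency_years: float
    rounded_cycle_years: int
    clamped: bool


def fit_log1p_model(
    aggregates: Sequence[SurveyAggregate],
    features: Sequence[SafetyFeatures] | pd.DataFrame,
    regressors: Sequence[str] = MODEL_REGRESSORS,
    bp_variant: str = "studentized",
) -> ModelFit:
    """Fit the log1p OLS model of aggregated frequency on the regressors.

    Parameters
    ----------
    aggregates:
        Geometric-mean survey frequencies (the response, before log1p).
    features:
        Feature table (or DataFrame) containing every regressor column;
        joined to aggregates on substance_id.
    regressors:
        Regressor names, default the five screened model variables.
    bp_variant:
        Breusch-Pagan variant stored in the fit diagnostics.

    Confidence intervals are 95% t-intervals with n - k - 1 degrees of
    freedom; p-values are two-sided t-tests.
    """
    feat = _feature_frame(features)
    agg = aggregates_to_frame(aggregates)
    merged = agg.merge(feat, on="substance_id", how="inner")
    missing = [v for v in regressors if v not in merged.columns]
    if missing:
        raise RegistryError(f"regressors not present in features: {missing}")
    n = len(merged)
    k = len(regressors)
    if n <= k + 1:
        raise RegistryError(
            f"need more observations than regressors + 1: n={n}, k={k}"
        )

    raw = merged[list(regressors)].to_numpy(float)
    if np.any(raw < -1):
        raise RegistryError("regressor values below -1 are outside log1p domain")
    X = sm.add_constant(np.log1p(raw), has_constant="add")
    y = np.log1p(merged["geometric_mean_frequency"].to_numpy(float))

    ols = sm.OLS(y, X)
    try:
        res = ols.fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RegistryError(f"singular design matrix: {exc}") from exc
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [
            regressors[j - 1]
            for j in range(1, X.shape[1])
            if np.ptp(X[:, j]) == 0
        ]
        raise RegistryError(
            f"rank-deficient design; aliased or constant columns: "
            f"{aliased or 'linear combination among regressors'}"
        )

    ci = res.conf_int(alpha=0.05)

    def coef(j: int) -> CoefficientEstimate:
        return CoefficientEstimate(
            estimate=float(res.params[j]),
            std_error=float(res.bse[j]),
            ci_low=float(ci[j, 0]),
            ci_high=float(ci[j, 1]),
            p_value=float(res.pvalues[j]),
        )

    bp_stat, bp_p = breusch_pagan_arrays(res.resid, X, variant=bp_variant)
    return ModelFit(
        regressors=tuple(regressors),
        intercept_log_scale=coef(0),
        coefficients_log_scale={v: coef(j + 1) for j, v in enumerate(regressors)},
        adjusted_r_squared=float(res.rsquared_adj),
        r_squared=float(res.rsquared),
        bp_statistic=float(bp_stat),
        bp_p_value=float(bp_p),
        n_obs=n,
        residuals=np.asarray(res.resid),
        fitted_values=np.asarray(res.fittedvalues),
        design=X,
        substance_ids=tuple(merged["substance_id"]),
        regressor_means={v: float(merged[v].mean()) for v in regressors},
    )


def breusch_pagan_arrays(
    resid: np.ndarray, exog: np.ndarray, variant: str = "studentized"
) -> tuple[float, float]:
    """Breusch-Pagan heteroscedasticity test on residuals and design.

    Auxiliary regression of squared residuals on the design matrix.
    ``classic`` assumes Gaussian errors (LM = half the explained sum of
    squares of e^2/sigma-hat^2); ``studentized`` is Koenker's
    scale-robust variant LM = n * R^2 of the auxiliary regression. Both
    are referred to chi-squared with k (non-constant columns) degrees of
    freedom; the p-value is the upper tail.
    """
    resid = np.asarray(resid, float)
    exog = np.asarray(exog, float)
    if resid.ndim != 1 or exog.shape[0] != resid.shape[0]:
        raise ValueError("resid must be 1-D and aligned with exog rows")
    if np.ptp(resid**2) == 0:
        # no variation in squared residuals: nothing to explain
        return 0.0, 1.0
    if variant == "studentized":
        lm, lm_pvalue, _, _ = het_breuschpagan(resid, exog, robust=True)
    elif variant == "classic":
        lm, lm_pvalue, _, _ = het_breuschpagan(resid, exog, robust=False)
    else:
        raise ValueError(f"unknown Breusch-Pagan variant {variant!r}")
    return float(lm), float(lm_pvalue)


def breusch_pagan(fit: ModelFit, variant: str = "studentized") -> tuple[float, float]:
    """Breusch-Pagan test on a fitted model's stored residuals."""
    if fit.residuals.size == 0:
        raise RegistryError(
            "fit carries no residuals (loaded from JSON?); "
            "re-fit to run diagnostics"
        )
    return breusch_pagan_arrays(fit.residuals, fit.design, variant=variant)


def _predict_continuous(fit: ModelFit, raw_regressor_values: np.ndarray) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(raw_regressor_values)), np.log1p(raw_regressor_values)]
    )
    return np.expm1(X @ fit.coef_vector)


def back_transform(
    fit: ModelFit,
    mode: str = "marginal_effect",
    reference_point: Mapping[str, float] | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Coefficients on the natural (years) scale.

    ``exponentiated``
        Returns exp(b0) for the intercept and the raw exponents b_i of
        the power-law form (1 + F) = exp(b0) * prod (1 + x_i)^{b_i}.
    ``marginal_effect`` (default)
        Returns dF/dx_i in years per unit of x_i evaluated at a
        reference point (default: the sample means of the regressors
        recorded at fit time):

            dF/dx_i = (1 + F(x)) * b_i / (1 + x_i)

        This is the additive years-per-unit reading: one extra signal
        procedure changes the predicted cycle by approximately this
        many years near the reference substance. Confidence limits are
        the coefficient CI endpoints mapped through the same formula.

    Returns a dict mapping variable (and ``"intercept"``) to
    (estimate, ci_low, ci_high).
    """
    if mode == "exponentiated":
        out: dict[str, tuple[float, float, float]] = {
            "intercept": (
                math.exp(fit.intercept_log_scale.estimate),
                math.exp(fit.intercept_log_scale.ci_low),
                math.exp(fit.intercept_log_scale.ci_high),
            )
        }
        for v, c in fit.coefficients_log_scale.items():
            out[v] = (c.estimate, c.ci_low, c.ci_high)
        return out
    if mode != "marginal_effect":
        raise RegistryError(f"unknown back-transform mode {mode!r}")

    if reference_point is None:
        if not fit.regressor_means:
            raise RegistryError("marginal_effect requires a reference point")
        reference_point = fit.regressor_means
    ref = np.array([[float(reference_point[v]) for v in fit.regressors]])
    f_hat = float(_predict_continuous(fit, ref)[0])

    out = {
        "intercept": (
            math.expm1(fit.intercept_log_scale.estimate),
            math.expm1(fit.intercept_log_scale.ci_low),
            math.expm1(fit.intercept_log_scale.ci_high),
        )
    }
    for j, v in enumerate(fit.regressors):
        c = fit.coefficients_log_scale[v]
        scale = (1.0 + f_hat) / (1.0 + ref[0, j])
        lo, hi = sorted((c.ci_low * scale, c.ci_high * scale))
        out[v] = (c.estimate * scale, lo, hi)
    return out


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves rounding up."""
    return int(math.floor(x + 0.5))


def predict_cycle(
    fit: ModelFit,
    features: Sequence[Mapping[str, float]] | pd.DataFrame,
    floor_years: int = DEFAULT_FLOOR_YEARS,
    ceiling_years: int | None = DEFAULT_CEILING_YEARS,
    rounding=round_half_up,
) -> list[Prediction]:
    """Predict continuous and integer-year PSUR cycles per substance.

    The continuous prediction is expm1 of the linear predictor on log1p
    inputs; it is rounded to whole years (round-half-up by default) and
    clamped to [floor_years, ceiling_years]. ``clamped`` flags rows
    where clamping changed the rounded value.
    """
    if isinstance(features, pd.DataFrame):
        frame = features
    else:
        frame = pd.DataFrame(list(features))
    missing = [v for v in fit.regressors if v not in frame.columns]
    if missing:
        raise RegistryError(f"prediction input missing regressors: {missing}")
    raw = frame[list(fit.regressors)].to_numpy(float)
    if np.any(raw < 0):
        raise RegistryError("negative feature counts are not valid inputs")
    if not np.all(np.isfinite(raw)):
        raise RegistryError("non-finite regressor values in prediction input")
    continuous = _predict_continuous(fit, raw)

    ids = (
        frame["substance_id"].astype(str).tolist()
        if "substance_id" in frame.columns
        else [str(i) for i in range(len(frame))]
    )
    predictions = []
    for sid, value in zip(ids, continuous):
        unclamped = rounding(float(value))
        cycle = max(unclamped, floor_years)
        if ceiling_years is not None:
            cycle = min(cycle, ceiling_years)
        predictions.append(
            Prediction(
                substance_id=sid,
                continuous_frequency_years=float(value),
                rounded_cycle_years=int(cycle),
                clamped=cycle != unclamped,
            )
        )
    return predictions


def cases_for_equivalent_reduction(
    per_case_effect_years: float, reduction_months: float
) -> int:
    """Number of cases with the same cycle reduction as a reference effect.

    If one adverse-event case shortens the predicted cycle by
    ``per_case_effect_years`` (years), the number of cases equivalent to
    a reduction of ``reduction_months`` months is
    ``reduction_months / (per_case_effect_years * 12)``, rounded to the
    nearest whole case. For example a 5-month reduction at 0.02
    years/case takes about 21 cases.
    """
    if per_case_effect_years <= 0 or reduction_months <= 0:
        raise RegistryError(
            "per_case_effect_years and reduction_months must both be > 0"
        )
    return round_half_up(reduction_months / (per_case_effect_years * 12.0))
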