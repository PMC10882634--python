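"""Survey aggregation, correlation screening, and collinearity pruning.

Expert raters propose a PSUR frequency per substance; because proposals
are right-skewed, they are aggregated with the geometric mean. Candidate
safety variables are then screened by their Pearson correlation with the
aggregated frequency, and variables that are nearly collinear with a
preferred partner (squared pairwise correlation at or above a threshold)
are pruned before model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import RegistryError, SafetyFeatures, SurveyTable, features_to_frame

__all__ = [
    "SurveyAggregate",
    "ScreenRow",
    "ScreenReport",
    "DEFAULT_KEEP_RULES",
    "DEFAULT_R2_THRESHOLD",
    "MODEL_REGRESSORS",
    "aggregate_survey",
    "aggregates_to_frame",
    "pearson_screen",
    "prune_collinear",
    "correlation_matrix",
]

#: The five regressors of the frequency-prediction model after pruning.
MODEL_REGRESSORS: tuple[str, ...] = (
    "years_in_eurd",
    "signals_regulatory_action",
    "n_safety_referrals",
    "cases_total",
    "cases_pregnancy",
)

#: Preference order used when one of a collinear pair must be dropped:
#: total cases are kept over their fatal/life-threatening and DME
#: subsets, and pregnancy cases over paediatric cases (the regressor the
#: fitted model uses). Earlier in the list wins.
DEFAULT_KEEP_RULES: tuple[str, ...] = MODEL_REGRESSORS + (
    "cases_fatal_lt",
    "cases_dme",
    "cases_paediatric",
)

#: Smallest round threshold covering pairwise r-squared values of
#: 0.82-0.93 observed between total-case counts and their subsets.
DEFAULT_R2_THRESHOLD: float = 0.80


@dataclass(frozen=True)
class SurveyAggregate:
    """Geometric-mean proposed frequency for one substance."""

    substance_id: str
    geometric_mean_frequency: float
    n_raters: int


@dataclass(frozen=True)
class ScreenRow:
    variable_name: str
    pearson_r: float | None
    retained: bool
    dropped_for: str | None = None
    pair_r_squared: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if (not self.retained) != (self.dropped_for is not None):
            raise ValueError("retained=False exactly when dropped_for is set")
        if (self.pair_r_squared is not None) != (self.dropped_for is not None):
            raise ValueError("pair_r_squared set exactly when dropped_for is set")


@dataclass
class ScreenReport:
    rows: list[ScreenRow] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [r.variable_name for r in self.rows if r.retained]

    @property
    def dropped(self) -> list[str]:
        return [r.variable_name for r in self.rows if not r.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.variable_name, r.pearson_r, r.retained, r.dropped_for,
                 r.pair_r_squared, r.degenerate)
                for r in self.rows
            ],
            columns=[
                "variable_name", "pearson_r", "retained", "dropped_for",
                "pair_r_squared", "degenerate",
            ],
        )


def aggregate_survey(survey: SurveyTable) -> list[SurveyAggregate]:
    """Aggregate rater proposals per substance by geometric mean.

    geometric mean = exp(mean(log(proposals))); chosen because proposed
    frequencies are right-skewed and rater noise is closer to
    multiplicative than additive. Requires every proposal > 0.
    """
    survey.validate()
    by_substance: dict[str, list[float]] = {}
    for entry in survey.entries:
        by_substance.setdefault(entry.substance_id, []).append(
            entry.proposed_frequency_years
        )
    return [
        SurveyAggregate(
            substance_id=sid,
            geometric_mean_frequency=math.exp(
                sum(math.log(p) for p in proposals) / len(proposals)
            ),
            n_raters=len(proposals),
        )
        for sid, proposals in sorted(by_substance.items())
    ]


def aggregates_to_frame(aggregates: Iterable[SurveyAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.substance_id, a.geometric_mean_frequency, a.n_raters) for a in aggregates],
        columns=["substance_id", "geometric_mean_frequency", "n_raters"],
    )


def _feature_frame(
    features: Sequence[SafetyFeatures] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return features_to_frame(features)


def pearson_screen(
    aggregates: Sequence[SurveyAggregate],
    features: Sequence[SafetyFeatures] | pd.DataFrame,
    variables: Sequence[str],
) -> ScreenReport:
    """Pearson correlation of each candidate variable with the aggregate.

    Correlations are computed on raw (untransformed) values; the log1p
    transform belongs to the model stage. A zero-variance variable is
    flagged degenerate with an undefined correlation rather than letting
    NaN propagate.
    """
    feat = _feature_frame(features)
    agg = aggregates_to_frame(aggregates)
    merged = agg.merge(feat, on="substance_id", how="inner")
    if len(merged) < 3:
        raise RegistryError(
            f"need >= 3 substances with both survey and feature data, "
            f"got {len(merged)}"
        )
    missing = [v for v in variables if v not in merged.columns]
    if missing:
        raise RegistryError(f"variables not present in features: {missing}")

    y = merged["geometric_mean_frequency"].to_numpy(float)
    rows = []
    for var in variables:
        x = merged[var].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(ScreenRow(var, None, retained=True, degenerate=True))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append(ScreenRow(var, r, retained=True))
    return ScreenReport(rows=rows)


def correlation_matrix(
    features: Sequence[SafetyFeatures] | pd.DataFrame,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of candidate variables."""
    feat = _feature_frame(features)
    missing = [v for v in variables if v not in feat.columns]
    if missing:
        raise RegistryError(f"variables not present in features: {missing}")
    return feat[list(variables)].corr(method="pearson")


def prune_collinear(
    features: Sequence[SafetyFeatures] | pd.DataFrame,
    candidate_vars: Sequence[str],
    keep_rules: Sequence[str] = DEFAULT_KEEP_RULES,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> ScreenReport:
    """Drop one variable of each highly collinear pair.

    For every unordered pair of candidates whose squared Pearson
    correlation is at or above ``r2_threshold``, the variable appearing
    earlier in ``keep_rules`` is retained and the other is marked
    dropped, recording the partner and the pair's r-squared. With the
    default preference list the retained set is the five model
    regressors.
    """
    if not 0 < r2_threshold <= 1:
        raise RegistryError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    corr = correlation_matrix(features, candidate_vars)
    rank: Mapping[str, int] = {v: i for i, v in enumerate(keep_rules)}

    dropped: dict[str, tuple[str, float]] = {}
    for a, b in combinations(candidate_vars, 2):
        r = corr.loc[a, b]
        if pd.isna(r):
            continue
        r2 = float(r) ** 2
        if r2 < r2_threshold:
            continue
        if a not in rank or b not in rank:
            raise RegistryError(
                f"keep_rules does not cover the collinear pair ({a!r}, {b!r}) "
                f"with r^2 = {r2:.3f}"
            )
        loser = b if rank[a] < rank[b] else a
        winner = a if loser == b else b
        # a variable already dropped keeps its first recorded partner
        if loser not in dropped:
            dropped[loser] = (winner, r2)

    # dropping is transitive-safe: a winner that itself lost earlier in
    # rank order cannot occur because preference is a total order
    rows = [
        ScreenRow(
            var,
            None,
            retained=var not in dropped,
            dropped_for=dropped.get(var, (None,))[0],
            pair_r_squared=dropped[var][1] if var in dropped else None,
            degenerate=False,
        )
        for var in candidate_vars
    ]
    return ScreenReport(rows=rows)
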