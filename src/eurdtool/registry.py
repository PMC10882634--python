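"""Domain types and CSV interchange for substance registries.

Three flat tables make up a study dataset:

``substances.csv``
    One row per registry entry (an active substance or combination):
    its current PSUR cycle, the calendar year of its next data lock
    point (DLP), how long it has been listed, and whether its first
    assessment was deferred.

``features.csv``
    Per-substance safety feature counts: EudraVigilance-style case
    counts over a trailing three-year window, signal procedures that
    required regulatory action, and safety referrals.

``survey.csv``
    Long-format rater x substance proposals of PSUR frequencies in
    years, later aggregated by geometric mean.

All readers validate row-by-row and raise :class:`RegistryError` with
row-level diagnostics rather than silently dropping bad rows.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SubstanceRecord",
    "SafetyFeatures",
    "SurveyEntry",
    "SurveyTable",
    "RegistryError",
    "SCHEMAS",
    "COUNT_VARIABLES",
    "read_registry",
    "write_registry",
    "substances_to_frame",
    "features_to_frame",
    "years_in_list",
]


class RegistryError(ValueError):
    """Raised for schema violations, parse failures, or invariant breaches."""


@dataclass(frozen=True)
class SubstanceRecord:
    """One registry entry.

    Parameters
    ----------
    substance_id:
        Opaque unique key.
    name:
        Free-text substance name.
    years_in_eurd:
        Years since the first EU authorisation of a product containing
        the substance (non-negative).
    frequency_years:
        Current PSUR submission cycle in years (> 0; sub-year cycles
        such as 0.5 are valid for newly authorised products).
    dlp_year:
        Calendar year of the next data lock point.
    deferred:
        True for entries parked on the long 13-year cycle awaiting a
        newly assigned frequency.
    mapped:
        Whether the entry maps to the safety-feature source; unmapped
        entries are carried through reporting but excluded from
        prediction and scheduling.
    """

    substance_id: str
    name: str
    years_in_eurd: float
    frequency_years: float
    dlp_year: int
    deferred: bool
    mapped: bool = True

    def validate(self) -> None:
        if self.years_in_eurd < 0:
            raise RegistryError(
                f"substance {self.substance_id!r}: years_in_eurd must be >= 0, "
                f"got {self.years_in_eurd}"
            )
        if not self.frequency_years > 0:
            raise RegistryError(
                f"substance {self.substance_id!r}: frequency_years must be > 0, "
                f"got {self.frequency_years}"
            )


#: Count variables carried in the features table, in canonical column order.
COUNT_VARIABLES: tuple[str, ...] = (
    "signals_regulatory_action",
    "n_safety_referrals",
    "cases_total",
    "cases_pregnancy",
    "cases_paediatric",
    "cases_fatal_lt",
    "cases_dme",
)


@dataclass(frozen=True)
class SafetyFeatures:
    """Per-substance safety feature counts (trailing three-year window).

    ``cases_fatal_lt`` (fatal and/or life-threatening) and ``cases_dme``
    (designated medical events) are subsets of ``cases_total`` and may
    not exceed it.
    """

    substance_id: str
    signals_regulatory_action: int
    n_safety_referrals: int
    cases_total: int
    cases_pregnancy: int
    cases_paediatric: int
    cases_fatal_lt: int
    cases_dme: int

    def validate(self) -> None:
        for var in COUNT_VARIABLES:
            value = getattr(self, var)
            if value < 0 or value != int(value):
                raise RegistryError(
                    f"substance {self.substance_id!r}: {var} must be a "
                    f"non-negative integer, got {value}"
                )
        if self.cases_fatal_lt > self.cases_total:
            raise RegistryError(
                f"substance {self.substance_id!r}: cases_fatal_lt "
                f"({self.cases_fatal_lt}) exceeds cases_total ({self.cases_total})"
            )
        if self.cases_dme > self.cases_total:
            raise RegistryError(
                f"substance {self.substance_id!r}: cases_dme "
                f"({self.cases_dme}) exceeds cases_total ({self.cases_total})"
            )


@dataclass(frozen=True)
class SurveyEntry:
    substance_id: str
    rater_id: str
    proposed_frequency_years: float

    def validate(self) -> None:
        if not self.proposed_frequency_years > 0:
            raise RegistryError(
                f"survey proposal by rater {self.rater_id!r} for substance "
                f"{self.substance_id!r} must be > 0 "
                f"(geometric-mean aggregation requires positivity), "
                f"got {self.proposed_frequency_years}"
            )


@dataclass
class SurveyTable:
    """Rater x substance proposed PSUR frequencies, long format."""

    entries: list[SurveyEntry]

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for entry in self.entries:
            entry.validate()
            key = (entry.substance_id, entry.rater_id)
            if key in seen:
                raise RegistryError(
                    f"duplicate survey entry for substance {key[0]!r}, "
                    f"rater {key[1]!r}"
                )
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.substance_id, e.rater_id, e.proposed_frequency_years)
                for e in self.entries
            ],
            columns=list(SCHEMAS["survey"]),
        )


SCHEMAS: dict[str, tuple[str, ...]] = {
    "substances": (
        "substance_id",
        "name",
        "years_in_eurd",
        "frequency_years",
        "dlp_year",
        "deferred",
        "mapped",
    ),
    "features": ("substance_id",) + COUNT_VARIABLES,
    "survey": ("substance_id", "rater_id", "proposed_frequency_years"),
}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(value: object, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text not in _BOOL_MAP:
        raise RegistryError(
            f"row {row}: column {column!r} must be boolean-like, got {value!r}"
        )
    return _BOOL_MAP[text]


def _parse_number(value: object, column: str, row: int, kind: type) -> float | int:
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise RegistryError(
            f"row {row}: column {column!r} is not numeric: {value!r}"
        ) from exc


def read_registry(path: str | Path, schema: str):
    """Read and validate one of the three study tables.

    Parameters
    ----------
    path:
        CSV file whose header must exactly match the schema's columns.
    schema:
        One of ``"substances"``, ``"features"``, ``"survey"``.

    Returns
    -------
    list[SubstanceRecord] | list[SafetyFeatures] | SurveyTable
    """
    if schema not in SCHEMAS:
        raise RegistryError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SCHEMAS[schema]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise RegistryError(
            f"{path}: schema {schema!r} is missing column(s) {missing}"
        )
    frame = frame[list(expected)]

    if schema == "substances":
        records = []
        seen_ids: set[str] = set()
        for i, row in enumerate(frame.itertuples(index=False)):
            sid = row.substance_id
            if sid in seen_ids:
                raise RegistryError(f"row {i}: duplicate substance_id {sid!r}")
            seen_ids.add(sid)
            rec = SubstanceRecord(
                substance_id=sid,
                name=row.name,
                years_in_eurd=_parse_number(row.years_in_eurd, "years_in_eurd", i, float),
                frequency_years=_parse_number(row.frequency_years, "frequency_years", i, float),
                dlp_year=int(_parse_number(row.dlp_year, "dlp_year", i, float)),
                deferred=_parse_bool(row.deferred, "deferred", i),
                mapped=_parse_bool(row.mapped, "mapped", i),
            )
            try:
                rec.validate()
            except RegistryError as exc:
                raise RegistryError(f"row {i}: {exc}") from None
            records.append(rec)
        return records

    if schema == "features":
        features = []
        seen_ids = set()
        for i, row in enumerate(frame.itertuples(index=False)):
            sid = row.substance_id
            if sid in seen_ids:
                raise RegistryError(f"row {i}: duplicate substance_id {sid!r}")
            seen_ids.add(sid)
            feat = SafetyFeatures(
                substance_id=sid,
                **{
                    var: int(_parse_number(getattr(row, var), var, i, float))
                    for var in COUNT_VARIABLES
                },
            )
            try:
                feat.validate()
            except RegistryError as exc:
                raise RegistryError(f"row {i}: {exc}") from None
            features.append(feat)
        return features

    entries = [
        SurveyEntry(
            substance_id=row.substance_id,
            rater_id=row.rater_id,
            proposed_frequency_years=_parse_number(
                row.proposed_frequency_years, "proposed_frequency_years", i, float
            ),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]
    table = SurveyTable(entries=entries)
    table.validate()
    return table


def write_registry(records, path: str | Path) -> None:
    """Write a validated table as RFC-4180-style CSV.

    Output is deterministic: canonical column order, rows sorted by
    substance_id (and rater_id for surveys). Writing the same records
    twice yields byte-identical files.
    """
    path = Path(path)
    if isinstance(records, SurveyTable):
        records.validate()
        frame = records.to_frame().sort_values(
            ["substance_id", "rater_id"], kind="mergesort"
        )
    else:
        records = list(records)
        schema = _infer_schema(records)
        for rec in records:
            rec.validate()
        frame = pd.DataFrame(
            [[getattr(r, f.name) for f in dc_fields(r)] for r in records]
            if records
            else [],
            columns=list(SCHEMAS[schema]),
        ).sort_values("substance_id", kind="mergesort")
    frame.to_csv(path, index=False, lineterminator="\r\n")


def _infer_schema(records: Sequence) -> str:
    if not records:
        raise RegistryError(
            "cannot infer schema from an empty record list; "
            "write a SurveyTable or pass at least one record"
        )
    first = records[0]
    if isinstance(first, SubstanceRecord):
        return "substances"
    if isinstance(first, SafetyFeatures):
        return "features"
    raise RegistryError(f"unsupported record type {type(first).__name__}")


def substances_to_frame(records: Iterable[SubstanceRecord]) -> pd.DataFrame:
    """Substance records as a DataFrame in canonical column order."""
    return pd.DataFrame(
        [
            (r.substance_id, r.name, r.years_in_eurd, r.frequency_years,
             r.dlp_year, r.deferred, r.mapped)
            for r in records
        ],
        columns=list(SCHEMAS["substances"]),
    )


def features_to_frame(
    features: Iterable[SafetyFeatures],
    substances: Iterable[SubstanceRecord] | None = None,
) -> pd.DataFrame:
    """Feature counts as a DataFrame, optionally joined with years_in_eurd.

    The regression uses the substance's age in the list alongside the
    safety counts, so most callers pass ``substances`` to obtain the
    joined design table keyed by substance_id.
    """
    frame = pd.DataFrame(
        [
            (f.substance_id, *[getattr(f, v) for v in COUNT_VARIABLES])
            for f in features
        ],
        columns=list(SCHEMAS["features"]),
    )
    if substances is not None:
        ages = pd.DataFrame(
            [(r.substance_id, r.years_in_eurd) for r in substances],
            columns=["substance_id", "years_in_eurd"],
        )
        frame = frame.merge(ages, on="substance_id", how="left")
    return frame


def years_in_list(first_authorisation_year: int, reference_year: int) -> float:
    """Convert an authorisation year and reference year to age in years."""
    if reference_year < first_authorisation_year:
        raise RegistryError(
            f"reference year {reference_year} precedes first authorisation "
            f"year {first_authorisation_year}"
        )
    return float(reference_year - first_authorisation_year)
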