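"""Workload computation and allocation of deferred substances.

Every registry entry generates recurring PSUR submissions: one at its
next data lock point (DLP) year and one every cycle thereafter.
Summing those events per calendar year gives the background workload
series. Deferred entries, whose new cycles come from the prediction
model, must then be slotted in, either all starting from a common year
(``from_start``) or greedily against a yearly capacity cap
(``capacity``). Under a cap, only the year's allocation pass is
constrained: recurrences of already-allocated entries are never moved,
so later totals can overshoot the cap — the cumulative-recurrence
effect.

Counting conventions: recurrence stepping uses integer-year cycles
(cycles are rounded to whole years, minimum 1); sub-year cycles (e.g.
6-month PSURs for new products) contribute ceil(1/f) submissions in
every year from their DLP onward, since workload is tallied per
calendar year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import RegistryError, SubstanceRecord

__all__ = [
    "WorkloadSeries",
    "Schedule",
    "PolicyConfig",
    "compute_workload",
    "median_workload",
    "apply_scenario2",
    "allocate_from_start",
    "allocate_capacity",
    "summarize_schedule",
    "percent_increase",
    "frequency_mix",
    "DEFAULT_HORIZON",
]

#: Default horizon: simulations check completion as far out as 2100.
DEFAULT_HORIZON: tuple[int, int] = (2022, 2100)


@dataclass
class WorkloadSeries:
    """Submission counts per calendar year over a closed horizon."""

    start_year: int
    end_year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise RegistryError(
                f"horizon end {self.end_year} precedes start {self.start_year}"
            )
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.end_year - self.start_year + 1,):
            raise RegistryError("counts length must match the horizon span")

    @classmethod
    def zeros(cls, start_year: int, end_year: int) -> "WorkloadSeries":
        if end_year < start_year:
            raise RegistryError(
                f"horizon end {end_year} precedes start {start_year}"
            )
        return cls(start_year, end_year, np.zeros(end_year - start_year + 1, int))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def __getitem__(self, year: int) -> int:
        if not self.start_year <= year <= self.end_year:
            raise KeyError(f"year {year} outside horizon "
                           f"[{self.start_year}, {self.end_year}]")
        return int(self.counts[year - self.start_year])

    def copy(self) -> "WorkloadSeries":
        return WorkloadSeries(self.start_year, self.end_year, self.counts.copy())

    def add(self, other: "WorkloadSeries") -> "WorkloadSeries":
        if (other.start_year, other.end_year) != (self.start_year, self.end_year):
            raise RegistryError("cannot add series with different horizons")
        return WorkloadSeries(self.start_year, self.end_year,
                              self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "count": self.counts})


@dataclass
class Schedule:
    """Result of allocating deferred substances to first review years."""

    allocation: dict[str, int]
    policy: str
    completion_year: int | str   # calendar year, or "incomplete"
    series: WorkloadSeries
    cap: int | None = None
    unallocated: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.completion_year != "incomplete"


@dataclass(frozen=True)
class PolicyConfig:
    """Allocation policy settings for a simulation run."""

    policy: str = "from_start"             # "from_start" | "capacity"
    start_year: int = 2022
    cap: int | None = None
    ordering: str = "cycle_asc"            # "cycle_asc" | "id"
    horizon_end: int = DEFAULT_HORIZON[1]
    median_window: tuple[int, int] = (2022, 2032)

    def __post_init__(self) -> None:
        if self.policy not in ("from_start", "capacity"):
            raise RegistryError(f"unknown policy {self.policy!r}")
        if self.policy == "capacity" and (self.cap is None or self.cap <= 0):
            raise RegistryError("capacity policy requires a positive cap")
        if self.horizon_end < self.start_year:
            raise RegistryError("horizon_end must be >= start_year")


def _submission_years(dlp_year: int, frequency_years: float,
                      start: int, end: int) -> Iterable[tuple[int, int]]:
    """(year, n_submissions) pairs within [start, end] for one entry."""
    if frequency_years < 1:
        per_year = math.ceil(1.0 / frequency_years)
        for year in range(max(dlp_year, start), end + 1):
            yield year, per_year
        return
    step = max(1, int(math.floor(frequency_years + 0.5)))
    year = dlp_year
    # fast-forward past the horizon start without looping from far past
    if year < start:
        year += ((start - year + step - 1) // step) * step
    while year <= end:
        yield year, 1
        year += step


def compute_workload(
    substances: Sequence[SubstanceRecord],
    horizon: tuple[int, int] = DEFAULT_HORIZON,
) -> WorkloadSeries:
    """Per-year submission counts implied by current DLPs and cycles.

    Each entry contributes a submission at its DLP year and every
    (rounded) cycle thereafter, truncated to the closed horizon.
    """
    start, end = horizon
    series = WorkloadSeries.zeros(start, end)
    for record in substances:
        for year, n in _submission_years(
            record.dlp_year, record.frequency_years, start, end
        ):
            series.counts[year - start] += n
    return series


def median_workload(series: WorkloadSeries, window: tuple[int, int]) -> float:
    """Median per-year count inside a closed year window."""
    lo, hi = window
    if hi < lo:
        raise RegistryError(f"empty window {window}")
    if lo < series.start_year or hi > series.end_year:
        raise RegistryError(f"window {window} outside series horizon")
    segment = series.counts[lo - series.start_year: hi - series.start_year + 1]
    return float(np.median(segment))


def apply_scenario2(
    substances: Sequence[SubstanceRecord],
) -> list[SubstanceRecord]:
    """Extend short cycles to five years for non-deferred entries.

    Non-deferred entries with a cycle strictly greater than one year
    and below five years are set to a 5-year cycle. Entries on a cycle
    of one year or less keep it (newly authorised products under close
    monitoring), as do entries already at five years or longer and all
    deferred entries.
    """
    out = []
    for record in substances:
        if not record.deferred and 1 < record.frequency_years < 5:
            out.append(replace(record, frequency_years=5.0))
        else:
            out.append(record)
    return out


def _ordered(deferred: Sequence[tuple[str, int]], ordering: str):
    if ordering == "cycle_asc":
        return sorted(deferred, key=lambda t: (t[1], t[0]))
    if ordering == "id":
        return sorted(deferred, key=lambda t: t[0])
    raise RegistryError(f"unknown ordering {ordering!r}")


def allocate_from_start(
    deferred: Sequence[tuple[str, int]],
    start_year: int,
    background: WorkloadSeries | None = None,
    horizon_end: int = DEFAULT_HORIZON[1],
) -> Schedule:
    """Apply each entry's predicted cycle from a common start year.

    The first review of an entry with cycle ``c`` falls at
    ``start_year + c`` (a 9-year cycle starting from 2022 is first
    reviewed in 2031), with recurrences every ``c`` years after that.
    """
    for sid, cycle in deferred:
        if cycle < 1:
            raise RegistryError(f"substance {sid!r}: cycle must be >= 1 year")
    if background is None:
        series = WorkloadSeries.zeros(start_year, horizon_end)
    else:
        series = background.copy()
        horizon_end = series.end_year
    allocation = {sid: start_year + int(cycle) for sid, cycle in deferred}
    for sid, cycle in deferred:
        for year, n in _submission_years(
            allocation[sid], int(cycle), series.start_year, horizon_end
        ):
            series.counts[year - series.start_year] += n
    completion = max(allocation.values()) if allocation else start_year
    return Schedule(
        allocation=allocation,
        policy="from_start",
        completion_year=completion,
        series=series,
    )


def allocate_capacity(
    deferred: Sequence[tuple[str, int]],
    background: WorkloadSeries,
    cap: int,
    start_year: int,
    ordering: str = "cycle_asc",
    horizon_end: int | None = None,
) -> Schedule:
    """Greedy yearly allocation against a capacity cap.

    Walking years from ``start_year``, the running load of year ``y``
    is the background plus all recurrences of previously allocated
    entries that fall in ``y``. While that load is below ``cap``, the
    next unallocated entry (default order: ascending cycle, ties by
    substance id) receives first DLP ``y``, and its future recurrences
    are added to the running load immediately. Recurrences scheduled
    before a year's allocation pass are never deferred, so totals in
    later years may exceed the cap.

    If entries remain once the horizon is exhausted, the schedule is
    returned with completion "incomplete" and the leftover ids listed.
    """
    if cap <= 0:
        raise RegistryError(f"cap must be positive, got {cap}")
    for sid, cycle in deferred:
        if cycle < 1:
            raise RegistryError(f"substance {sid!r}: cycle must be >= 1 year")
    series = background.copy()
    if horizon_end is None:
        horizon_end = series.end_year
    if horizon_end > series.end_year or start_year < series.start_year:
        raise RegistryError("background must cover [start_year, horizon_end]")

    queue = list(_ordered(deferred, ordering))
    allocation: dict[str, int] = {}
    offset = series.start_year
    for year in range(start_year, horizon_end + 1):
        while queue and series.counts[year - offset] < cap:
            sid, cycle = queue.pop(0)
            allocation[sid] = year
            for y, n in _submission_years(year, int(cycle), year, horizon_end):
                series.counts[y - offset] += n
    completion: int | str
    if queue:
        completion = "incomplete"
    else:
        completion = max(allocation.values()) if allocation else start_year
    return Schedule(
        allocation=allocation,
        policy="capacity",
        completion_year=completion,
        series=series,
        cap=cap,
        unallocated=[sid for sid, _ in queue],
    )


def percent_increase(target: float, baseline_median: float) -> int:
    """Percent increase of a target load over a baseline median,
    rounded to the nearest integer percent (1000 over 868 is 15%)."""
    if baseline_median <= 0:
        raise RegistryError("baseline median must be positive")
    return int(math.floor(100.0 * (target - baseline_median) / baseline_median + 0.5))


def summarize_schedule(
    schedule: Schedule,
    baseline: WorkloadSeries,
    window: tuple[int, int],
    target: float | None = None,
) -> dict:
    """Summary metrics for a schedule against a baseline workload.

    Reports the completion year, the per-year series, the peak year
    and count, the median inside ``window``, and — when a ``target``
    level is given (e.g. a capacity cap) — its percent increase over
    the baseline median.
    """
    series = schedule.series
    baseline_median = median_workload(baseline, window)
    peak_idx = int(np.argmax(series.counts))
    report = {
        "policy": schedule.policy,
        "cap": schedule.cap,
        "completion_year": schedule.completion_year,
        "n_allocated": len(schedule.allocation),
        "n_unallocated": len(schedule.unallocated),
        "unallocated": list(schedule.unallocated),
        "peak_year": int(series.years[peak_idx]),
        "peak_count": int(series.counts[peak_idx]),
        "median_in_window": median_workload(series, window),
        "baseline_median_in_window": baseline_median,
        "series": {int(y): int(c) for y, c in zip(series.years, series.counts)},
    }
    if target is not None:
        report["target"] = target
        report["percent_increase_over_baseline"] = percent_increase(
            target, baseline_median
        )
    return report


def frequency_mix(
    frequencies: Sequence[float] | Sequence[SubstanceRecord],
    thresholds: Sequence[int],
) -> dict[int, float]:
    """Share of entries (percent) with cycle >= each threshold.

    Accepts raw frequencies in years or substance records. Used to
    compare the cycle mix before and after allocating deferred entries
    (e.g. the share of entries on cycles of 7 years or longer).
    """
    values = np.array(
        [
            f.frequency_years if isinstance(f, SubstanceRecord) else float(f)
            for f in frequencies
        ]
    )
    if values.size == 0:
        raise RegistryError("frequency_mix needs at least one entry")
    return {
        int(t): float(100.0 * np.mean(values >= t)) for t in thresholds
    }
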