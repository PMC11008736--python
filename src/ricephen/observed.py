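"""Observed generation periods from field peak dates and count series.

In twice-weekly sticky-board surveys of paddy planthoppers, a generation
shows up as a peak of adult density (or adult percentage) roughly 3-5.5
weeks after the previous arrival or peak.  The observed development
period of a cohort is therefore the calendar interval between successive
event dates — first arrival (or release) to first peak, then peak to
peak.  This module derives those intervals from tabulated event dates and
detects peaks in raw count series.

A table of adult peak dates recorded in 2021 in three paddy fields (three
transplant timings, each split into a normal and a continuously-irrigated
low-water-temperature plot) ships with the package and is loaded with
:func:`load_reference_peak_table`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SPECIES_NAMES

TRANSPLANTS = ("May", "June", "July")
PLOTS = ("normal", "low")


@dataclass(frozen=True)
class PeakRow:
    """One cohort's ordered event dates: start (arrival/release/peak), then peaks."""

    species: str
    transplant: str
    plot: str
    event_dates: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        if self.species not in SPECIES_NAMES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.transplant not in TRANSPLANTS:
            raise ValueError(f"unknown transplant {self.transplant!r}")
        if self.plot not in PLOTS:
            raise ValueError(f"unknown plot {self.plot!r}")
        if len(self.event_dates) < 1:
            raise ValueError("a peak row needs at least one date")
        if any(b <= a for a, b in zip(self.event_dates, self.event_dates[1:])):
            raise ValueError(f"event dates must be strictly increasing: {self.event_dates}")


@dataclass(frozen=True)
class PeakTable:
    rows: tuple[PeakRow, ...]


@dataclass(frozen=True)
class DevelopmentPeriod:
    """One observed generation interval (calendar days, end - start)."""

    species: str
    transplant: str
    plot: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("end_date must follow start_date")

    @property
    def days(self) -> int:
        return (self.end_date - self.start_date).days


@dataclass(frozen=True)
class CountSeries:
    """Sticky-board density series (insects per hill) at ~2 surveys/week."""

    species: str
    plot: str
    survey_dates: tuple[dt.date, ...]
    counts: np.ndarray  # adult (or total) density per hill
    counts_nymph: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.counts_nymph is not None:
            object.__setattr__(
                self, "counts_nymph", np.asarray(self.counts_nymph, dtype=float)
            )
        if len(self.survey_dates) != counts.size:
            raise ValueError("survey_dates and counts differ in length")
        if any(b <= a for a, b in zip(self.survey_dates, self.survey_dates[1:])):
            raise ValueError("survey dates must be strictly increasing")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")


def extract_periods(table: PeakTable) -> list[DevelopmentPeriod]:
    """One development period per successive date pair in each row.

    A row (start, peak1, peak2, ...) yields start->peak1, peak1->peak2, ...
    Rows with a single date yield nothing.
    """
    periods = []
    for row in table.rows:
        for a, b in zip(row.event_dates, row.event_dates[1:]):
            periods.append(
                DevelopmentPeriod(
                    species=row.species,
                    transplant=row.transplant,
                    plot=row.plot,
                    start_date=a,
                    end_date=b,
                )
            )
    return periods


def summarize_mean_period(
    periods: list[DevelopmentPeriod], species: str, plot: str
) -> dict:
    """Sample size and mean observed period (days, 2 dp) for one species/plot."""
    days = [p.days for p in periods if p.species == species and p.plot == plot]
    if not days:
        raise ValueError(f"no periods for species={species!r}, plot={plot!r}")
    return {"n": len(days), "mean": round(float(np.mean(days)), 2)}


def detect_peaks(
    series: CountSeries,
    window_min_days: float = 14.0,
    window_max_days: float | None = None,
    min_count: float = 0.0,
    include_terminal: bool = False,
) -> list[dt.date]:
    """Dates of population peaks in a count series.

    A peak is a survey date whose count is >= both neighbours (ties to the
    earlier date) and >= ``min_count``.  Candidates are then thinned so
    successive kept peaks are at least ``window_min_days`` apart, keeping
    the higher count (earlier date on ties).  Terminal survey dates only
    qualify when ``include_terminal`` is set, since a rising edge at the
    series end cannot be confirmed as a peak.  ``window_max_days``
    optionally drops a peak more than that many days after the previous
    kept peak (or the series start).
    """
    if len(series.survey_dates) < 3:
        raise ValueError("need at least 3 survey dates to detect peaks")
    dates, counts = series.survey_dates, series.counts
    n = counts.size

    candidates = []
    for i in range(n):
        left = counts[i - 1] if i > 0 else None
        right = counts[i + 1] if i < n - 1 else None
        if counts[i] < min_count:
            continue
        if left is None or right is None:
            if include_terminal and (
                (left is None and right is not None and counts[i] > right)
                or (right is None and left is not None and counts[i] > left)
            ):
                candidates.append(i)
            continue
        # strict against the earlier neighbour so a flat-topped peak
        # resolves to its first date
        if counts[i] > left and counts[i] >= right:
            candidates.append(i)

    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: (-counts[i], dates[i])):
        if all(abs((dates[i] - dates[j]).days) >= window_min_days for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: dates[i])

    if window_max_days is not None:
        filtered: list[int] = []
        prev = dates[0]
        for i in kept:
            if (dates[i] - prev).days <= window_max_days:
                filtered.append(i)
                prev = dates[i]
        kept = filtered

    return [dates[i] for i in kept]


def load_reference_peak_table(path: str | Path | None = None) -> PeakTable:
    """Load the packaged 2021 field-survey adult peak-date table (or a CSV
    in the same dialect: species, transplant, plot, event_index, date, with
    event_index restarting at 0 on each new cohort row)."""
    if path is None:
        src = resources.files("ricephen.data").joinpath("adult_peak_dates.csv")
        with resources.as_file(src) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    return peak_table_from_frame(frame)


def peak_table_from_frame(frame: pd.DataFrame) -> PeakTable:
    required = {"species", "transplant", "plot", "event_index", "date"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"peak-table CSV missing columns: {sorted(missing)}")
    rows: list[PeakRow] = []
    current: list | None = None
    prev_index = None
    for rec in frame.itertuples(index=False):
        idx = int(rec.event_index)
        date = pd.Timestamp(rec.date).date()
        if prev_index is None or idx <= prev_index:
            if current:
                rows.append(PeakRow(*current[:3], tuple(current[3])))
            current = [rec.species, rec.transplant, rec.plot, [date]]
        else:
            current[3].append(date)
        prev_index = idx
    if current:
        rows.append(PeakRow(*current[:3], tuple(current[3])))
    return PeakTable(rows=tuple(rows))


def peak_table_to_frame(table: PeakTable) -> pd.DataFrame:
    recs = [
        {
            "species": row.species,
            "transplant": row.transplant,
            "plot": row.plot,
            "event_index": i,
            "date": d.isoformat(),
        }
        for row in table.rows
        for i, d in enumerate(row.event_dates)
    ]
    return pd.DataFrame.from_records(recs)
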