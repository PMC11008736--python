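"""CSV/JSON readers and writers for the pipeline's exchange formats.

Temperature CSV: ``timestamp`` (ISO 8601), ``height_m``, ``temp_c``;
10-minute or hourly cadence is auto-detected and 10-minute records are
averaged into the clock hour they fall in (labelled by hour start).
Gaps of up to 3 h are filled by linear interpolation; longer gaps are an
error rather than silently invented data.

Count CSV: ``date``, ``species``, ``plot``, ``count_adult``,
``count_nymph``.  Peak-table CSV: see :mod:`ricephen.observed`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import HeightEvaluation, evaluations_to_frame
from .observed import CountSeries, PeakTable, peak_table_from_frame, peak_table_to_frame
from .series import TemperatureSeries

MAX_GAP_HOURS = 3


class SchemaError(ValueError):
    """A file does not match the expected CSV schema."""


def _require_columns(frame: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(frame.columns)
    if missing:
        raise SchemaError(f"{what} missing columns: {sorted(missing)}")
    if frame.empty:
        raise SchemaError(f"{what} contains no data rows")


def _to_hourly(group: pd.DataFrame) -> pd.DataFrame:
    """Aggregate one height's records to a gap-filled hourly series."""
    g = group.sort_values("timestamp").set_index("timestamp")
    if len(g) > 1:
        step = g.index.to_series().diff().median()
        if step < pd.Timedelta(hours=1):
            g = g.resample("h").mean()
        else:
            g = g.resample("h").asfreq()
    vals = g["temp_c"]
    n_missing = int(vals.isna().sum())
    if n_missing:
        gap_runs = vals.isna().astype(int).groupby(vals.notna().cumsum()).sum()
        if int(gap_runs.max()) > MAX_GAP_HOURS:
            raise SchemaError(
                f"temperature gap longer than {MAX_GAP_HOURS} h at height "
                f"{group['height_m'].iloc[0]} m"
            )
        vals = vals.interpolate(method="time", limit_area="inside")
        if vals.isna().any():
            raise SchemaError("temperature series starts or ends with missing values")
    return vals.reset_index()


def read_temperature_csv(path: str | Path) -> dict[float, TemperatureSeries]:
    """Read a (possibly 10-minute) temperature CSV into hourly series by height."""
    try:
        frame = pd.read_csv(path, parse_dates=["timestamp"])
    except ValueError as exc:
        raise SchemaError(f"malformed temperature CSV {path}: {exc}") from exc
    _require_columns(frame, {"timestamp", "height_m", "temp_c"}, f"temperature CSV {path}")
    if frame["timestamp"].isna().any():
        raise SchemaError(f"temperature CSV {path} has unparseable timestamps")
    out: dict[float, TemperatureSeries] = {}
    for height, group in frame.groupby("height_m"):
        hourly = _to_hourly(group)
        out[float(height)] = TemperatureSeries(
            height_m=float(height),
            timestamps=hourly["timestamp"].values,
            values=hourly["temp_c"].to_numpy(dtype=float),
        )
    return out


def write_temperature_csv(
    series: dict[float, TemperatureSeries] | TemperatureSeries, path: str | Path
) -> None:
    if isinstance(series, TemperatureSeries):
        series = {series.height_m: series}
    frames = [
        pd.DataFrame(
            {
                "timestamp": s.timestamps,
                "height_m": s.height_m,
                "temp_c": np.round(s.values, 4),
            }
        )
        for s in series.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_peak_table_csv(path: str | Path) -> PeakTable:
    try:
        frame = pd.read_csv(path)
        return peak_table_from_frame(frame)
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"bad peak-table CSV {path}: {exc}") from exc


def write_peak_table_csv(table: PeakTable, path: str | Path) -> None:
    peak_table_to_frame(table).to_csv(path, index=False)


def read_count_series_csv(path: str | Path) -> list[CountSeries]:
    try:
        frame = pd.read_csv(path, parse_dates=["date"])
    except ValueError as exc:
        raise SchemaError(f"malformed count CSV {path}: {exc}") from exc
    _require_columns(
        frame, {"date", "species", "plot", "count_adult", "count_nymph"},
        f"count CSV {path}",
    )
    out = []
    for (species, plot), grp in frame.groupby(["species", "plot"]):
        g = grp.sort_values("date")
        out.append(
            CountSeries(
                species=str(species),
                plot=str(plot),
                survey_dates=tuple(d.date() for d in g["date"]),
                counts=g["count_adult"].to_numpy(dtype=float),
                counts_nymph=g["count_nymph"].to_numpy(dtype=float),
            )
        )
    return out


def write_count_series_csv(series: list[CountSeries] | CountSeries, path: str | Path) -> None:
    if isinstance(series, CountSeries):
        series = [series]
    frames = [
        pd.DataFrame(
            {
                "date": [d.isoformat() for d in s.survey_dates],
                "species": s.species,
                "plot": s.plot,
                "count_adult": np.round(s.counts, 4),
                "count_nymph": np.round(
                    s.counts_nymph if s.counts_nymph is not None
                    else np.zeros(len(s.survey_dates)),
                    4,
                ),
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metrics_json(evals: list[HeightEvaluation], path: str | Path) -> None:
    frame = evaluations_to_frame(evals)
    Path(path).write_text(json.dumps(frame.to_dict(orient="records"), indent=2) + "\n")


def write_metrics_csv(evals: list[HeightEvaluation], path: str | Path) -> None:
    evaluations_to_frame(evals).to_csv(path, index=False)
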