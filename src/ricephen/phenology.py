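"""Piecewise-linear degree-day development model and hourly accumulation engine.

The development rate R (per day) of a stage at temperature T is

    R = (T - t_min) / k          for t_min <= T < t_upper
      = (t_upper - t_min) / k    for t_upper <= T < t_stop   (plateau)
      = 0                        for T < t_min or T >= t_stop

A stage completes when the hourly integral of R reaches 1; a generation is
the chain preoviposition -> egg -> nymph, each stage starting at the
previous stage's completion instant.  Completion is resolved sub-hourly by
linear interpolation inside the crossing hour, so durations are fractional
days and agree with the constant-temperature closed form K/(T - t_min) to
well under one hourly step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import GENERATION_STAGE_ORDER, SpeciesModel, StageParams
from .series import HOUR, TemperatureSeries

NS_PER_HOUR = 3_600_000_000_000


class SeriesExhaustedError(RuntimeError):
    """The temperature series ended before development completed."""


def development_rate(t, params: StageParams):
    """Development rate (day^-1) at temperature ``t`` (deg C); vectorized.

    Total on real inputs: temperatures outside the developmental window
    simply yield rate 0.
    """
    t = np.asarray(t, dtype=float)
    linear = (t - params.t_min) / params.k
    plateau = (params.t_upper - params.t_min) / params.k
    rate = np.where(t < params.t_upper, linear, plateau)
    rate = np.where((t < params.t_min) | (t >= params.t_stop), 0.0, rate)
    return rate if rate.ndim else float(rate)


@dataclass(frozen=True)
class StageResult:
    """Outcome of accumulating one stage over a temperature series."""

    stage_name: str
    start_time: pd.Timestamp
    completion_time: pd.Timestamp | None  # None if the series ran out first
    trace_times: np.ndarray  # hour boundaries from the start onward
    cumulative_r_trace: np.ndarray  # cumulative R at those boundaries

    @property
    def completed(self) -> bool:
        return self.completion_time is not None

    @property
    def duration_days(self) -> float:
        if self.completion_time is None:
            raise SeriesExhaustedError(
                f"stage {self.stage_name!r} did not complete before the series ended"
            )
        return (self.completion_time - self.start_time) / pd.Timedelta(days=1)


def _hourly_cumulative(series: TemperatureSeries, params: StageParams) -> np.ndarray:
    """Cumulative development at each hour boundary; c[i] is at timestamps[i],
    with one extra entry for the end of the final hour."""
    rates = development_rate(series.values, params) / 24.0
    c = np.empty(rates.size + 1)
    c[0] = 0.0
    np.cumsum(rates, out=c[1:])
    return c


def _locate(series: TemperatureSeries, instant: np.datetime64) -> tuple[int, float]:
    """Index of the hour containing ``instant`` and the fraction elapsed in it."""
    offset_ns = (instant - series.start).astype("timedelta64[ns]").astype(np.int64)
    idx, frac_ns = divmod(offset_ns, NS_PER_HOUR)
    idx = int(idx)
    if idx == len(series) and frac_ns == 0:  # exactly at end of coverage
        idx, frac_ns = idx - 1, NS_PER_HOUR
    return idx, frac_ns / NS_PER_HOUR


def _advance(
    series: TemperatureSeries, c: np.ndarray, start: np.datetime64
) -> np.datetime64 | None:
    """First instant at which cumulative R since ``start`` reaches 1, or None."""
    i0, frac = _locate(series, start)
    rate0 = c[i0 + 1] - c[i0]
    c_start = c[i0] + rate0 * frac
    target = c_start + 1.0
    if c[-1] < target:
        return None
    j = int(np.searchsorted(c, target, side="left"))  # c[j] >= target, c[j-1] < target
    hour_rate = c[j] - c[j - 1]
    inner = (target - c[j - 1]) / hour_rate  # hour_rate > 0 at a crossing
    frac_ns = int(round(inner * NS_PER_HOUR))
    return series.timestamps[j - 1] + np.timedelta64(frac_ns, "ns")


def accumulate_stage(
    series: TemperatureSeries, params: StageParams, start_time
) -> StageResult:
    """Accumulate one stage's development hour by hour from ``start_time``.

    Each hourly record contributes ``development_rate(T_h) / 24`` to the
    cumulative development R.  The stage completes at the first instant R
    reaches 1, interpolated linearly within the crossing hour.  If the
    series ends first the result is marked incomplete (its
    ``completion_time`` is None); an out-of-coverage start raises
    ``ValueError`` — a distinct condition from exhaustion.
    """
    start = np.datetime64(pd.Timestamp(start_time))
    if not series.covers(start) or start == series.end:
        raise ValueError(
            f"start_time {start} outside series coverage [{series.start}, {series.end})"
        )
    c = _hourly_cumulative(series, params)
    i0, frac = _locate(series, start)
    c_start = c[i0] + (c[i0 + 1] - c[i0]) * frac
    completion = _advance(series, c, start)

    trace_times = np.concatenate(
        [series.timestamps[i0 + 1 :], [series.timestamps[-1] + HOUR]]
    )
    trace = np.maximum(c[i0 + 1 :] - c_start, 0.0)
    return StageResult(
        stage_name=params.stage_name,
        start_time=pd.Timestamp(start),
        completion_time=None if completion is None else pd.Timestamp(completion),
        trace_times=trace_times,
        cumulative_r_trace=trace,
    )


def predict_generation_period(
    series: TemperatureSeries,
    model: SpeciesModel,
    start_time,
    stage_order: tuple[str, ...] = GENERATION_STAGE_ORDER,
) -> float:
    """Predicted length (fractional days) of one generation from ``start_time``.

    Chains the stages in ``stage_order`` (default preoviposition -> egg ->
    nymph), each starting at the previous stage's completion instant.
    Raises :class:`SeriesExhaustedError` if any stage is still incomplete
    when the series ends.
    """
    start = np.datetime64(pd.Timestamp(start_time))
    if not series.covers(start) or start == series.end:
        raise ValueError(
            f"start_time {start} outside series coverage [{series.start}, {series.end})"
        )
    t = start
    for params in model.generation_stages(stage_order):
        c = _hourly_cumulative(series, params)
        t_next = _advance(series, c, t)
        if t_next is None:
            raise SeriesExhaustedError(
                f"{model.species_name}: series ended during the "
                f"{params.stage_name} stage (started {pd.Timestamp(t)})"
            )
        t = t_next
    return float((t - start).astype("timedelta64[ns]").astype(np.int64)) / (
        NS_PER_HOUR * 24
    )


def predict_generation_periods(
    series: TemperatureSeries,
    model: SpeciesModel,
    start_times,
    stage_order: tuple[str, ...] = GENERATION_STAGE_ORDER,
) -> list[float | None]:
    """Batch variant of :func:`predict_generation_period`.

    Computes each stage's cumulative-development table once and reuses it
    for every start; starts whose chain is incomplete map to None instead
    of raising.
    """
    tables = [
        _hourly_cumulative(series, p) for p in model.generation_stages(stage_order)
    ]
    out: list[float | None] = []
    for s in start_times:
        t = np.datetime64(pd.Timestamp(s))
        if not series.covers(t) or t == series.end:
            raise ValueError(f"start_time {t} outside series coverage")
        for c in tables:
            t = _advance(series, c, t)
            if t is None:
                break
        if t is None:
            out.append(None)
        else:
            start = np.datetime64(pd.Timestamp(s))
            out.append(
                float((t - start).astype("timedelta64[ns]").astype(np.int64))
                / (NS_PER_HOUR * 24)
            )
    return out


def closed_form_constant_period(t: float, model: SpeciesModel) -> float:
    """Generation length (days) at a constant temperature, in closed form.

    For constant T each stage lasts K / (min(T, t_upper) - t_min) days, so
    the generation is the sum over stages.  Serves as the analytic oracle
    for the hourly accumulation engine.  Valid only for T strictly between
    the largest stage t_min and the smallest stage t_stop.
    """
    lo = max(p.t_min for p in model.stages)
    hi = min(p.t_stop for p in model.stages)
    if not (lo < t < hi):
        raise ValueError(
            f"constant temperature {t} outside the developmental band ({lo}, {hi})"
        )
    return sum(p.k / (min(t, p.t_upper) - p.t_min) for p in model.stages)
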