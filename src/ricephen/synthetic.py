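"""Seeded generators for canopy microclimate and planthopper count series.

The microclimate generator is phenomenological, not physical: each
height's hourly temperature is a height-specific daily-mean offset from
the 2.0 m reference, plus a damped diurnal sinusoid, a day/night
inversion term (inside the canopy the daytime deficit relative to 2.0 m
is smaller than the nighttime deficit), a centred seasonal trend, a
day-to-day weather anomaly shared across heights, and hourly Gaussian
noise.  Default offsets reproduce the daily-mean temperature profile
observed in the 2021 paddy study: relative to 25.8 deg C at 2.0 m, the
canopy is 0.7-1.4 deg C cooler in the normal plot and 1.0-2.2 deg C
cooler in the continuously-irrigated low-water-temperature plot, with
water (0.0 m) at -0.8 and -2.9 deg C respectively (a ~2.1 deg C
normal-minus-low water difference).

The population generator places one density pulse per generation at the
dates the degree-day model itself predicts by iterating from a start
date, renders each pulse as a Gaussian in time, samples it at twice-weekly
survey dates and applies mean-preserving lognormal count noise — so the
ground-truth generation intervals driving a synthetic survey are known
exactly.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .observed import CountSeries
from .params import SpeciesModel
from .phenology import SeriesExhaustedError, predict_generation_period
from .series import TemperatureSeries

DEFAULT_SEED = 20210730

CANOPY_HEIGHTS = (2.0, 1.0, 0.75, 0.5, 0.25)

# Daily-mean offsets (deg C) from the 2.0 m reference, by plot.
HEIGHT_MEAN_OFFSETS = {
    "normal": {2.0: 0.0, 1.0: -0.7, 0.75: -1.2, 0.5: -1.3, 0.25: -1.4},
    "low": {2.0: 0.0, 1.0: -1.0, 0.75: -1.5, 0.5: -1.9, 0.25: -2.2},
}
WATER_MEAN_OFFSETS = {"normal": -0.8, "low": -2.9}

# Fraction of the 2.0 m diurnal amplitude surviving at each height; the
# paddy canopy and the water beneath it buffer the diurnal cycle.
AMPLITUDE_DAMPING = {2.0: 1.0, 1.0: 0.65, 0.75: 0.55, 0.5: 0.45, 0.25: 0.40}


@dataclass(frozen=True)
class MicroclimateParams:
    """Parameters of the phenomenological multi-height temperature generator.

    ``base_mean`` is the 2.0 m daily-mean temperature (deg C) at
    ``trend_reference_date``; the linear ``seasonal_trend`` (deg C/day) is
    applied relative to that date so the calibration-window mean stays at
    ``base_mean``.  ``diurnal_amplitude`` is the half-range of the 2.0 m
    sinusoid (peak mid-afternoon).  ``night_inversion`` deepens the
    canopy's nighttime deficit and symmetrically relaxes its daytime
    deficit (mean-preserving).  ``weather_sd`` is the s.d. of the daily
    anomaly shared by all heights; ``noise_sd`` is per-hour sensor noise.
    """

    plot: str = "normal"
    season_start: dt.date = dt.date(2021, 7, 30)
    season_end: dt.date = dt.date(2021, 10, 20)
    base_mean: float = 25.8
    seasonal_trend: float = -0.06
    trend_reference_date: dt.date = dt.date(2021, 8, 30)
    diurnal_amplitude: float = 4.5
    height_mean_offsets: dict[float, float] = field(default_factory=dict)
    amplitude_damping: dict[float, float] = field(default_factory=dict)
    night_inversion: float = 1.0
    water_offset: float | None = None
    water_amplitude_damping: float = 0.35
    water_lag_hours: float = 3.0
    weather_sd: float = 1.5
    noise_sd: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.plot not in HEIGHT_MEAN_OFFSETS:
            raise ValueError(f"plot must be 'normal' or 'low', got {self.plot!r}")
        if not self.height_mean_offsets:
            object.__setattr__(
                self, "height_mean_offsets", dict(HEIGHT_MEAN_OFFSETS[self.plot])
            )
        if not self.amplitude_damping:
            object.__setattr__(self, "amplitude_damping", dict(AMPLITUDE_DAMPING))
        if self.water_offset is None:
            object.__setattr__(self, "water_offset", WATER_MEAN_OFFSETS[self.plot])
        if self.season_end <= self.season_start:
            raise ValueError("season_end must follow season_start")
        if self.noise_sd < 0 or self.weather_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        offs = [self.height_mean_offsets[h] for h in sorted(self.height_mean_offsets)]
        if any(b < a - 1e-9 for a, b in zip(offs, offs[1:])):
            raise ValueError("height mean offsets must not decrease with height")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the synthetic sticky-board survey generator."""

    species: str = "N_lugens"
    plot: str = "normal"
    start_date: dt.date = dt.date(2021, 7, 30)
    n_generations: int = 2
    peak_height: float = 20.0  # adults per hill at a generation peak
    peak_width_days: float = 5.0  # s.d. of the Gaussian pulse
    survey_interval_days: float = 3.5  # twice-weekly surveys
    observation_noise: float = 0.3  # per-board lognormal sigma; count CV ~ 30%
    n_replicates: int = 3  # sticky boards averaged per survey, as in the field
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_generations", "peak_height", "peak_width_days",
                     "survey_interval_days", "n_replicates"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.observation_noise < 0:
            raise ValueError("observation_noise must be nonnegative")


def _hour_grid(params: MicroclimateParams) -> pd.DatetimeIndex:
    n_days = (params.season_end - params.season_start).days + 1
    return pd.date_range(params.season_start, periods=n_days * 24, freq="h")


def _deterministic_profile(
    params: MicroclimateParams,
    index: pd.DatetimeIndex,
    mean_offset: float,
    damping: float,
    inversion: float,
    lag_hours: float = 0.0,
) -> np.ndarray:
    day_offset = (index.normalize() - pd.Timestamp(params.trend_reference_date)).days
    hod = index.hour.to_numpy(dtype=float)
    diurnal = params.diurnal_amplitude * damping * np.sin(
        2 * np.pi * (hod - lag_hours - 9.0) / 24.0
    )
    # +inv/2 by day (06-18 h), -inv/2 by night: mean-preserving over 24 h
    day_mask = (hod >= 6) & (hod < 18)
    inv = inversion * np.where(day_mask, 0.5, -0.5)
    return (
        params.base_mean
        + params.seasonal_trend * day_offset.to_numpy(dtype=float)
        + mean_offset
        + diurnal
        + inv
    )


def _weather_anomaly(params: MicroclimateParams, n_days: int) -> np.ndarray:
    """Day-to-day anomaly shared across heights, mean-zero over the season
    (the seasonal norm is carried by base_mean and the trend)."""
    rng = np.random.default_rng([params.seed, 101])
    daily = rng.normal(0.0, params.weather_sd, n_days)
    if n_days > 1:
        daily = daily - daily.mean()
    return np.repeat(daily, 24)


def generate_canopy_series(
    params: MicroclimateParams,
) -> dict[float, TemperatureSeries]:
    """Hourly air-temperature series at 2.0, 1.0, 0.75, 0.5 and 0.25 m."""
    index = _hour_grid(params)
    weather = _weather_anomaly(params, index.size // 24)
    out: dict[float, TemperatureSeries] = {}
    for i, h in enumerate(CANOPY_HEIGHTS):
        rng = np.random.default_rng([params.seed, 202, i])
        base = _deterministic_profile(
            params,
            index,
            mean_offset=params.height_mean_offsets[h],
            damping=params.amplitude_damping[h],
            inversion=params.night_inversion if h < 2.0 else 0.0,
        )
        vals = base + weather + rng.normal(0.0, params.noise_sd, index.size)
        out[h] = TemperatureSeries(height_m=h, timestamps=index.values, values=vals)
    return out


def generate_water_series(
    params: MicroclimateParams, plot: str | None = None
) -> TemperatureSeries:
    """Hourly water temperature (height 0.0 m): a damped, lagged diurnal
    cycle around the plot's water daily mean."""
    if plot is not None and plot != params.plot:
        params = replace(
            params, plot=plot, height_mean_offsets={}, water_offset=None
        )
    index = _hour_grid(params)
    weather = _weather_anomaly(params, index.size // 24)
    rng = np.random.default_rng([params.seed, 303])
    base = _deterministic_profile(
        params,
        index,
        mean_offset=float(params.water_offset),
        damping=params.water_amplitude_damping,
        inversion=0.0,
        lag_hours=params.water_lag_hours,
    )
    vals = base + weather + rng.normal(0.0, params.noise_sd, index.size)
    return TemperatureSeries(height_m=0.0, timestamps=index.values, values=vals)


def generate_plot_series(params: MicroclimateParams) -> dict[float, TemperatureSeries]:
    """All six series of one plot: canopy heights plus water at 0.0 m."""
    series = generate_canopy_series(params)
    series[0.0] = generate_water_series(params)
    return series


@dataclass(frozen=True)
class PopulationSample:
    """A synthetic survey with its generating ground truth."""

    counts: CountSeries
    true_peak_times: tuple[pd.Timestamp, ...]  # fractional instants
    complete: bool  # False if the series ran out before n_generations

    @property
    def true_peak_dates(self) -> tuple[dt.date, ...]:
        return tuple(t.date() for t in self.true_peak_times)


def generate_population_series(
    temps: TemperatureSeries,
    model: SpeciesModel,
    params: PopulationParams,
) -> PopulationSample:
    """Sticky-board-style counts with generation peaks placed by the model.

    Peak instants are obtained by iterating the generation predictor from
    ``start_date``; each peak becomes a Gaussian density pulse sampled at
    the survey dates with mean-preserving lognormal noise.
    """
    start = pd.Timestamp(params.start_date)
    peaks: list[pd.Timestamp] = []
    complete = True
    t = start
    for _ in range(params.n_generations):
        try:
            period = predict_generation_period(temps, model, t)
        except (SeriesExhaustedError, ValueError):
            complete = False
            break
        t = t + pd.Timedelta(days=period)
        peaks.append(t)

    season_end = pd.Timestamp(temps.end)
    n_surveys = int(
        np.floor((season_end - start) / pd.Timedelta(days=params.survey_interval_days))
    ) + 1
    day_offsets = np.round(np.arange(n_surveys) * params.survey_interval_days)
    survey_times = start + pd.to_timedelta(day_offsets, unit="D")
    survey_dates = tuple(ts.date() for ts in survey_times)

    tdays = day_offsets.astype(float)
    signal = np.zeros_like(tdays)
    for pk in peaks:
        center = (pk - start) / pd.Timedelta(days=1)
        signal += params.peak_height * np.exp(
            -0.5 * ((tdays - center) / params.peak_width_days) ** 2
        )
    rng = np.random.default_rng([params.seed, 404])
    sigma = params.observation_noise
    if sigma > 0:
        # each survey is the mean of n_replicates noisy boards, as in the
        # field protocol; mean-preserving lognormal per board
        noise = rng.lognormal(
            mean=-0.5 * sigma**2, sigma=sigma, size=(params.n_replicates, tdays.size)
        ).mean(axis=0)
        counts = signal * noise
    else:
        counts = signal

    return PopulationSample(
        counts=CountSeries(
            species=params.species,
            plot=params.plot,
            survey_dates=survey_dates,
            counts=counts,
        ),
        true_peak_times=tuple(peaks),
        complete=complete,
    )
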