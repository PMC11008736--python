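"""Hourly temperature series tagged by sensor height."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOUR = np.timedelta64(1, "h")


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly temperatures (deg C) at one height above the paddy surface.

    ``height_m`` 0.0 denotes water temperature; 0.25-1.0 m are inside the
    rice canopy and 2.0 m is the reference height.  Timestamps are
    timezone-naive local time, strictly increasing and equally spaced at
    one hour; values must be gap-free (see :mod:`ricephen.io` for
    aggregation and gap filling of raw logger files).
    """

    height_m: float
    timestamps: np.ndarray  # datetime64[ns], hourly
    values: np.ndarray  # float64, deg C

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype="datetime64[ns]")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if not (0.0 <= self.height_m <= 2.0):
            raise ValueError(f"height_m must be in [0, 2] m, got {self.height_m}")
        if ts.ndim != 1 or vals.shape != ts.shape or ts.size == 0:
            raise ValueError("timestamps and values must be equal-length 1-d arrays")
        steps = np.diff(ts)
        if ts.size > 1 and not np.all(steps == HOUR):
            raise ValueError("timestamps must be strictly increasing at 1 h spacing")
        if np.isnan(vals).any():
            raise ValueError("temperature values contain NaN; gap-fill first")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def start(self) -> np.datetime64:
        return self.timestamps[0]

    @property
    def end(self) -> np.datetime64:
        """End of coverage: the final hourly record covers one full hour."""
        return self.timestamps[-1] + HOUR

    def covers(self, instant) -> bool:
        t = np.datetime64(pd.Timestamp(instant))
        return bool(self.start <= t <= self.end)

    def daily_mean(self) -> pd.Series:
        """Daily mean temperature indexed by calendar date."""
        s = pd.Series(self.values, index=pd.DatetimeIndex(self.timestamps))
        return s.resample("D").mean()

    @classmethod
    def constant(
        cls,
        temp_c: float,
        n_hours: int,
        start="2021-07-30",
        height_m: float = 2.0,
    ) -> "TemperatureSeries":
        """A constant-temperature series, mainly for oracle tests."""
        ts = pd.date_range(start, periods=n_hours, freq="h").values
        return cls(height_m=height_m, timestamps=ts, values=np.full(n_hours, float(temp_c)))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, height_m: float) -> "TemperatureSeries":
        """Build from a frame with ``timestamp`` and ``temp_c`` columns."""
        f = frame.sort_values("timestamp")
        return cls(
            height_m=height_m,
            timestamps=f["timestamp"].values,
            values=f["temp_c"].to_numpy(dtype=float),
        )
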