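"""Temperature series driving rate summation.

A :class:`TemperatureSeries` is an ordered sequence of (hour, degree C)
samples.  Constructors cover the three cases used in practice: a constant
temperature, a sinusoidal daily cycle between the daily minimum and
maximum, and logged records read from delimited text (timestamp, degree C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemperatureSeries", "make_sine_series"]


@dataclass(frozen=True)
class TemperatureSeries:
    """Time-stamped temperatures, hours from the series origin."""

    times_h: np.ndarray
    temps: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        x = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "temps", x)
        if t.ndim != 1 or t.shape != x.shape or len(t) < 2:
            raise ValueError("need matching 1-d arrays with at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(dt > 24.0):
            raise ValueError("sampling step must not exceed 24 h")
        if not np.all(np.isfinite(x)):
            raise ValueError("temperatures must be finite")

    @property
    def duration_days(self) -> float:
        return float(self.times_h[-1] - self.times_h[0]) / 24.0

    @classmethod
    def constant(cls, temp: float, days: float, step_hours: float = 24.0) -> "TemperatureSeries":
        n = int(np.ceil(days * 24.0 / step_hours)) + 1
        t = np.arange(n) * step_hours
        return cls(t, np.full(n, float(temp)))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureSeries":
        """Build from a two-column table (timestamp, temperature)."""
        ts = pd.to_datetime(df.iloc[:, 0])
        hours = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
        return cls(hours, df.iloc[:, 1].to_numpy(dtype=float))

    @classmethod
    def read_csv(cls, path) -> "TemperatureSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self, origin: str = "2000-01-01") -> pd.DataFrame:
        ts = pd.Timestamp(origin) + pd.to_timedelta(self.times_h, unit="h")
        return pd.DataFrame({"timestamp": ts, "temp_c": self.temps})


def make_sine_series(
    mean: float, amplitude: float, days: float, step_hours: float = 1.0
) -> TemperatureSeries:
    """Sinusoidal daily temperature cycle spanning ``mean +/- amplitude``.

    The coldest hour is at t = 0 (night) and the warmest 12 h later; any
    ``step_hours`` that divides 24 samples the cycle so that the daily
    minimum, maximum and mean are hit exactly.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if step_hours <= 0 or (24.0 / step_hours) % 1 != 0:
        raise ValueError("step_hours must be positive and divide 24")
    n = int(round(days * 24.0 / step_hours)) + 1
    t = np.arange(n) * step_hours
    temps = mean - amplitude * np.cos(2.0 * np.pi * t / 24.0)
    return TemperatureSeries(t, temps)
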