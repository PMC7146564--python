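"""Shared time-series containers and interval-fraction arithmetic.

Two containers carry all sensor data through the pipeline:

* :class:`SensorSeries` — a uniformly sampled scalar series (temperature,
  relative humidity, gas concentration, or a derived per-second statistic)
  with missing values kept as NaN, never silently dropped.
* :class:`AccelStream` — a tri-axial accelerometer log in g units with an
  explicit measurable range (the wristband rails, -8.00 g to +7.98 g).

On top of them sit the three kernels every phase KPI reuses: the Euclidean
acceleration module, the per-second maximum of the module, and the
fraction of time a series spends inside a value band.  Under uniform
sampling the fraction of samples equals the fraction of time, which is the
convention used for every "% of time" KPI; irregular series are first
regularised onto their nominal grid, carrying the last value across gaps
of at most twice the sample period and flagging longer gaps as missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidInputError

logger = logging.getLogger(__name__)

#: Units accepted on a SensorSeries.
VALID_UNITS = ("degC", "%RH", "g", "ppm")


class Percentage(float):
    """A float constrained to [0, 100]; the return type of every fraction KPI."""

    def __new__(cls, value: float):
        v = float(value)
        if not (0.0 <= v <= 100.0) or math.isnan(v):
            raise InvalidInputError(f"percentage outside [0, 100]: {value!r}")
        return super().__new__(cls, v)


@dataclass(frozen=True)
class SensorSeries:
    """Time-stamped scalar measurements on a nominally uniform grid.

    Parameters
    ----------
    timestamps
        Strictly increasing epoch seconds (float, seconds resolution or finer).
    values
        Measurements; NaN marks an explicitly missing sample.
    unit
        One of ``degC``, ``%RH``, ``g``, ``ppm``.
    sample_period
        Nominal spacing between samples in seconds (> 0).
    """

    timestamps: np.ndarray
    values: np.ndarray
    unit: str
    sample_period: float

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if ts.ndim != 1 or vals.ndim != 1 or len(ts) != len(vals):
            raise InvalidInputError("timestamps and values must be 1-D and equally long")
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(ts)):
            raise InvalidInputError("timestamps must be finite")
        if self.unit not in VALID_UNITS:
            raise InvalidInputError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not (self.sample_period > 0):
            raise InvalidInputError("sample_period must be > 0")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        """Values with flagged-missing samples removed."""
        return self.values[~self.missing_mask]

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if len(self) < 2:
            return True
        return bool(np.allclose(np.diff(self.timestamps), self.sample_period,
                                rtol=rtol, atol=1e-9))

    def to_frame(self) -> pd.DataFrame:
        stamps = pd.to_datetime(self.timestamps, unit="s", utc=True)
        return pd.DataFrame({"timestamp": stamps, "value": self.values, "unit": self.unit})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_period: float | None = None) -> "SensorSeries":
        df = pd.read_csv(path)
        for col in ("timestamp", "value", "unit"):
            if col not in df.columns:
                from .errors import SchemaError
                raise SchemaError(f"series CSV missing column {col!r}", column=col)
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        epoch = ts.astype("int64").to_numpy() / 1e9
        units = df["unit"].unique()
        if len(units) != 1:
            raise InvalidInputError(f"series CSV mixes units: {sorted(units)}")
        if sample_period is None:
            diffs = np.diff(epoch)
            sample_period = float(np.median(diffs)) if len(diffs) else 1.0
        return cls(epoch, df["value"].to_numpy(float), str(units[0]), sample_period)


def regularize(series: SensorSeries, max_gap_periods: float = 2.0) -> SensorSeries:
    """Resample an irregular series onto its nominal uniform grid.

    Values are carried forward across gaps no longer than
    ``max_gap_periods * sample_period``; grid points beyond a longer gap
    become missing (NaN).  A series already on its grid is returned as-is.
    """
    if len(series) == 0 or series.is_uniform():
        return series
    p = series.sample_period
    ts = series.timestamps
    grid = ts[0] + p * np.arange(int(np.floor((ts[-1] - ts[0]) / p)) + 1)
    idx = np.searchsorted(ts, grid + 1e-9, side="right") - 1  # last sample at/before grid point
    gap = grid - ts[idx]
    vals = series.values[idx].copy()
    vals[gap > max_gap_periods * p] = np.nan
    n_gap = int(np.sum(gap > max_gap_periods * p))
    if n_gap:
        logger.info("regularize: %d grid points beyond %.1f periods flagged missing",
                    n_gap, max_gap_periods)
    return SensorSeries(grid, vals, series.unit, p)


@dataclass(frozen=True)
class Band:
    """A real interval with configurable endpoint closure.

    ``closed`` is one of ``both``, ``left``, ``right``, ``neither`` and says
    which finite endpoints belong to the band.
    """

    lower: float = -math.inf
    upper: float = math.inf
    closed: str = "both"

    def __post_init__(self):
        if self.closed not in ("both", "left", "right", "neither"):
            raise InvalidInputError(f"bad closure {self.closed!r}")
        if self.lower > self.upper:
            raise InvalidInputError("band lower bound exceeds upper bound")

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = x >= self.lower if self.closed in ("both", "left") else x > self.lower
        hi = x <= self.upper if self.closed in ("both", "right") else x < self.upper
        return lo & hi


def fraction_of_time(series: SensorSeries, band: Band) -> Percentage:
    """Percentage of (non-missing) time the series spends inside ``band``.

    Under uniform sampling the sample-count fraction equals the time
    fraction; missing samples are excluded from numerator and denominator
    so sensor outages do not bias the KPI.  An empty series raises
    :class:`EmptyInputError` — the KPI is undefined, not zero.
    """
    series = regularize(series)
    vals = series.valid_values()
    if len(vals) == 0:
        raise EmptyInputError("fraction_of_time on a series with no valid samples")
    return Percentage(100.0 * np.count_nonzero(band.contains(vals)) / len(vals))


@dataclass(frozen=True)
class AccelStream:
    """Tri-axial accelerometer log in g units.

    The default measurable range matches the logging wristband used during
    loading: -8.00 g is the lowest representable value and +7.98 g the
    highest; a raw sample pinned at either rail is the footprint left by
    clipping ("saturation").
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float
    range_low: float = -8.00
    range_high: float = 7.98

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        for name in ("ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if len(arr) != len(ts):
                raise InvalidInputError(f"{name} length differs from timestamps")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite samples")
            if np.any(arr < self.range_low) or np.any(arr > self.range_high):
                raise InvalidInputError(
                    f"{name} outside measurable range [{self.range_low}, {self.range_high}] g")
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise InvalidInputError("timestamps must be strictly increasing")
        if not (self.sample_rate > 0):
            raise InvalidInputError("sample_rate must be > 0")
        if not (self.range_low < self.range_high):
            raise InvalidInputError("range_low must be below range_high")

    def __len__(self) -> int:
        return len(self.timestamps)

    def module(self) -> np.ndarray:
        """Per-sample acceleration module ``sqrt(ax^2 + ay^2 + az^2)``."""
        return np.sqrt(self.ax ** 2 + self.ay ** 2 + self.az ** 2)

    def to_csv(self, path) -> None:
        stamps = pd.to_datetime(self.timestamps, unit="s", utc=True)
        df = pd.DataFrame({
            "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
            "ax": self.ax, "ay": self.ay, "az": self.az,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None,
                 range_low: float = -8.00, range_high: float = 7.98) -> "AccelStream":
        df = pd.read_csv(path)
        for col in ("timestamp", "ax", "ay", "az"):
            if col not in df.columns:
                from .errors import SchemaError
                raise SchemaError(f"accelerometer CSV missing column {col!r}", column=col)
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        epoch = ts.astype("int64").to_numpy() / 1e9
        if sample_rate is None:
            diffs = np.diff(epoch)
            sample_rate = 1.0 / float(np.median(diffs)) if len(diffs) else 1.0
        return cls(epoch, df["ax"].to_numpy(float), df["ay"].to_numpy(float),
                   df["az"].to_numpy(float), sample_rate,
                   range_low=range_low, range_high=range_high)


def accel_module(ax: float, ay: float, az: float) -> float:
    """Euclidean norm of the three axis accelerations, in g.

    Scalar form of :meth:`AccelStream.module`; always non-negative.
    """
    for v in (ax, ay, az):
        if not math.isfinite(v):
            raise InvalidInputError(f"non-finite acceleration component: {v!r}")
    return math.sqrt(ax * ax + ay * ay + az * az)


def covered_seconds(timestamps: np.ndarray) -> np.ndarray:
    """Integer epoch seconds spanned by the stream, inclusive of both ends.

    Second boundaries are aligned to integer epoch seconds, half-open
    [s, s + 1), so grouping is deterministic and order-independent.
    """
    if len(timestamps) == 0:
        raise EmptyInputError("empty stream covers no seconds")
    first = int(np.floor(timestamps[0]))
    last = int(np.floor(timestamps[-1]))
    return np.arange(first, last + 1, dtype=np.int64)


def per_second_max_module(stream: AccelStream) -> SensorSeries:
    """Maximum acceleration module in each covered wall-clock second.

    Returns one value per second in the stream's span; seconds containing
    no samples are flagged missing (NaN).
    """
    if len(stream) == 0:
        raise EmptyInputError("per_second_max_module on an empty stream")
    secs = covered_seconds(stream.timestamps)
    idx = np.floor(stream.timestamps).astype(np.int64) - secs[0]
    out = np.full(len(secs), -np.inf)
    np.maximum.at(out, idx, stream.module())
    out[np.isinf(out)] = np.nan
    return SensorSeries(secs.astype(float), out, "g", 1.0)


def align(a: SensorSeries, b: SensorSeries, atol: float = 1e-6):
    """Check two series share a timestamp grid; raise AlignmentError otherwise."""
    from .errors import AlignmentError
    if len(a) != len(b) or not np.allclose(a.timestamps, b.timestamps, atol=atol):
        raise AlignmentError("series are not sampled on the same timestamps")
    return a, b


def with_values(series: SensorSeries, values: np.ndarray, unit: str | None = None) -> SensorSeries:
    """A copy of ``series`` with new values (and optionally a new unit)."""
    return replace(series, values=np.asarray(values, dtype=float),
                   unit=unit if unit is not None else series.unit)
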