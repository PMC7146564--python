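"""Transport-phase KPIs: thermal comfort and driving abruptness.

Four thermal KPIs give the fraction of journey time outside the flock's
comfort envelope: temperature above 31 degC or below 18 degC, relative
humidity above 80% or below 60% (all strict inequalities).

The fifth KPI, **Abrupt Movements**, scores the driver's abruptness from
the truck accelerometer.  The per-sample acceleration module is passed
through a smoothed z-score peak detector: a new point is signalled (+1 or
-1) when it lies strictly more than ``threshold`` moving standard
deviations away from the moving mean of the previous ``lag`` filtered
points.  Signalled points enter the filtered series with weight
``influence`` (0 = signals never move the detection threshold; 1 = no
smoothing of signals).  The KPI is the percentage of evaluated samples
(those after the warm-up window) carrying a non-zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AccelStream, Band, Percentage, SensorSeries, align, fraction_of_time
from .errors import ConfigurationError, EmptyInputError, InsufficientDataError

# comfort envelope during transport
HIGH_TEMP_C = 31.0
LOW_TEMP_C = 18.0
HIGH_RH_PCT = 80.0
LOW_RH_PCT = 60.0


@dataclass(frozen=True)
class ZPeakParams:
    """Configuration of the smoothed z-score peak detector.

    lag
        Size of the moving window (samples, >= 2): how much data is
        smoothed and how adaptive the detector is to long-term drift.
    threshold
        Z-score at which a point is signalled (> 0).
    influence
        Weight in [0, 1] of signalled points on the moving statistics.
    """

    lag: int = 25
    threshold: float = 5.0
    influence: float = 0.0

    def __post_init__(self):
        if int(self.lag) != self.lag or self.lag < 2:
            raise ConfigurationError("lag must be an integer >= 2")
        if not (self.threshold > 0):
            raise ConfigurationError("threshold must be > 0")
        if not (0.0 <= self.influence <= 1.0):
            raise ConfigurationError("influence must lie in [0, 1]")


@dataclass(frozen=True)
class ZPeakResult:
    """Detector output: three vectors, one entry per input sample.

    ``signals`` takes values -1/0/+1 (0 for the first ``lag`` warm-up
    samples); ``avg_filter`` and ``std_filter`` are the moving mean and
    (population) standard deviation of the filtered series, updated each
    time a new point is analysed.
    """

    signals: np.ndarray
    avg_filter: np.ndarray
    std_filter: np.ndarray


def zpeak(series, params: ZPeakParams | None = None) -> ZPeakResult:
    """Run the smoothed z-score peak detector over a 1-D series.

    The first ``lag`` samples seed the filtered series with the raw values
    and receive signal 0; from sample ``lag`` on, each point is compared
    against the mean/std of the trailing ``lag`` filtered points.  A tie at
    exactly ``threshold`` standard deviations is not a signal (strict
    inequality).  Deterministic: identical input and parameters give
    identical output.
    """
    params = params or ZPeakParams()
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ConfigurationError("zpeak expects a 1-D series")
    n = len(y)
    lag = int(params.lag)
    if n <= lag:
        raise InsufficientDataError(f"series length {n} must exceed lag {lag}")
    if not np.all(np.isfinite(y)):
        raise ConfigurationError("zpeak input must be finite")

    signals = np.zeros(n, dtype=np.int8)
    filtered = y.copy()
    avg_filter = np.empty(n)
    std_filter = np.empty(n)
    # warm-up: statistics of the seed window, held constant over it
    avg_filter[:lag] = np.mean(y[:lag])
    std_filter[:lag] = np.std(y[:lag])
    infl = float(params.influence)
    thr = float(params.threshold)
    for i in range(lag, n):
        prev_avg = avg_filter[i - 1]
        prev_std = std_filter[i - 1]
        if abs(y[i] - prev_avg) > thr * prev_std:
            signals[i] = 1 if y[i] > prev_avg else -1
            filtered[i] = infl * y[i] + (1.0 - infl) * filtered[i - 1]
        else:
            filtered[i] = y[i]
        window = filtered[i - lag + 1: i + 1]
        avg_filter[i] = window.mean()
        std_filter[i] = window.std()
    return ZPeakResult(signals, avg_filter, std_filter)


def abrupt_movements_kpi(stream: AccelStream, params: ZPeakParams | None = None) -> Percentage:
    """% of evaluated journey samples signalled as abrupt speed changes.

    The acceleration module is computed per sample and fed to the peak
    detector; the denominator excludes the ``lag`` warm-up samples, where
    signals are undefined.
    """
    params = params or ZPeakParams()
    result = zpeak(stream.module(), params)
    evaluated = result.signals[params.lag:]
    return Percentage(100.0 * np.count_nonzero(evaluated) / len(evaluated))


def thermal_comfort_kpis(temps: SensorSeries, rhs: SensorSeries) -> dict[str, Percentage]:
    """The four thermal-comfort time fractions for one journey."""
    if len(temps) == 0 or len(rhs) == 0:
        raise EmptyInputError("empty journey series")
    align(temps, rhs)
    return {
        "high_temperature": fraction_of_time(temps, Band(HIGH_TEMP_C, closed="neither")),
        "low_temperature": fraction_of_time(temps, Band(upper=LOW_TEMP_C, closed="neither")),
        "high_relative_humidity": fraction_of_time(rhs, Band(HIGH_RH_PCT, closed="neither")),
        "low_relative_humidity": fraction_of_time(rhs, Band(upper=LOW_RH_PCT, closed="neither")),
    }


def transport_kpis(temps: SensorSeries, rhs: SensorSeries, stream: AccelStream,
                   params: ZPeakParams | None = None) -> dict[str, Percentage]:
    """All five transport KPIs as a name -> value mapping."""
    kpis = thermal_comfort_kpis(temps, rhs)
    kpis["abrupt_movements"] = abrupt_movements_kpi(stream, params)
    return kpis
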