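"""Breeding-phase KPIs.

Five indicators summarise the rearing climate of a broiler flock:

* **Temperature Warning** — % of time the house temperature deviates
  between 1.5 and 3 degC (inclusive) from the farmer-set optimal profile.
* **Temperature Alarm** — % of time the deviation exceeds 3 degC.
* **Alert / Danger / Emergency Situation** — % of time the heat-stress
  index (HIS), a combined temperature-humidity score, falls in the bands
  [70, 76), [76, 81] and above 81 respectively.

The optimal temperature is a step function of time: farmers set discrete
setpoints per growth stage and may edit them mid-rearing, so no
interpolation is applied between segments.

The HIS source chart is published only as a figure, so the index itself
is pluggable: formulas register by id, and the default ``thi_default`` is
the classical livestock temperature-humidity index

    THI = 0.8 T + (RH / 100) (T - 14.4) + 46.4      (T in degC, RH in %)

which lands on the same 70-81 scale the stress bands use.  Any registered
formula must be monotonically non-decreasing in both temperature and
relative humidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import Band, Percentage, SensorSeries, align, fraction_of_time, regularize, with_values
from .errors import ConfigurationError, EmptyInputError, InvalidInputError

# deviation bands, in degC away from the optimal profile
WARNING_LOW = 1.5
WARNING_HIGH = 3.0   # inclusive: exactly 3 degC is still a warning, not an alarm


@dataclass(frozen=True)
class ComfortProfile:
    """Piecewise-constant optimal house temperature over the rearing period.

    ``segments`` is an ordered list of ``(start_epoch_seconds, optimal_degC)``
    pairs; each setpoint holds from its start until the next segment begins.
    """

    segments: tuple
    temp_limits: tuple = (10.0, 40.0)

    def __post_init__(self):
        segs = tuple((float(t), float(v)) for t, v in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ConfigurationError("comfort profile needs at least one segment")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError("profile segment starts must be strictly increasing")
        lo, hi = self.temp_limits
        for _, v in segs:
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"optimal temperature {v} degC outside sane range [{lo}, {hi}]")

    def optimal_at(self, timestamps) -> np.ndarray:
        """Setpoint active at each timestamp (step function)."""
        ts = np.asarray(timestamps, dtype=float)
        starts = np.array([t for t, _ in self.segments])
        temps = np.array([v for _, v in self.segments])
        idx = np.searchsorted(starts, ts, side="right") - 1
        if np.any(idx < 0):
            raise ConfigurationError("comfort profile does not cover the start of the series")
        return temps[idx]

    def to_csv(self, path) -> None:
        stamps = pd.to_datetime([t for t, _ in self.segments], unit="s", utc=True)
        pd.DataFrame({
            "start_timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "optimal_temp_c": [v for _, v in self.segments],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ComfortProfile":
        df = pd.read_csv(path)
        for col in ("start_timestamp", "optimal_temp_c"):
            if col not in df.columns:
                from .errors import SchemaError
                raise SchemaError(f"profile CSV missing column {col!r}", column=col)
        ts = pd.to_datetime(df["start_timestamp"], utc=True, format="ISO8601")
        epoch = ts.astype("int64").to_numpy() / 1e9
        return cls(tuple(zip(epoch, df["optimal_temp_c"].to_numpy(float))))


def _deviations(temps: SensorSeries, profile: ComfortProfile) -> np.ndarray:
    if temps.unit != "degC":
        raise InvalidInputError(f"temperature series must be in degC, got {temps.unit!r}")
    temps = regularize(temps)
    opt = profile.optimal_at(temps.timestamps)
    dev = np.abs(temps.values - opt)
    if np.all(np.isnan(dev)):
        raise EmptyInputError("no valid temperature samples")
    return dev[~np.isnan(dev)]


def temperature_warning_kpi(temps: SensorSeries, profile: ComfortProfile) -> Percentage:
    """% of time at mildly uncomfortable temperatures: 1.5 <= |T - opt| <= 3 degC."""
    dev = _deviations(temps, profile)
    inside = (dev >= WARNING_LOW) & (dev <= WARNING_HIGH)
    return Percentage(100.0 * np.count_nonzero(inside) / len(dev))


def temperature_alarm_kpi(temps: SensorSeries, profile: ComfortProfile) -> Percentage:
    """% of time at severely uncomfortable temperatures: |T - opt| > 3 degC."""
    dev = _deviations(temps, profile)
    return Percentage(100.0 * np.count_nonzero(dev > WARNING_HIGH) / len(dev))


# ---------------------------------------------------------------------------
# heat-stress index

def _thi(temp, rh):
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    return 0.8 * temp + (rh / 100.0) * (temp - 14.4) + 46.4


#: registry of HIS formulas; each maps (temp degC, rh %) -> index value and
#: must be monotone non-decreasing in both arguments.
HIS_FORMULAS: dict[str, Callable] = {"thi_default": _thi}


def register_his_formula(formula_id: str, fn: Callable) -> None:
    HIS_FORMULAS[formula_id] = fn


@dataclass(frozen=True)
class HisConfig:
    """Stress-band thresholds on the heat-stress index scale.

    Defaults: alert [70, 76), danger [76, 81], emergency above 81.  The
    published band wording leaves (75, 76) unassigned; the alert band is
    closed at 76 (exclusive) so the bands tile the scale without overlap.
    """

    formula_id: str = "thi_default"
    alert_band: tuple = (70.0, 76.0)     # [lo, hi)
    danger_band: tuple = (76.0, 81.0)    # [lo, hi]
    emergency_threshold: float = 81.0    # strictly above

    def __post_init__(self):
        a_lo, a_hi = self.alert_band
        d_lo, d_hi = self.danger_band
        if not (a_lo < a_hi <= d_lo < d_hi <= self.emergency_threshold):
            raise ConfigurationError("HIS bands must be ordered and non-overlapping")

    def formula(self) -> Callable:
        try:
            return HIS_FORMULAS[self.formula_id]
        except KeyError:
            raise ConfigurationError(f"unknown HIS formula id {self.formula_id!r}") from None


def his_value(temp: float, rh: float, config: HisConfig | None = None) -> float:
    """Heat-stress index for one (temperature, relative humidity) pair."""
    config = config or HisConfig()
    if not (0.0 <= rh <= 100.0):
        raise InvalidInputError(f"relative humidity outside [0, 100]: {rh!r}")
    return float(config.formula()(temp, rh))


def his_situation_kpis(temps: SensorSeries, rhs: SensorSeries,
                       config: HisConfig | None = None) -> dict[str, Percentage]:
    """Fractions of time in the alert, danger and emergency stress bands.

    The bands are disjoint, so the three fractions sum to at most 100%.
    Samples missing in either series are excluded from both.
    """
    config = config or HisConfig()
    temps, rhs = regularize(temps), regularize(rhs)
    align(temps, rhs)
    if temps.unit != "degC" or rhs.unit != "%RH":
        raise InvalidInputError("expected a degC series and a %RH series")
    his = config.formula()(temps.values, rhs.values)
    his = with_values(temps, np.where(np.isnan(rhs.values), np.nan, his))
    a_lo, a_hi = config.alert_band
    d_lo, d_hi = config.danger_band
    return {
        "alert": fraction_of_time(his, Band(a_lo, a_hi, closed="left")),
        "danger": fraction_of_time(his, Band(d_lo, d_hi, closed="both")),
        "emergency": fraction_of_time(his, Band(config.emergency_threshold, closed="neither")),
    }


def breeding_kpis(temps: SensorSeries, rhs: SensorSeries, profile: ComfortProfile,
                  config: HisConfig | None = None) -> dict[str, Percentage]:
    """All five breeding KPIs as a name -> value mapping."""
    his = his_situation_kpis(temps, rhs, config)
    return {
        "temperature_warning": temperature_warning_kpi(temps, profile),
        "temperature_alarm": temperature_alarm_kpi(temps, profile),
        "alert_situation": his["alert"],
        "danger_situation": his["danger"],
        "emergency_situation": his["emergency"],
    }
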