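"""Seeded generators for every input the KPI pipeline consumes.

No production-chain sensor data is publicly deposited, so the package
ships generators that emulate each phase's raw streams with *planted*
ground truth: the band fractions, saturation rates and rule structure a
scenario declares are the values the downstream KPIs must recover.

Construction style matters for testing:

* Band-occupancy KPIs (breeding deviation/stress bands, transport
  humidity) are built by **stratified exact allocation** — each sample is
  assigned a band, then jittered within it — so the realised fraction
  equals the planted fraction up to integer rounding and KPI unit tests
  are exact.  An i.i.d. mode is deliberately not the default; it would
  mix sampling noise into logic checks.
* Algorithm-mediated quantities (abrupt-movement detection, wristband
  minute statistics) are planted through the mechanism itself — inserted
  spike episodes, per-minute accumulation draws, Poisson rail pinning —
  and recovered approximately, within documented Monte-Carlo tolerance.

Every generator is a pure function of its scenario, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .advisor import AM, ES, HH, HT, LT, RuleSet, predict, reference_rule_set
from .breeding import ComfortProfile, HisConfig
from .core import AccelStream, SensorSeries
from .errors import ConfigurationError
from .transport import ZPeakParams

_EPOCH0 = 1_556_582_400.0  # 2019-04-30T00:00:00Z, a realistic rearing start


def _allocate_counts(n: int, fractions) -> list[int]:
    """Nearest-integer counts for percentage fractions of n samples.

    The fractions need not sum to 100; the unallocated complement is the
    caller's background band.  Counts are rounded half-up and trimmed if
    rounding pushed their sum past n.
    """
    if any(f < 0 for f in fractions) or sum(fractions) > 100.0 + 1e-9:
        raise ConfigurationError(f"planted fractions invalid: {fractions}")
    counts = [int(math.floor(n * f / 100.0 + 0.5)) for f in fractions]
    excess = sum(counts) - n
    order = sorted(range(len(counts)), key=lambda i: counts[i], reverse=True)
    for i in range(max(excess, 0)):
        counts[order[i % len(order)]] -= 1
    return counts


# ---------------------------------------------------------------------------
# breeding

def default_profile(start: float = _EPOCH0, duration_days: float = 49.0) -> ComfortProfile:
    """A three-stage setpoint profile stepping 30 -> 29 -> 28 degC.

    The absolute level is kept in the high twenties so that every stress
    band (including "no stress") is physically reachable from every
    deviation band; see docs/methods.md for the feasibility geometry.
    """
    third = duration_days * 86400.0 / 3.0
    return ComfortProfile(((start, 30.0), (start + third, 29.0), (start + 2 * third, 28.0)))


@dataclass(frozen=True)
class FarmScenario:
    """Planted ground truth for one rearing period.

    Fractions are percentages of samples: ``warning``/``alarm`` are the
    temperature-deviation bands, ``alert``/``danger``/``emergency`` the
    heat-stress bands.  ``warning + alarm <= 100`` and
    ``alert + danger + emergency <= 100``.
    """

    duration_days: float = 49.0
    sample_period: float = 30.0
    profile: ComfortProfile | None = None
    warning: float = 0.0
    alarm: float = 0.0
    alert: float = 0.0
    danger: float = 0.0
    emergency: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("warning", "alarm", "alert", "danger", "emergency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ConfigurationError(f"planted {name} outside [0, 100]: {v}")
        if self.warning + self.alarm > 100.0 + 1e-9:
            raise ConfigurationError("warning + alarm exceeds 100%")
        if self.alert + self.danger + self.emergency > 100.0 + 1e-9:
            raise ConfigurationError("alert + danger + emergency exceeds 100%")


_H_MARGIN = 0.05   # keep planted index values clear of band edges


def _his_band_geometry(band: str, config: HisConfig):
    """(H_lo, H_hi, T_lo, T_hi): target index interval and feasible temperatures.

    Under the default THI the index at RH 0 is ``0.8 T + 46.4`` and at
    RH 100 is ``1.8 T + 32``.  An index value h is reachable iff the two
    envelopes straddle it, giving ``T >= (h - 32)/1.8`` (from the RH-100
    ceiling) and ``T <= (h - 46.4)/0.8`` (from the RH-0 floor).  Deriving
    the temperature bounds from the *margined* index interval guarantees a
    non-empty index choice at any feasible temperature.
    """
    a_lo, a_hi = config.alert_band
    d_lo, d_hi = config.danger_band
    if band == "none":
        h_lo, h_hi = -np.inf, a_lo - _H_MARGIN
    elif band == "alert":
        h_lo, h_hi = a_lo, a_hi - _H_MARGIN        # [lo, hi) band
    elif band == "danger":
        h_lo, h_hi = d_lo, d_hi                    # closed band
    elif band == "emergency":
        h_lo, h_hi = config.emergency_threshold + _H_MARGIN, np.inf
    else:
        raise ConfigurationError(f"unknown stress band {band!r}")
    t_lo = (h_lo - 32.0) / 1.8 if np.isfinite(h_lo) else -np.inf
    t_hi = (h_hi - 46.4) / 0.8 if np.isfinite(h_hi) else np.inf
    return h_lo, h_hi, t_lo, t_hi


_DEV_MAGNITUDES = {  # |temperature - setpoint| interval per deviation band, degC
    "warning": (1.55, 2.95),     # inside the closed [1.5, 3] band with a float margin
    "alarm": (3.05, 6.0),
}


def _dev_candidates(dev_band: str, his_band: str):
    """Offset intervals realising a deviation band, cool side first when the
    stress band prefers cool temperatures (a cold alarm carries no heat
    stress; a hot alarm usually does)."""
    if dev_band == "comfortable":
        return [(-1.4, 1.4)]
    lo, hi = _DEV_MAGNITUDES[dev_band]
    warm, cool = (lo, hi), (-hi, -lo)
    return [cool, warm] if his_band in ("none", "alert") else [warm, cool]


def gen_farm_climate(scenario: FarmScenario,
                     config: HisConfig | None = None):
    """Temperature and relative-humidity series with exact planted fractions.

    Each sample receives a (deviation band, stress band) pair; the pairing
    is built by sorting both allocations by the temperature they require,
    so cool-needing stress bands meet cool deviation bands.  Temperature
    is drawn inside the intersection of the two constraints and humidity
    is solved from the target heat-stress index.  Infeasible combinations
    (e.g. more "no stress" time than cool-band time) raise
    :class:`ConfigurationError`.
    """
    config = config or HisConfig()
    if config.formula_id != "thi_default":
        raise ConfigurationError("the climate generator plants bands under thi_default")
    profile = scenario.profile or default_profile(duration_days=scenario.duration_days)
    n = int(scenario.duration_days * 86400.0 / scenario.sample_period)
    if n < 1:
        raise ConfigurationError("scenario spans no samples")
    rng = np.random.default_rng(scenario.seed)

    nw, na = _allocate_counts(n, (scenario.warning, scenario.alarm))[:2]
    dev_labels = (["comfortable"] * (n - nw - na) + ["warning"] * nw + ["alarm"] * na)
    n_alert, n_danger, n_emerg = _allocate_counts(
        n, (scenario.alert, scenario.danger, scenario.emergency))
    his_labels = (["none"] * (n - n_alert - n_danger - n_emerg)
                  + ["alert"] * n_alert + ["danger"] * n_danger + ["emergency"] * n_emerg)
    # both lists are sorted coolest-first already; pair index-wise, then shuffle
    pairs = list(zip(dev_labels, his_labels))
    perm = rng.permutation(n)
    t0 = profile.segments[0][0]
    timestamps = t0 + scenario.sample_period * np.arange(n)
    opt = profile.optimal_at(timestamps)

    temps = np.empty(n)
    rhs = np.empty(n)
    for i in range(n):
        dev_band, his_band = pairs[perm[i]]
        h_lo, h_hi, f_lo, f_hi = _his_band_geometry(his_band, config)
        interval = None
        for lo_off, hi_off in _dev_candidates(dev_band, his_band):
            lo, hi = max(opt[i] + lo_off, f_lo), min(opt[i] + hi_off, f_hi)
            if lo <= hi:
                interval = (lo, hi)
                break
        if interval is None:
            raise ConfigurationError(
                f"planted fractions infeasible: deviation band {dev_band!r} cannot "
                f"realise stress band {his_band!r} at setpoint {opt[i]:.1f} degC")
        t = rng.uniform(*interval)
        his_min = 0.8 * t + 46.4          # RH = 0
        his_max = 1.8 * t + 32.0          # RH = 100
        h = rng.uniform(max(h_lo, his_min), min(h_hi, his_max))
        rh = 100.0 * (h - 46.4 - 0.8 * t) / (t - 14.4)
        temps[i] = t
        rhs[i] = min(max(rh, 0.0), 100.0)
    return (SensorSeries(timestamps, temps, "degC", scenario.sample_period),
            SensorSeries(timestamps, rhs, "%RH", scenario.sample_period))


# ---------------------------------------------------------------------------
# transport

@dataclass(frozen=True)
class JourneyBundle:
    temps: SensorSeries
    rhs: SensorSeries
    accel: AccelStream
    params: ZPeakParams


def gen_transport(duration: float = 3600.0, high_rh: float = 0.0, abrupt: float = 0.0,
                  params: ZPeakParams | None = None, seed: int = 0,
                  sample_period: float = 1.0) -> JourneyBundle:
    """One truck journey with planted humidity and abruptness fractions.

    Humidity is stratified (``high_rh``% of samples strictly above 80%),
    temperature stays inside the comfort envelope.  The acceleration
    module is a bounded-noise 1 g base with spike samples (+2 g) inserted
    at ``abrupt``% of the post-warm-up positions; with influence 0 the
    detector flags exactly the inserted spikes, because bounded base
    noise cannot cross a threshold of 5 moving standard deviations.
    """
    params = params or ZPeakParams()
    n = int(duration / sample_period)
    if n <= params.lag:
        raise ConfigurationError("journey shorter than the detector lag window")
    if not (0.0 <= high_rh <= 100.0) or not (0.0 <= abrupt <= 100.0):
        raise ConfigurationError("planted fractions must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    timestamps = _EPOCH0 + sample_period * np.arange(n)

    temps = rng.uniform(22.0, 28.0, n)
    n_high = _allocate_counts(n, (high_rh,))[0]
    rh = np.concatenate([rng.uniform(80.5, 92.0, n_high),
                         rng.uniform(61.0, 79.0, n - n_high)])
    rng.shuffle(rh)

    n_eval = n - params.lag
    k = round(abrupt / 100.0 * n_eval)
    base = 1.0 + rng.uniform(-0.03, 0.03, n)
    spike_idx = rng.choice(np.arange(params.lag, n), size=k, replace=False)
    module = base.copy()
    module[spike_idx] += 2.0
    axis = module / math.sqrt(3.0)
    accel = AccelStream(timestamps, axis, axis, axis, sample_rate=1.0 / sample_period)
    return JourneyBundle(
        temps=SensorSeries(timestamps, temps, "degC", sample_period),
        rhs=SensorSeries(timestamps, rh, "%RH", sample_period),
        accel=accel, params=params)


# ---------------------------------------------------------------------------
# loading (wristband)

def gen_wristband(duration: float = 600.0, rate: float = 100.0,
                  saturation_per_min: float = 0.0,
                  accumulation_mean: float = 60.0,
                  accumulation_std: float = 0.0,
                  seed: int = 0,
                  range_low: float = -8.00, range_high: float = 7.98) -> AccelStream:
    """A wristband stream whose loading KPIs recover the planted values.

    Per complete minute, a target accumulation is drawn from
    N(mean, std^2) and realised exactly by the 60 per-second maxima of the
    acceleration module.  Rail-pinned samples arrive as a per-minute
    Poisson process with the planted intensity; a pinned sample's module
    (just under 8 g) necessarily dominates its second's maximum — a
    saturating swing *is* a large acceleration — so the remaining seconds
    of that minute are scaled down to keep the minute's accumulation on
    target.  Within each second, one sample carries the target maximum
    and the rest sit below it.
    """
    if rate > 1000.0:
        raise ConfigurationError("rate exceeds the wristband's 1000 Hz hardware maximum")
    if accumulation_mean > 60.0 * range_high:
        raise ConfigurationError("planted accumulation mean exceeds what the rails allow")
    if saturation_per_min < 0 or accumulation_std < 0:
        raise ConfigurationError("planted parameters must be non-negative")
    rng = np.random.default_rng(seed)
    n_min = int(duration // 60.0)
    if n_min < 1:
        raise ConfigurationError("duration must cover at least one minute")
    per_sec = int(round(rate))
    n_sec = n_min * 60

    if accumulation_std > 0:
        acc = rng.normal(accumulation_mean, accumulation_std, n_min)
        acc = np.clip(acc, 6.0, 60.0 * range_high * 0.9)
    else:
        acc = np.full(n_min, accumulation_mean)
    pin_module = math.sqrt(range_high ** 2 + 2 * 0.1 ** 2)  # pinned-sample module

    # per-second target maxima: saturated seconds carry the pinned module,
    # the others share the remaining accumulation evenly
    sec_max = np.empty(n_sec)
    pinned = np.zeros(n_sec, dtype=bool)
    for j in range(n_min):
        k = min(int(rng.poisson(saturation_per_min)) if saturation_per_min > 0 else 0, 59)
        sat_secs = rng.choice(60, size=k, replace=False)
        target = max(acc[j], k * pin_module + (60 - k) * 0.05)
        other = (target - k * pin_module) / (60 - k)
        block = np.full(60, other)
        block[sat_secs] = pin_module
        sec_max[j * 60:(j + 1) * 60] = block
        pinned[j * 60 + sat_secs] = True

    # start on an exact epoch minute so every generated minute is complete
    t0 = math.ceil(_EPOCH0 / 60.0) * 60.0
    timestamps = t0 + np.arange(n_sec * per_sec) / rate
    module = np.empty(n_sec * per_sec)
    peak_at = np.empty(n_sec, dtype=int)
    for s in range(n_sec):
        m = sec_max[s] if not pinned[s] else min(sec_max[s], range_high * 0.5)
        block = rng.uniform(0.2, 0.8, per_sec) * m
        if not pinned[s]:
            block[rng.integers(per_sec)] = m
        module[s * per_sec:(s + 1) * per_sec] = block
        peak_at[s] = rng.integers(per_sec)
    axis = module / math.sqrt(3.0)
    ax, ay, az = axis.copy(), axis.copy(), axis.copy()
    for s in np.flatnonzero(pinned):
        i = s * per_sec + peak_at[s]
        ax[i], ay[i], az[i] = range_high, 0.1, 0.1
    return AccelStream(timestamps, ax, ay, az, sample_rate=rate,
                       range_low=range_low, range_high=range_high)


# ---------------------------------------------------------------------------
# historical chain-KPI tables

@dataclass(frozen=True)
class ChainScenario:
    """Planted rule structure for a table of historical production chains."""

    n_chains: int = 2000
    rules: RuleSet | None = None            # defaults to the reference rule set
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigurationError("label_noise must lie in [0, 0.5)")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")


def gen_chain_dataset(scenario: ChainScenario) -> pd.DataFrame:
    """KPI rows labelled by the planted rules, with optional label noise.

    Features are the five KPIs named in the reference rules, drawn
    uniformly on [0, 100]; each row's grade is the planted rules'
    prediction, flipped A<->B with probability ``label_noise``.
    """
    rules = scenario.rules or reference_rule_set()
    rng = np.random.default_rng(scenario.seed)
    feats = sorted({c.feature for r in rules.rules for c in r.conditions})
    n = scenario.n_chains
    table = pd.DataFrame({f: rng.uniform(0.0, 100.0, n) for f in feats})
    labels = [predict(rules, row) for _, row in table.iterrows()]
    if scenario.label_noise > 0:
        flip = rng.random(n) < scenario.label_noise
        labels = [({"A": "B", "B": "A"}.get(l, l) if f else l)
                  for l, f in zip(labels, flip)]
    table.insert(0, "chain_id", [f"chain-{i:05d}" for i in range(n)])
    table[rules.target] = labels
    return table
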