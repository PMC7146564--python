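"""Loading-phase KPIs from operator wristband accelerometer streams.

Catching and loading birds into transport cages is manual work; the force
with which operators handle the animals is monitored through the arm-sway
acceleration of a logging wristband.  Three KPIs summarise a session:

* **Saturation Rate** — saturated seconds per minute, averaged over
  minutes.  "Exceeding the sensor range" is unobservable directly because
  the logger clips at its rails; a second is counted as saturated when any
  raw sample in it sits exactly at a rail (-8.00 g or +7.98 g by default,
  with a configurable tolerance).
* **Mean Accumulation** — the per-minute accumulation of acceleration
  (sum over the minute of the per-second maxima of the acceleration
  module, in g*s), averaged over minutes.
* **Standard Deviation** — the spread of the same per-minute accumulation
  (sample standard deviation, n-1 denominator, by default).

Minute boundaries are aligned to integer epoch minutes; partial leading or
trailing minutes are excluded so incomplete coverage cannot bias the
statistics downward.  Seconds inside a complete minute that contain no
samples contribute 0 to the accumulation and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import AccelStream, Percentage, covered_seconds, per_second_max_module
from .errors import EmptyInputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoadingKpis:
    saturation_rate: float       # saturated seconds per minute, in [0, 60]
    mean_accumulation: float     # g*s per minute
    std_accumulation: float      # g*s per minute, >= 0


def saturation_flags(stream: AccelStream, rail_epsilon: float = 0.0):
    """Per-second saturation flags over the stream's covered seconds.

    Returns ``(seconds, flags)``: integer epoch seconds and a boolean array
    where True marks a second containing at least one sample pinned within
    ``rail_epsilon`` of either rail on any axis.
    """
    if len(stream) == 0:
        raise EmptyInputError("saturation_flags on an empty stream")
    secs = covered_seconds(stream.timestamps)
    sample_sat = np.zeros(len(stream), dtype=bool)
    for axis in (stream.ax, stream.ay, stream.az):
        sample_sat |= np.abs(axis - stream.range_low) <= rail_epsilon
        sample_sat |= np.abs(axis - stream.range_high) <= rail_epsilon
    idx = np.floor(stream.timestamps).astype(np.int64) - secs[0]
    flags = np.zeros(len(secs), dtype=bool)
    np.logical_or.at(flags, idx, sample_sat)
    return secs, flags


def _complete_minutes(secs: np.ndarray) -> np.ndarray:
    """Epoch-minute indices whose full 60 seconds lie inside the covered span."""
    first, last = secs[0], secs[-1]
    m0 = int(np.ceil(first / 60.0))
    m1 = int(np.floor((last + 1) / 60.0)) - 1
    if m1 < m0:
        raise InsufficientDataError(
            "stream does not cover one full epoch-aligned minute")
    return np.arange(m0, m1 + 1, dtype=np.int64)


def saturation_rate(stream: AccelStream, rail_epsilon: float = 0.0) -> float:
    """Mean number of saturated seconds per complete minute."""
    secs, flags = saturation_flags(stream, rail_epsilon)
    minutes = _complete_minutes(secs)
    counts = [int(flags[(secs >= m * 60) & (secs < (m + 1) * 60)].sum()) for m in minutes]
    return float(np.mean(counts))


def accumulation_per_minute(stream: AccelStream):
    """Per-minute accumulation of acceleration, in g*s.

    For each complete minute: the sum of the 60 per-second maxima of the
    acceleration module.  Returns ``(minute_start_seconds, accumulations)``.
    """
    per_sec = per_second_max_module(stream)
    secs = per_sec.timestamps.astype(np.int64)
    minutes = _complete_minutes(secs)
    vals = per_sec.values
    n_empty = int(np.isnan(vals).sum())
    if n_empty:
        logger.info("accumulation_per_minute: %d empty seconds contribute 0", n_empty)
    vals = np.nan_to_num(vals, nan=0.0)
    acc = np.array([vals[(secs >= m * 60) & (secs < (m + 1) * 60)].sum() for m in minutes])
    return minutes * 60, acc


def loading_kpis(stream: AccelStream, rail_epsilon: float = 0.0, ddof: int = 1) -> LoadingKpis:
    """All three loading KPIs for one wristband session.

    ``ddof=1`` (sample standard deviation) is the default; pass ``ddof=0``
    for the population convention.
    """
    _, acc = accumulation_per_minute(stream)
    std = float(np.std(acc, ddof=ddof)) if len(acc) > ddof else 0.0
    return LoadingKpis(
        saturation_rate=saturation_rate(stream, rail_epsilon),
        mean_accumulation=float(np.mean(acc)),
        std_accumulation=std,
    )
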