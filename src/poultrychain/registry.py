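"""Canonical KPI registry: 32 indicators split 5/3/5/19 across the four phases."""

from __future__ import annotations

from .slaughter import KPI_FIELDS as _SLAUGHTER_FIELDS

PHASES = ("breeding", "loading", "transport", "slaughterhouse")

PHASE_KPIS: dict[str, tuple] = {
    "breeding": (
        "temperature_warning",
        "temperature_alarm",
        "alert_situation",
        "danger_situation",
        "emergency_situation",
    ),
    "loading": (
        "saturation_rate",
        "mean_accumulation",
        "std_accumulation",
    ),
    "transport": (
        "low_temperature",
        "high_temperature",
        "low_relative_humidity",
        "high_relative_humidity",
        "abrupt_movements",
    ),
    "slaughterhouse": _SLAUGHTER_FIELDS,
}

#: unit of each KPI, keyed (phase, name); fractions are % of phase time
KPI_UNITS: dict[tuple, str] = {}
for _name in PHASE_KPIS["breeding"]:
    KPI_UNITS[("breeding", _name)] = "%"
KPI_UNITS[("loading", "saturation_rate")] = "count/min"
KPI_UNITS[("loading", "mean_accumulation")] = "g*s/min"
KPI_UNITS[("loading", "std_accumulation")] = "g*s/min"
for _name in PHASE_KPIS["transport"]:
    KPI_UNITS[("transport", _name)] = "%"
for _name in PHASE_KPIS["slaughterhouse"]:
    KPI_UNITS[("slaughterhouse", _name)] = "count"
KPI_UNITS[("slaughterhouse", "weight_range")] = "kg"
KPI_UNITS[("slaughterhouse", "farm_weight")] = "kg"
KPI_UNITS[("slaughterhouse", "meat_quality")] = "grade"


def total_kpis() -> int:
    return sum(len(v) for v in PHASE_KPIS.values())


def is_registered(phase: str, kpi_name: str) -> bool:
    return kpi_name in PHASE_KPIS.get(phase, ())
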