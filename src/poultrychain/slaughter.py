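"""Slaughterhouse-phase KPI records: reader, validator and writer.

At the slaughterhouse, operators inspect a random sample of birds from
each arriving flock (200 by default) and record 19 quality indicators per
flock: carcass weights, injury and processing-defect counts, lot-level
losses and a final binary meat-quality grade (A = mostly high grade,
B otherwise).  The native format here is a CSV template with one row per
flock and a fixed header: ``flock_id``, ``sample_size``, then the 19 KPI
fields.

Count fields are validated against their scope: injury/defect counts
refer to the inspected sample and must not exceed ``sample_size``;
``dead_in_transport`` and ``confiscated`` refer to the whole lot and must
not exceed ``numbers_of_chickens``.  ``weight_range`` is stored as a
scalar in kg — the source template prints a single number under that
heading, indistinguishable from a mean (see docs/methods.md).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

from .errors import InvalidInputError, SchemaError

#: the inspected-sample count fields (<= sample_size each)
SAMPLE_COUNT_FIELDS = (
    "total_hematoms", "broken_wing", "hematoma_wings", "hematoma_armpit",
    "breast", "broken_bones", "overscalded", "bad_extraction_viscera",
    "bad_plucked", "bad_wash", "scab", "crops", "knuckles",
)

#: lot-level count fields (dead/confiscated <= numbers_of_chickens)
LOT_COUNT_FIELDS = ("dead_in_transport", "confiscated", "numbers_of_chickens")

WEIGHT_FIELDS = ("weight_range", "farm_weight")

#: the 19 KPI fields of the template, in header order
KPI_FIELDS = WEIGHT_FIELDS + SAMPLE_COUNT_FIELDS + LOT_COUNT_FIELDS + ("meat_quality",)

HEADER = ("flock_id", "sample_size") + KPI_FIELDS

MEAT_QUALITY_VALUES = ("A", "B")


@dataclass(frozen=True)
class SlaughterRecord:
    """One flock's 19 slaughterhouse KPIs plus its identity and sample size."""

    flock_id: str
    sample_size: int = 200
    weight_range: float = 0.0          # kg
    farm_weight: float = 0.0           # kg
    total_hematoms: int = 0
    broken_wing: int = 0
    hematoma_wings: int = 0
    hematoma_armpit: int = 0
    breast: int = 0
    broken_bones: int = 0
    overscalded: int = 0
    bad_extraction_viscera: int = 0
    bad_plucked: int = 0
    bad_wash: int = 0
    scab: int = 0
    crops: int = 0
    knuckles: int = 0
    dead_in_transport: int = 0
    confiscated: int = 0
    numbers_of_chickens: int = 0
    meat_quality: str = "A"

    def __post_init__(self):
        if not self.flock_id:
            raise InvalidInputError("flock_id must be non-empty")
        if self.sample_size <= 0:
            raise InvalidInputError("sample_size must be positive")
        for name in SAMPLE_COUNT_FIELDS + LOT_COUNT_FIELDS:
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        for name in SAMPLE_COUNT_FIELDS:
            if getattr(self, name) > self.sample_size:
                raise InvalidInputError(
                    f"{name}={getattr(self, name)} exceeds inspected sample size {self.sample_size}")
        for name in ("dead_in_transport", "confiscated"):
            if self.numbers_of_chickens and getattr(self, name) > self.numbers_of_chickens:
                raise InvalidInputError(f"{name} exceeds lot size {self.numbers_of_chickens}")
        for name in WEIGHT_FIELDS:
            v = float(getattr(self, name))
            if v < 0:
                raise InvalidInputError(f"{name} must be >= 0 kg")
            object.__setattr__(self, name, v)
        if self.meat_quality not in MEAT_QUALITY_VALUES:
            raise InvalidInputError(
                f"meat_quality must be one of {MEAT_QUALITY_VALUES}, got {self.meat_quality!r}")

    def kpi_values(self) -> dict:
        """The 19 KPI fields as a name -> value mapping."""
        return {name: getattr(self, name) for name in KPI_FIELDS}


def parse_records(file) -> list[SlaughterRecord]:
    """Read all flock rows from a template CSV.

    Column order is free but every header column must be present; decimal
    points (never commas) are required in weight fields.
    """
    path = Path(file)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for col in HEADER:
            if col not in cols:
                raise SchemaError(f"slaughterhouse CSV missing column {col!r}", column=col)
        records = []
        for lineno, row in enumerate(reader, start=2):
            kwargs = {"flock_id": row["flock_id"].strip()}
            try:
                kwargs["sample_size"] = int(row["sample_size"])
                for name in WEIGHT_FIELDS:
                    kwargs[name] = float(row[name])
                for name in SAMPLE_COUNT_FIELDS + LOT_COUNT_FIELDS:
                    kwargs[name] = int(row[name])
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
            kwargs["meat_quality"] = row["meat_quality"].strip()
            try:
                records.append(SlaughterRecord(**kwargs))
            except InvalidInputError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from None
    return records


def parse_record(file) -> SlaughterRecord:
    """Read a single-flock template CSV (convenience wrapper)."""
    records = parse_records(file)
    if len(records) != 1:
        raise InvalidInputError(f"expected exactly one flock row, found {len(records)}")
    return records[0]


def write_records(records, file) -> None:
    """Write records to the template CSV; round-trips bit-identically.

    Counts are written as integers and weights with ``repr`` so that
    ``parse_records(write_records(rs)) == rs`` exactly.
    """
    records = [records] if isinstance(records, SlaughterRecord) else list(records)
    path = Path(file)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for r in records:
            row = [r.flock_id, r.sample_size]
            for name in KPI_FIELDS:
                v = getattr(r, name)
                row.append(repr(v) if isinstance(v, float) else v)
            writer.writerow(row)


def write_record(record: SlaughterRecord, file) -> None:
    write_records([record], file)
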