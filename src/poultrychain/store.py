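"""The JSON-lines KPI store.

Every computed KPI becomes one :class:`KpiRecord` appended to a flat
JSON-lines file — diffable, dependency-free, and schemaless enough to
absorb new KPIs without migration.  The tuple
``(chain_id, phase, kpi_name, params_digest)`` is unique within a store,
so re-running a phase with identical inputs and configuration is
idempotent: duplicates are silently skipped.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import InvalidInputError
from .registry import is_registered


def params_digest(config: dict) -> str:
    """Short stable hash of the configuration a KPI was computed under."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%S%z")


@dataclass(frozen=True)
class KpiRecord:
    chain_id: str
    phase: str
    kpi_name: str
    value: object
    unit: str
    computed_at: str = ""
    params_digest: str = params_digest({})

    def __post_init__(self):
        if not self.chain_id:
            raise InvalidInputError("chain_id must be non-empty")
        if not is_registered(self.phase, self.kpi_name):
            raise InvalidInputError(
                f"KPI {self.kpi_name!r} is not registered for phase {self.phase!r}")
        if not self.computed_at:
            object.__setattr__(self, "computed_at", _utcnow())

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.phase, self.kpi_name, self.params_digest)


class KpiStore:
    """Append-only JSON-lines store with idempotent writes."""

    def __init__(self, path):
        self.path = Path(path)

    def read(self) -> list[KpiRecord]:
        if not self.path.exists():
            return []
        records = []
        with self.path.open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(KpiRecord(**json.loads(line)))
        return records

    def append(self, records) -> int:
        """Append records whose key is not yet stored; return how many were new."""
        existing = {r.key for r in self.read()}
        added = 0
        with self.path.open("a") as fh:
            for rec in records:
                if rec.key in existing:
                    continue
                fh.write(json.dumps(asdict(rec)) + "\n")
                existing.add(rec.key)
                added += 1
        return added
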