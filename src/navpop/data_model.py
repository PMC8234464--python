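"""Experiment-record schema, JSON I/O, QC hooks and crossover groupings.

An :class:`ExperimentRecord` is one published dataset: a curve of one of
the five kinds together with the protocol that produced it and the
recording conditions (source paper, bath temperature, Na+
concentrations, capacitance-normalisation flag).  A
:class:`StudyDataset` collects records across papers and exposes the two
partitions (by source paper, by experiment kind) used by the sampler's
crossover move.

Units follow the package-wide convention: currents in pA (with pF
capacitance) or pA/pF, voltages in mV, times in ms.  The JSON schema is
versioned and self-defined; unknown fields are preserved on round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from .clamp_protocols import CurveData, ProtocolSpec, qc_reversal

__all__ = [
    "SCHEMA_VERSION",
    "ExperimentRecord",
    "StudyDataset",
    "ParseError",
    "read_dataset",
    "write_dataset",
    "crossover_groups",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Schema violation, naming the offending record and field."""


@dataclass
class ExperimentRecord:
    id: str
    paper_id: str
    kind: str
    protocol: ProtocolSpec
    data: CurveData
    temperature: float
    capacitance_normalized: bool = False
    extra: dict = field(default_factory=dict)  # unknown fields, preserved

    def __post_init__(self) -> None:
        if self.kind != self.protocol.kind:
            raise ParseError(f"record {self.id}: kind {self.kind!r} does not match "
                             f"protocol.kind {self.protocol.kind!r}")
        if not np.isfinite(self.temperature):
            raise ParseError(f"record {self.id}: temperature must be finite")

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "paper_id": self.paper_id,
            "kind": self.kind,
            "protocol": self.protocol.to_dict(),
            "data": self.data.to_dict(),
            "temperature": self.temperature,
            "capacitance_normalized": self.capacitance_normalized,
        }
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentRecord":
        known = {"id", "paper_id", "kind", "protocol", "data", "temperature",
                 "capacitance_normalized"}
        rid = d.get("id", "<missing id>")
        for f in ("id", "paper_id", "kind", "protocol", "data", "temperature"):
            if f not in d:
                raise ParseError(f"record {rid}: missing field {f!r}")
        try:
            proto = ProtocolSpec.from_dict(d["protocol"])
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"record {rid}: bad protocol: {e}") from e
        try:
            data = CurveData.from_dict(d["data"])
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"record {rid}: bad data: {e}") from e
        return cls(
            id=str(d["id"]),
            paper_id=str(d["paper_id"]),
            kind=str(d["kind"]),
            protocol=proto,
            data=data,
            temperature=float(d["temperature"]),
            capacitance_normalized=bool(d.get("capacitance_normalized", False)),
            extra={k: v for k, v in d.items() if k not in known},
        )


@dataclass
class StudyDataset:
    records: list[ExperimentRecord]
    qc_log: list[dict] = field(default_factory=list)

    @property
    def papers(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.paper_id not in seen:
                seen.append(r.paper_id)
        return seen

    @property
    def kinds(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.kind not in seen:
                seen.append(r.kind)
        return seen

    @property
    def n_points(self) -> int:
        return int(sum(r.data.x.size for r in self.records))

    def __len__(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict:
        return {"schema_version": SCHEMA_VERSION,
                "records": [r.to_dict() for r in self.records]}


def _apply_qc(records: list[ExperimentRecord]) -> StudyDataset:
    """Reversal-potential QC on IV records; exclusions logged, survivors shifted."""
    kept: list[ExperimentRecord] = []
    log: list[dict] = []
    for r in records:
        if r.kind != "IV":
            kept.append(r)
            continue
        bath = r.protocol.bath
        verdict, shifted, dev = qc_reversal(r.data, bath)
        entry = {"record_id": r.id, "paper_id": r.paper_id, "check": "reversal",
                 "deviation_mV": None if np.isnan(dev) else round(dev, 6),
                 "verdict": verdict}
        log.append(entry)
        if verdict == "exclude":
            continue
        r.data = shifted
        kept.append(r)
    return StudyDataset(records=kept, qc_log=log)


def read_dataset(path: str | Path, apply_qc: bool = True) -> StudyDataset:
    """Load a dataset from a JSON file or a directory of ``*.json`` files.

    IV records are passed through the reversal-potential QC: deviations
    above 10 mV are excluded (logged in ``qc_log``), smaller ones voltage-
    shifted onto the Nernst prediction.
    """
    path = Path(path)
    raw_records: list[dict] = []
    files = sorted(path.glob("*.json")) if path.is_dir() else [path]
    for f in files:
        text = f.read_text().strip()
        if not text:
            continue
        doc = json.loads(text)
        if isinstance(doc, dict) and "records" in doc:
            raw_records.extend(doc["records"])
        elif isinstance(doc, list):
            raw_records.extend(doc)
        else:
            raw_records.append(doc)
    records = [ExperimentRecord.from_dict(d) for d in raw_records]
    if apply_qc:
        return _apply_qc(records)
    return StudyDataset(records=records)


def write_dataset(ds: StudyDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ds.to_dict(), indent=1))


def write_qc_log(ds: StudyDataset, path: str | Path) -> None:
    """QC outcomes as line-delimited JSON."""
    with open(path, "w") as fh:
        for entry in ds.qc_log:
            fh.write(json.dumps(entry) + "\n")


def crossover_groups(ds: StudyDataset) -> dict[str, list[list[int]]]:
    """The two record-index partitions used by the crossover move.

    ``by_paper`` groups experiments from the same source paper,
    ``by_kind`` groups experiments of the same type; each record appears
    in exactly one group of each partition.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset has no crossover groups")
    by_paper: dict[str, list[int]] = {}
    by_kind: dict[str, list[int]] = {}
    for i, r in enumerate(ds.records):
        by_paper.setdefault(r.paper_id, []).append(i)
        by_kind.setdefault(r.kind, []).append(i)
    return {"by_paper": list(by_paper.values()), "by_kind": list(by_kind.values())}
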