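"""Core containers: documents, stand-off annotations, extractions, records.

Corpora are serialised as JSON Lines, one document per line, with stand-off
gold spans given as 0-based half-open intervals in Unicode code points —
never bytes, so CJK text slices unambiguously.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Optional, Union

Value = Union[float, int, str, tuple]

MANUAL_RE = "manual_re"
MACHINE_RE = "machine_re"


class CorpusFormatError(ValueError):
    """Malformed corpus file; message names the offending line/doc."""


@dataclass(frozen=True)
class GoldAnnotation:
    """One gold concept mention: concept, character span, normalised value."""

    concept: str
    span: tuple[int, int]
    value: Value
    date: Optional[Date] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        s, e = self.span
        if not s < e:
            raise ValueError(f"empty span {self.span} for {self.concept}")


@dataclass(frozen=True)
class EMRDocument:
    """One outpatient note: free text plus the structured age field."""

    doc_id: str
    text: str
    age: Optional[float] = None
    gold: Optional[tuple[GoldAnnotation, ...]] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"{self.doc_id}: text must be non-empty")
        if self.age is not None and not 10 <= self.age <= 70:
            raise ValueError(f"{self.doc_id}: age {self.age} outside [10, 70]")


@dataclass(frozen=True)
class TimedValue:
    """A measurement, optionally dated, with its source span and unit."""

    value: Value
    date: Optional[Date] = None
    unit: Optional[str] = None
    span: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class Extraction:
    """One raw extractor hit, before/after postprocessing."""

    concept: str
    value: Value
    unit: Optional[str] = None
    date: Optional[Date] = None
    span: Optional[tuple[int, int]] = None
    provenance: str = MANUAL_RE
    raw: Optional[str] = None  # surface form as captured, for malformed checks


@dataclass
class PatientRecord:
    """Structured output for one document.

    ``singles`` holds first-occurrence values for non-timed concepts;
    ``series`` holds date-ordered measurement series for timed ones.
    """

    doc_id: str
    age: Optional[float] = None
    singles: dict[str, Value] = field(default_factory=dict)
    series: dict[str, list[TimedValue]] = field(default_factory=dict)

    def n_values(self) -> int:
        return len(self.singles) + sum(len(v) for v in self.series.values())


# ---------------------------------------------------------------------------
# JSONL serialisation


def _value_to_json(v: Value):
    if isinstance(v, tuple):
        return list(v)
    return v


def _value_from_json(v):
    if isinstance(v, list):
        return tuple(v)
    return v


def _gold_to_json(g: GoldAnnotation) -> dict:
    return {
        "concept": g.concept,
        "start": g.span[0],
        "end": g.span[1],
        "value": _value_to_json(g.value),
        "date": g.date.isoformat() if g.date else None,
        "unit": g.unit,
    }


def _gold_from_json(d: dict) -> GoldAnnotation:
    return GoldAnnotation(
        concept=d["concept"],
        span=(d["start"], d["end"]),
        value=_value_from_json(d["value"]),
        date=Date.fromisoformat(d["date"]) if d.get("date") else None,
        unit=d.get("unit"),
    )


def document_to_json(doc: EMRDocument) -> str:
    payload = {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "age": doc.age,
        "gold": [_gold_to_json(g) for g in doc.gold] if doc.gold is not None else None,
    }
    return json.dumps(payload, ensure_ascii=False)


def document_from_json(line: str, lineno: int = 0) -> EMRDocument:
    try:
        d = json.loads(line)
        gold = d.get("gold")
        return EMRDocument(
            doc_id=d["doc_id"],
            text=d["text"],
            age=d.get("age"),
            gold=tuple(_gold_from_json(g) for g in gold) if gold is not None else None,
        )
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        doc_id = ""
        try:
            doc_id = json.loads(line).get("doc_id", "")
        except Exception:
            pass
        raise CorpusFormatError(
            f"malformed corpus record at line {lineno}" + (f" (doc_id={doc_id})" if doc_id else "")
            + f": {exc}"
        ) from exc


def write_corpus(corpus: Iterable[EMRDocument], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(document_to_json(doc) + "\n")


def read_corpus(path: Union[str, Path]) -> list[EMRDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            docs.append(document_from_json(line, lineno))
    return docs


def record_to_json(rec: PatientRecord) -> str:
    payload = {
        "doc_id": rec.doc_id,
        "age": rec.age,
        "singles": {k: _value_to_json(v) for k, v in rec.singles.items()},
        "series": {
            k: [
                {
                    "value": _value_to_json(tv.value),
                    "date": tv.date.isoformat() if tv.date else None,
                    "unit": tv.unit,
                }
                for tv in vals
            ]
            for k, vals in rec.series.items()
        },
    }
    return json.dumps(payload, ensure_ascii=False)


def record_from_json(line: str) -> PatientRecord:
    d = json.loads(line)
    return PatientRecord(
        doc_id=d["doc_id"],
        age=d.get("age"),
        singles={k: _value_from_json(v) for k, v in d["singles"].items()},
        series={
            k: [
                TimedValue(
                    value=_value_from_json(e["value"]),
                    date=Date.fromisoformat(e["date"]) if e.get("date") else None,
                    unit=e.get("unit"),
                )
                for e in vals
            ]
            for k, vals in d["series"].items()
        },
    )


def write_records(records: Iterable[PatientRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(record_to_json(rec) + "\n")


def read_records(path: Union[str, Path]) -> list[PatientRecord]:
    with open(path, encoding="utf-8") as fh:
        return [record_from_json(line) for line in fh if line.strip()]


def records_to_table(records: Iterable[PatientRecord]):
    """Flatten records to a long table: one row per doc x concept x occasion."""
    import pandas as pd

    rows = []
    for rec in records:
        for concept, value in sorted(rec.singles.items()):
            rows.append(
                {"doc_id": rec.doc_id, "concept": concept, "occasion": 0,
                 "date": None, "value": str(_value_to_json(value)), "unit": None}
            )
        for concept, vals in sorted(rec.series.items()):
            for i, tv in enumerate(vals):
                rows.append(
                    {"doc_id": rec.doc_id, "concept": concept, "occasion": i,
                     "date": tv.date.isoformat() if tv.date else None,
                     "value": str(_value_to_json(tv.value)), "unit": tv.unit}
                )
    return pd.DataFrame(rows, columns=["doc_id", "concept", "occasion", "date", "value", "unit"])
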