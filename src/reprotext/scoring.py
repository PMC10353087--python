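"""Knowledge-based ovarian-reserve scoring: DOR, POI and POF score cards.

The model encodes the clinical criteria — DOR: FSH > 10 IU/L, AMH <= 1
ng/mL, AFC <= 5; POI: menstrual irregularity with FSH > 25 IU/L under age
40; POF: the same with FSH > 40 IU/L — as additive subsection scores.
Occasion-based subscores follow the pattern: no qualifying occasion 0, one
occasion 1, at least two occasions within four weeks 2, at least two
occasions more than four weeks apart 3; undocumented inputs score null and
an all-null block has a null total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Callable, Optional, Sequence

from . import concepts as C
from .documents import PatientRecord
from .synth import AMH_PMOL_PER_NG

SubScore = Optional[int]

# model thresholds; one place, defaulting to the published criteria
THRESHOLDS = {
    "fsh_dor": 10.0,       # IU/L
    "fsh_poi": 25.0,       # IU/L
    "fsh_pof": 40.0,       # IU/L
    "amh_low": 1.0,        # ng/mL
    "afc_low": 5,          # follicles, both ovaries
    "cycle_min": 24,       # days
    "cycle_max": 35,       # days
    "weeks4_days": 28,     # "> 4 weeks apart" = strictly more than 28 days
    "age_gate": 40.0,      # POI/POF scored only under this age
}


@dataclass(frozen=True)
class ScoreInputs:
    """Preprocessed inputs for the scoring model (nulls where undocumented)."""

    age: float
    cycle_days: Optional[object] = None  # int or (lo, hi) range
    amh_min: Optional[float] = None      # ng/mL, minimum over documented values
    fsh_series: tuple = ()               # (optional date, IU/L) pairs
    afc_series: tuple = ()               # (optional date, total AFC) pairs


@dataclass(frozen=True)
class Block:
    subscores: dict[str, SubScore]

    @property
    def total(self) -> Optional[int]:
        vals = [v for v in self.subscores.values() if v is not None]
        return sum(vals) if vals else None

    def __getitem__(self, k: str) -> SubScore:
        return self.subscores[k]


@dataclass(frozen=True)
class ScoreCard:
    dor: Block
    poi: Block
    pof: Block

    def all_null(self) -> bool:
        return all(
            v is None
            for block in (self.dor, self.poi, self.pof)
            for v in block.subscores.values()
        )


def occasion_score(series: Sequence[tuple[Optional[Date], float]],
                   predicate: Callable[[float], bool],
                   apart_days: int = THRESHOLDS["weeks4_days"]) -> SubScore:
    """Score a measurement series against a threshold predicate.

    Null for an empty series; 0/1 for no/one qualifying occasion; with two or
    more qualifying occasions, 3 when some qualifying *dated* pair lies more
    than ``apart_days`` apart, else 2 (undated occasions count toward the
    occasion number but cannot certify the four-week separation).
    """
    if not series:
        return None
    qualifying = [(d, v) for d, v in series if predicate(v)]
    if not qualifying:
        return 0
    # an "occasion" is a distinct calendar date; undated measurements each
    # count as an occasion but cannot certify the separation condition
    dates = sorted({d for d, _ in qualifying if d is not None})
    n_occasions = len(dates) + sum(1 for d, _ in qualifying if d is None)
    if n_occasions == 1:
        return 1
    if dates and (dates[-1] - dates[0]).days > apart_days:
        return 3
    return 2


def _cycle_subscore(cycle_days, th=THRESHOLDS) -> SubScore:
    if cycle_days is None:
        return None
    lo, hi = (cycle_days, cycle_days) if not isinstance(cycle_days, tuple) else cycle_days
    return 1 if (lo < th["cycle_min"] or hi > th["cycle_max"]) else 0


def score_dor(inputs: ScoreInputs, th: dict = THRESHOLDS) -> Block:
    afc = occasion_score(inputs.afc_series, lambda v: v <= th["afc_low"], th["weeks4_days"])
    amh = None if inputs.amh_min is None else (3 if inputs.amh_min <= th["amh_low"] else 0)
    fsh10 = occasion_score(inputs.fsh_series, lambda v: v > th["fsh_dor"], th["weeks4_days"])
    return Block({"afc": afc, "amh": amh, "fsh10": fsh10})


def score_poi(inputs: ScoreInputs, th: dict = THRESHOLDS) -> Block:
    if inputs.age >= th["age_gate"]:
        return Block({"cycle": None, "fsh25": None})
    cycle = _cycle_subscore(inputs.cycle_days, th)
    fsh25 = occasion_score(inputs.fsh_series, lambda v: v > th["fsh_poi"], th["weeks4_days"])
    return Block({"cycle": cycle, "fsh25": fsh25})


def score_pof(inputs: ScoreInputs, th: dict = THRESHOLDS) -> Block:
    if inputs.age >= th["age_gate"]:
        return Block({"cycle": None, "fsh40": None})
    cycle = _cycle_subscore(inputs.cycle_days, th)
    fsh40 = occasion_score(inputs.fsh_series, lambda v: v > th["fsh_pof"], th["weeks4_days"])
    return Block({"cycle": cycle, "fsh40": fsh40})


def score_card(inputs: ScoreInputs, th: dict = THRESHOLDS) -> ScoreCard:
    return ScoreCard(dor=score_dor(inputs, th), poi=score_poi(inputs, th), pof=score_pof(inputs, th))


# ---------------------------------------------------------------------------
# building score inputs from extracted records

_FSH_IU_UNITS = {None, "IU/L", "U/L", "mIU/ml", "mIU/mL", "mIU/L"}


def _amh_to_ng_ml(value: float, unit: Optional[str]) -> float:
    if unit and unit.lower().startswith("pmol"):
        return value / AMH_PMOL_PER_NG
    return value


def build_score_inputs(record: PatientRecord, age: Optional[float] = None) -> ScoreInputs:
    """Convert a structured record into scoring inputs.

    AMH values in pmol/L are converted to ng/mL (/ 7.14) and the minimum
    documented value is kept; FSH in mIU/mL is taken as numerically equal to
    IU/L; per-occasion AFC totals are formed only where left and right counts
    share a date (a side missing on an occasion nulls that occasion).
    """
    if age is None:
        age = record.age
    if age is None:
        raise ValueError(f"{record.doc_id}: age is required for scoring")

    fsh_series = tuple(
        (tv.date, float(tv.value)) for tv in record.series.get(C.FSH, ())
    )

    amh_vals = [
        _amh_to_ng_ml(float(tv.value), tv.unit) for tv in record.series.get(C.AMH, ())
    ]
    amh_min = min(amh_vals) if amh_vals else None

    left = {tv.date: int(tv.value) for tv in record.series.get(C.AFC_LEFT, ()) if tv.date is not None}
    right = {tv.date: int(tv.value) for tv in record.series.get(C.AFC_RIGHT, ()) if tv.date is not None}
    afc_series = tuple(sorted((d, left[d] + right[d]) for d in left.keys() & right.keys()))
    if not afc_series:
        # undated exam: pair sides only when each side has exactly one undated count
        lu = [tv for tv in record.series.get(C.AFC_LEFT, ()) if tv.date is None]
        ru = [tv for tv in record.series.get(C.AFC_RIGHT, ()) if tv.date is None]
        if len(lu) == 1 and len(ru) == 1:
            afc_series = ((None, int(lu[0].value) + int(ru[0].value)),)

    cycle = record.singles.get(C.MENSTRUAL_CYCLE)
    return ScoreInputs(age=float(age), cycle_days=cycle, amh_min=amh_min,
                       fsh_series=fsh_series, afc_series=afc_series)


def score_record(record: PatientRecord, age: Optional[float] = None,
                 th: dict = THRESHOLDS) -> ScoreCard:
    return score_card(build_score_inputs(record, age), th)


def scorecards_to_table(cards: dict[str, ScoreCard]):
    """One row per patient with all seven subscores and the three totals."""
    import pandas as pd

    rows = []
    for doc_id, card in cards.items():
        rows.append({
            "doc_id": doc_id,
            "dor_afc": card.dor["afc"], "dor_amh": card.dor["amh"],
            "dor_fsh10": card.dor["fsh10"], "dor_total": card.dor.total,
            "poi_cycle": card.poi["cycle"], "poi_fsh25": card.poi["fsh25"],
            "poi_total": card.poi.total,
            "pof_cycle": card.pof["cycle"], "pof_fsh40": card.pof["fsh40"],
            "pof_total": card.pof.total,
        })
    return pd.DataFrame(rows)
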