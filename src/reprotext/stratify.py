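"""Risk stratification: score card + age -> machine diagnosis and risk group.

The decision is deliberately loosened relative to the strict diagnostic
criteria: a single abnormal but pivotal FSH result is enough to flag risk,
because outpatient notes are often incomplete.  The ordered rule is:

1. every applicable subscore null          -> Insufficient (indeterminate)
2. age < 40 and the FSH>40 subscore >= 1   -> POF  (high risk)
3. age < 40 and the FSH>25 subscore >= 1   -> POI  (high risk)
4. DOR total >= 1                          -> DOR  (high risk)
5. otherwise                               -> Healthy (low risk)

Menstrual irregularity alone (cycle subscore 1 with all reserve markers
normal) maps to Healthy by default; set ``require_irregular_menses`` to
demand the textbook conjunction of irregular menses and elevated FSH for
POI/POF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import THRESHOLDS, ScoreCard

POF_LABEL, POI_LABEL, DOR_LABEL = "POF", "POI", "DOR"
HEALTHY_LABEL, INSUFFICIENT_LABEL = "Healthy", "Insufficient"
LABELS = (POF_LABEL, POI_LABEL, DOR_LABEL, HEALTHY_LABEL, INSUFFICIENT_LABEL)

HIGH, LOW, INDETERMINATE = "high", "low", "indeterminate"
_RISK = {POF_LABEL: HIGH, POI_LABEL: HIGH, DOR_LABEL: HIGH,
         HEALTHY_LABEL: LOW, INSUFFICIENT_LABEL: INDETERMINATE}


@dataclass(frozen=True)
class Diagnosis:
    label: str
    risk: str


def diagnose(card: ScoreCard, age: float,
             require_irregular_menses: bool = False,
             th: dict = THRESHOLDS) -> Diagnosis:
    """Map one score card to exactly one diagnosis label and risk group."""
    if card.all_null():
        return Diagnosis(INSUFFICIENT_LABEL, INDETERMINATE)
    under_age = age < th["age_gate"]

    def _menses_ok(block) -> bool:
        return not require_irregular_menses or (block["cycle"] or 0) >= 1

    fsh40 = card.pof.subscores.get("fsh40")
    if under_age and fsh40 is not None and fsh40 >= 1 and _menses_ok(card.pof):
        return Diagnosis(POF_LABEL, HIGH)
    fsh25 = card.poi.subscores.get("fsh25")
    if under_age and fsh25 is not None and fsh25 >= 1 and _menses_ok(card.poi):
        return Diagnosis(POI_LABEL, HIGH)
    dor_total = card.dor.total
    if dor_total is not None and dor_total >= 1:
        return Diagnosis(DOR_LABEL, HIGH)
    return Diagnosis(HEALTHY_LABEL, LOW)


def diagnose_cohort(cards: dict[str, ScoreCard], ages: dict[str, float],
                    require_irregular_menses: bool = False) -> dict[str, Diagnosis]:
    return {
        doc_id: diagnose(card, ages[doc_id], require_irregular_menses)
        for doc_id, card in cards.items()
    }


def describe_by_diagnosis(cards: Sequence[ScoreCard],
                          diagnoses: Sequence[Diagnosis]) -> pd.DataFrame:
    """Per-diagnosis mean +/- SD of the DOR/POI/POF totals (nulls excluded).

    Mirrors a descriptive cohort table: one row per observed label, columns
    ``<block>_mean`` and ``<block>_sd``.
    """
    if len(cards) != len(diagnoses):
        raise ValueError("cards and diagnoses must align")
    rows = []
    for card, diag in zip(cards, diagnoses):
        rows.append({
            "label": diag.label,
            "dor": card.dor.total, "poi": card.poi.total, "pof": card.pof.total,
        })
    df = pd.DataFrame(rows, columns=["label", "dor", "poi", "pof"])
    if df.empty:
        return pd.DataFrame(columns=["label", "n", "dor_mean", "dor_sd",
                                     "poi_mean", "poi_sd", "pof_mean", "pof_sd"])
    out = []
    for label, grp in df.groupby("label", sort=True):
        row = {"label": label, "n": len(grp)}
        for block in ("dor", "poi", "pof"):
            vals = grp[block].dropna().astype(float)
            row[f"{block}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{block}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan)
        out.append(row)
    return pd.DataFrame(out)


def diagnoses_to_table(cards: dict[str, ScoreCard], diagnoses: dict[str, Diagnosis]) -> pd.DataFrame:
    rows = []
    for doc_id, diag in diagnoses.items():
        card = cards[doc_id]
        rows.append({
            "doc_id": doc_id, "label": diag.label, "risk": diag.risk,
            "dor_total": card.dor.total, "poi_total": card.poi.total,
            "pof_total": card.pof.total,
        })
    return pd.DataFrame(rows)
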