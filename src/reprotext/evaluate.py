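"""Extraction and diagnosis evaluation.

Extraction quality is scored per concept against gold stand-off values:
precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R).  Concepts
followed over time are compared as multisets of (date, value) pairs; the
others as single first-occurrence values.  Five-fold cross-validation
averages the metrics over folds with a Student-t 95% interval, and
diagnosis agreement is reported as a confusion matrix, risk-level
accuracy/sensitivity and Cohen's kappa.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from . import concepts as C
from .concepts import DATE, UnknownConceptError, default_specs
from .documents import EMRDocument, GoldAnnotation, PatientRecord

EVAL_CONCEPTS = tuple(n for n, s in default_specs().items() if s.rule != DATE)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    precision: Optional[float]
    recall: float
    fscore: float
    ci95: Optional[tuple[float, float]] = None


def _norm_value(v) -> object:
    """Normalise values for comparison: numerics to float, ranges to tuples."""
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):
        return float(v)
    if isinstance(v, (tuple, list)):
        return tuple(float(x) for x in v)
    return v


def match_extractions(predicted: PatientRecord,
                      gold: Sequence[GoldAnnotation],
                      concept: str) -> ConfusionCounts:
    """Score one document's extractions for one concept against gold.

    Timed concepts: multiset matching of (date, value) pairs — matched pairs
    are TPs, unmatched predictions FPs, unmatched gold FNs.  Non-timed
    concepts: single-value comparison; a value where gold has none is an FP,
    a mismatch is an FP, absence on both sides is one TN.
    """
    spec = default_specs().get(concept)
    if spec is None:
        raise UnknownConceptError(concept)
    gold_for = [g for g in gold if g.concept == concept]
    if spec.timed:
        pred = Counter((tv.date, _norm_value(tv.value)) for tv in predicted.series.get(concept, ()))
        ref = Counter((g.date, _norm_value(g.value)) for g in gold_for)
        tp = sum((pred & ref).values())
        fp = sum((pred - ref).values())
        fn = sum((ref - pred).values())
        if tp == fp == fn == 0:
            return ConfusionCounts(tn=1)
        return ConfusionCounts(tp=tp, fp=fp, fn=fn)
    pv = predicted.singles.get(concept)
    gv = gold_for[0].value if gold_for else None
    if pv is None and gv is None:
        return ConfusionCounts(tn=1)
    if pv is None:
        return ConfusionCounts(fn=1)
    if gv is None:
        return ConfusionCounts(fp=1)
    if _norm_value(pv) == _norm_value(gv):
        return ConfusionCounts(tp=1)
    return ConfusionCounts(fp=1)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision/recall/F from counts.

    Zero-denominator convention: with nothing to find and nothing found
    (tp+fp = 0 and fn = 0) all three metrics are 1.0; with tp+fp = 0 but
    fn > 0 precision is undefined (None) and recall/F are 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0 and fn == 0:
        return Metrics(1.0, 1.0, 1.0)
    if tp + fp == 0:
        return Metrics(None, 0.0, 0.0)
    p = tp / (tp + fp)
    r = tp / (tp + fn) if tp + fn else 1.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return Metrics(p, r, f)


def evaluate_corpus(records: Sequence[PatientRecord],
                    docs: Sequence[EMRDocument],
                    concepts: Sequence[str] = EVAL_CONCEPTS) -> pd.DataFrame:
    """Pool per-document counts per concept and report the three metrics."""
    by_id = {r.doc_id: r for r in records}
    rows = []
    for concept in concepts:
        total = ConfusionCounts()
        for doc in docs:
            rec = by_id.get(doc.doc_id, PatientRecord(doc_id=doc.doc_id))
            total = total + match_extractions(rec, doc.gold or (), concept)
        m = metrics(total)
        rows.append({"concept": concept, "tp": total.tp, "fp": total.fp,
                     "tn": total.tn, "fn": total.fn,
                     "precision": m.precision, "recall": m.recall, "fscore": m.fscore})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic shuffled k-fold partition of range(n)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} documents into {k} folds")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(idx, k)]


def t_ci95(values: Sequence[float]) -> tuple[float, float]:
    """Student-t 95% interval for the mean of a small sample."""
    arr = np.asarray(values, dtype=float)
    m = float(arr.mean())
    if len(arr) < 2 or float(arr.std(ddof=1)) == 0.0:
        return (m, m)
    half = stats.t.ppf(0.975, len(arr) - 1) * arr.std(ddof=1) / math.sqrt(len(arr))
    return (m - half, m + half)


def cross_validate(corpus: Sequence[EMRDocument],
                   pipeline_factory: Callable[[Sequence[EMRDocument]], Callable],
                   k: int = 5,
                   seed: int = 0,
                   concepts: Sequence[str] = EVAL_CONCEPTS) -> pd.DataFrame:
    """k-fold evaluation of an extraction pipeline.

    ``pipeline_factory(train_docs)`` must return a callable mapping a list of
    documents to a list of :class:`PatientRecord`.  Returns per-concept mean
    precision/recall/F over folds with Student-t 95% CIs.
    """
    folds = kfold_indices(len(corpus), k, seed)
    per_fold: dict[str, list[Metrics]] = {c: [] for c in concepts}
    for fi, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_docs = [d for i, d in enumerate(corpus) if i not in test_set]
        test_docs = [corpus[i] for i in test_idx]
        extract_fn = pipeline_factory(train_docs)
        records = extract_fn(test_docs)
        table = evaluate_corpus(records, test_docs, concepts)
        for _, row in table.iterrows():
            per_fold[row["concept"]].append(
                Metrics(row["precision"], row["recall"], row["fscore"])
            )
    rows = []
    for concept in concepts:
        ms = per_fold[concept]
        precisions = [m.precision for m in ms if m.precision is not None]
        recalls = [m.recall for m in ms]
        fs = [m.fscore for m in ms]
        rows.append({
            "concept": concept,
            "precision_mean": float(np.mean(precisions)) if precisions else None,
            "recall_mean": float(np.mean(recalls)),
            "fscore_mean": float(np.mean(fs)),
            "fscore_ci_lo": t_ci95(fs)[0], "fscore_ci_hi": t_ci95(fs)[1],
            "n_folds": len(ms),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired comparisons


def paired_t(series_a: Sequence[float], series_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t test; pairing is per concept/condition."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if np.allclose(a, b):
        return (0.0, 1.0)
    t, p = stats.ttest_rel(a, b)
    return (float(t), float(p))


def friedman(*conditions: Sequence[float]) -> tuple[float, float]:
    """Friedman test over >= 3 matched conditions."""
    if len(conditions) < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    stat, p = stats.friedmanchisquare(*conditions)
    return (float(stat), float(p))


# ---------------------------------------------------------------------------
# diagnosis agreement

_HIGH_RISK = {"POF", "POI", "DOR"}


def diagnosis_agreement(machine: Sequence[str], reference: Sequence[str]) -> dict:
    """Agreement between machine and reference diagnosis labels.

    Risk-level 2x2 accuracy and sensitivity (high risk = positive class) plus
    label-level Cohen's kappa and a confusion matrix over the four diagnosis
    labels.  Kappa is null (with a warning flag) when the reference is
    degenerate (one class).
    """
    if len(machine) != len(reference):
        raise ValueError("label sequences must align")
    labels = sorted(set(machine) | set(reference))
    cm = confusion_matrix(reference, machine, labels=labels)

    m_high = np.array([lab in _HIGH_RISK for lab in machine])
    r_high = np.array([lab in _HIGH_RISK for lab in reference])
    n = len(machine)
    accuracy = float((m_high == r_high).mean()) if n else float("nan")
    sensitivity = float(m_high[r_high].mean()) if r_high.any() else float("nan")

    if len(set(reference)) < 2:
        kappa = None
        warning = "kappa undefined: reference labels are degenerate"
    else:
        kappa = float(cohen_kappa_score(reference, machine, labels=labels))
        warning = None
    return {
        "labels": labels,
        "confusion_matrix": cm.tolist(),
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "kappa": kappa,
        "agreement_rate": float(np.mean([m == r for m, r in zip(machine, reference)])) if n else float("nan"),
        "warning": warning,
    }


# ---------------------------------------------------------------------------
# descriptive missingness


def summarize_missingness(corpus: Sequence[EMRDocument],
                          concepts: Sequence[str] = EVAL_CONCEPTS) -> pd.DataFrame:
    """Per-concept absent-value counts plus mean/variance of numeric concepts."""
    rows = []
    for concept in concepts:
        absent = 0
        values: list[float] = []
        for doc in corpus:
            anns = [g for g in (doc.gold or ()) if g.concept == concept]
            if not anns:
                absent += 1
                continue
            for g in anns:
                v = _norm_value(g.value)
                if isinstance(v, float):
                    values.append(v)
                elif isinstance(v, tuple):
                    values.append(float(np.mean(v)))
        rows.append({
            "concept": concept,
            "n_docs": len(corpus),
            "absent": absent,
            "n_values": len(values),
            "mean": float(np.mean(values)) if values else None,
            "variance": float(np.var(values, ddof=1)) if len(values) > 1 else (0.0 if values else None),
        })
    return pd.DataFrame(rows)
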