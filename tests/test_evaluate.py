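"""Evaluation: confusion counts, metrics conventions, CV, agreement stats."""

import math
from datetime import date as Date

import numpy as np
import pytest

from reprotext import concepts as C
from reprotext.concepts import UnknownConceptError
from reprotext.documents import EMRDocument, GoldAnnotation, PatientRecord, TimedValue
from reprotext.evaluate import (
    EVAL_CONCEPTS,
    ConfusionCounts,
    cross_validate,
    diagnosis_agreement,
    evaluate_corpus,
    friedman,
    kfold_indices,
    match_extractions,
    metrics,
    paired_t,
    summarize_missingness,
    t_ci95,
)
from reprotext.extract import extract_corpus

D0 = Date(2019, 5, 1)


def _gold(concept, value, span=(0, 4), date=None):
    return GoldAnnotation(concept=concept, span=span, value=value, date=date)


class TestMatchExtractions:
    def test_exact_single_value_match_is_tp(self):
        rec = PatientRecord("d", singles={C.MENARCHE_AGE: 13})
        counts = match_extractions(rec, [_gold(C.MENARCHE_AGE, 13)], C.MENARCHE_AGE)
        assert counts == ConfusionCounts(tp=1)

    def test_prediction_without_gold_is_fp(self):
        rec = PatientRecord("d", singles={C.MENARCHE_AGE: 13})
        assert match_extractions(rec, [], C.MENARCHE_AGE) == ConfusionCounts(fp=1)

    def test_absent_on_both_sides_is_tn(self):
        assert match_extractions(PatientRecord("d"), [], C.MENARCHE_AGE) == ConfusionCounts(tn=1)

    def test_missed_gold_is_fn(self):
        assert match_extractions(PatientRecord("d"), [_gold(C.MENARCHE_AGE, 13)],
                                 C.MENARCHE_AGE) == ConfusionCounts(fn=1)

    def test_timed_concept_matches_date_value_pairs_as_multisets(self):
        rec = PatientRecord("d", series={C.FSH: [TimedValue(5.32, D0), TimedValue(7.0, None)]})
        gold = [_gold(C.FSH, 5.32, date=D0), _gold(C.FSH, 9.9, date=D0)]
        counts = match_extractions(rec, gold, C.FSH)
        assert counts == ConfusionCounts(tp=1, fp=1, fn=1)

    def test_int_and_float_forms_compare_equal(self):
        rec = PatientRecord("d", series={C.AFC_LEFT: [TimedValue(5, D0)]})
        assert match_extractions(rec, [_gold(C.AFC_LEFT, 5.0, date=D0)],
                                 C.AFC_LEFT).tp == 1

    def test_unknown_concept_raises(self):
        with pytest.raises(UnknownConceptError):
            match_extractions(PatientRecord("d"), [], "unknown")


class TestMetrics:
    def test_standard_arithmetic(self):
        m = metrics(ConfusionCounts(tp=9, fp=1, fn=1))
        assert (m.precision, m.recall, m.fscore) == (0.9, 0.9, 0.9)

    def test_perfect_absence_convention(self):
        m = metrics(ConfusionCounts(tn=3))
        assert (m.precision, m.recall, m.fscore) == (1.0, 1.0, 1.0)

    def test_nothing_found_with_gold_present(self):
        m = metrics(ConfusionCounts(fn=5))
        assert m.precision is None and m.recall == 0.0 and m.fscore == 0.0

    def test_all_wrong(self):
        m = metrics(ConfusionCounts(fp=5, fn=5))
        assert (m.precision, m.recall, m.fscore) == (0.0, 0.0, 0.0)

    def test_fscore_bounds_against_precision_recall(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, fn = rng.integers(0, 30, 3)
            m = metrics(ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn)))
            if m.precision is None or m.precision + m.recall == 0:
                continue
            lo = min(m.precision, m.recall)
            assert m.fscore <= 2 * lo / (1 + lo) + 1e-12
            assert m.fscore <= (m.precision + m.recall) / 2 + 1e-12

    def test_counts_must_be_non_negative(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestBruteForceTallyOracle:
    def test_corpus_metrics_match_independent_tally(self, clean_corpus, clean_records):
        docs, _ = clean_corpus
        table = evaluate_corpus(clean_records, docs).set_index("concept")
        by_id = {r.doc_id: r for r in clean_records}
        for concept in EVAL_CONCEPTS:
            tp = fp = fn = tn = 0
            timed = concept in {C.FSH, C.LH, C.E2, C.P, C.PRL, C.T, C.AMH,
                                C.ENDOMETRIUM, C.AFC_LEFT, C.AFC_RIGHT}
            for doc in docs:
                rec = by_id[doc.doc_id]
                gold = [g for g in doc.gold if g.concept == concept]
                if timed:
                    pred = sorted(
                        ((tv.date, float(tv.value)) for tv in rec.series.get(concept, ())),
                        key=str)
                    ref = sorted(((g.date, float(g.value)) for g in gold), key=str)
                    while pred and ref:
                        if pred[0] in ref:
                            ref.remove(pred[0]); pred.pop(0); tp += 1
                        else:
                            pred.pop(0); fp += 1
                    fp += len(pred); fn += len(ref)
                    if not gold and concept not in rec.series:
                        tn += 1
                else:
                    pv, gv = rec.singles.get(concept), (gold[0].value if gold else None)
                    norm = lambda v: tuple(map(float, v)) if isinstance(v, tuple) else (
                        float(v) if isinstance(v, (int, float)) else v)
                    if pv is None and gv is None:
                        tn += 1
                    elif pv is None:
                        fn += 1
                    elif gv is None or norm(pv) != norm(gv):
                        fp += 1
                    else:
                        tp += 1
            row = table.loc[concept]
            assert (row.tp, row.fp, row.tn, row.fn) == (tp, fp, tn, fn)


class TestCrossValidation:
    def test_folds_partition_the_corpus_exactly(self):
        folds = kfold_indices(400, 5, seed=0)
        assert [len(f) for f in folds] == [80] * 5
        assert sorted(np.concatenate(folds).tolist()) == list(range(400))

    def test_identical_seed_gives_identical_folds(self):
        a = kfold_indices(100, 5, seed=3)
        b = kfold_indices(100, 5, seed=3)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_single_fold_is_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(10, 1, seed=0)

    def test_manual_pipeline_cv_on_clean_corpus_is_perfect(self, clean_corpus):
        docs, _ = clean_corpus
        factory = lambda train: (lambda test: extract_corpus(list(test))[0])
        table = cross_validate(docs[:50], factory, k=5, seed=1,
                               concepts=(C.FSH, C.AMH, C.MENARCHE_AGE))
        assert (table.fscore_mean == 1.0).all()
        assert (table.n_folds == 5).all()
        # fold means coincide with a pooled recomputation here
        pooled = evaluate_corpus(extract_corpus(docs[:50])[0], docs[:50],
                                 concepts=(C.FSH, C.AMH, C.MENARCHE_AGE))
        assert np.allclose(table.fscore_mean.values, pooled.fscore.values)

    def test_t_ci_is_symmetric_and_degenerate_for_constant_series(self):
        lo, hi = t_ci95([0.9, 0.9, 0.9])
        assert lo == hi == 0.9
        lo, hi = t_ci95([0.8, 0.9, 1.0])
        assert lo < 0.9 < hi and math.isclose((lo + hi) / 2, 0.9)


class TestPairedComparisons:
    def test_identical_series_give_t0_p1(self):
        assert paired_t([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]) == (0.0, 1.0)

    def test_consistent_shift_gives_small_p(self):
        a = [0.90, 0.85, 0.80, 0.95, 0.88]
        b = [x - 0.10 + e for x, e in zip(a, [0.001, -0.002, 0.002, -0.001, 0.0])]
        t, p = paired_t(a, b)
        # closed form: t = mean(d) / (sd(d)/sqrt(n))
        d = np.array(a) - np.array(b)
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(expected_t)
        assert p < 0.001

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [1])

    def test_friedman_requires_three_conditions(self):
        with pytest.raises(ValueError):
            friedman([1, 2, 3], [2, 3, 4])
        stat, p = friedman([1, 2, 3, 4], [2, 3, 4, 5], [3, 4, 5, 6])
        assert stat > 0 and 0 <= p <= 1


def _kappa_from_matrix(cm):
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = (cm.sum(0) * cm.sum(1)).sum() / n**2
    return (po - pe) / (1 - pe)


class TestDiagnosisAgreement:
    def test_perfect_agreement_gives_kappa_one(self):
        labels = ["POF", "POI", "DOR", "Healthy"] * 5
        out = diagnosis_agreement(labels, labels)
        assert out["kappa"] == pytest.approx(1.0)
        assert out["accuracy"] == 1.0 and out["sensitivity"] == 1.0

    def test_degenerate_reference_yields_null_kappa_with_warning(self):
        out = diagnosis_agreement(["DOR", "Healthy"], ["Healthy", "Healthy"])
        assert out["kappa"] is None and out["warning"]

    def test_kappa_matches_brute_force_from_marginals(self):
        machine = ["POF"] * 6 + ["POI"] * 5 + ["DOR"] * 6 + ["Healthy"] * 8
        reference = (["POF"] * 4 + ["POI"] * 2 + ["POI"] * 4 + ["DOR"] * 1
                     + ["DOR"] * 5 + ["Healthy"] * 1 + ["Healthy"] * 7 + ["DOR"] * 1)
        out = diagnosis_agreement(machine, reference)
        assert out["kappa"] == pytest.approx(_kappa_from_matrix(out["confusion_matrix"]))

    def test_risk_level_sensitivity_counts_high_risk_as_positive(self):
        machine = ["Healthy", "DOR", "Healthy", "POF"]
        reference = ["DOR", "DOR", "Healthy", "POF"]
        out = diagnosis_agreement(machine, reference)
        assert out["sensitivity"] == pytest.approx(2 / 3)
        assert out["accuracy"] == pytest.approx(3 / 4)


class TestMissingness:
    def test_counts_and_moments(self):
        docs = [
            EMRDocument("a", "x", gold=(_gold(C.FSH, 5.0, (0, 1), D0),)),
            EMRDocument("b", "x", gold=()),
        ]
        table = summarize_missingness(docs, concepts=(C.FSH,)).iloc[0]
        assert table.absent == 1 and table.n_values == 1
        assert table["mean"] == 5.0 and table["variance"] == 0.0

    def test_all_missing_concept_counts_every_doc(self):
        docs = [EMRDocument(str(i), "x", gold=()) for i in range(4)]
        assert summarize_missingness(docs, concepts=(C.AMH,)).iloc[0].absent == 4
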