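"""Cohort evaluation: confusion matrices, ratio metrics, ROC/AUC,
concordance.  The AUC route is held to the brute-force pairwise
Mann-Whitney oracle and cross-checked against scikit-learn."""

import numpy as np
import pytest

from cscc_bn.evaluate import (
    ConfusionMatrix,
    PatientRecord,
    compute_metrics,
    concordance,
    confusion_for_node,
    metrics_report,
    predict_cohort,
    roc_auc,
)
from cscc_bn.network import ModelError
from cscc_bn.reference import CaseEvidence


def _record(pid, case, surgery=False, cemiplimab=False, excluded=False):
    return PatientRecord(pid, case, surgery, cemiplimab, excluded)


ADVANCED = CaseEvidence("cSCC", "T4a", "N3", "M0", "positive", "positive")
EARLY = CaseEvidence("cSCC", "T1", "N0", "M0")


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise concordance: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_back_solved_cemiplimab_confusion_matrix(self):
        """tp=9, fn=2, tn=54, fp=1 over 66 records: the three ratios are
        9/11, 54/55 and 63/66."""
        m = compute_metrics(ConfusionMatrix(tp=9, fp=1, tn=54, fn=2))
        assert m.sensitivity == pytest.approx(9 / 11)
        assert m.specificity == pytest.approx(54 / 55)
        assert m.accuracy == pytest.approx(63 / 66)
        assert round(100 * m.sensitivity, 1) == 81.8
        assert round(100 * m.specificity, 1) == 98.2
        assert round(100 * m.accuracy, 1) == 95.5

    def test_perfect_two_record_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=1, fp=0, tn=1, fn=0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_zero_denominator_flagged_not_nan(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=3, tn=5, fn=0))
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(5 / 8)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ModelError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", range(10))
    def test_accuracy_decomposes_by_prevalence(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        tp, fp, tn, fn = (int(rng.integers(1, 50)) for _ in range(4))
        cm = ConfusionMatrix(tp, fp, tn, fn)
        m = compute_metrics(cm)
        prevalence = (tp + fn) / cm.total
        assert m.accuracy == pytest.approx(
            m.sensitivity * prevalence + m.specificity * (1 - prevalence), abs=1e-12
        )


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert r.auc == 1.0
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)

    def test_all_ties_give_half(self):
        r = roc_auc([0.5, 0.5, 0.5, 0.5], [True, False, True, False])
        assert r.auc == pytest.approx(0.5, abs=1e-15)

    def test_three_of_four_pairs_concordant(self):
        r = roc_auc([0.9, 0.8, 0.4, 0.3], [True, False, True, False])
        assert r.auc == pytest.approx(0.75, abs=1e-15)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([0.2, 0.4], [True, True])

    def test_curve_is_monotone(self):
        rng = np.random.Generator(np.random.PCG64(3))
        scores = rng.random(50).round(1)  # force ties
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        r = roc_auc(list(scores), list(labels))
        xs, ys = zip(*r.points)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))

    @pytest.mark.parametrize("seed", range(100))
    def test_trapezoid_equals_pairwise_concordance(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        n = int(rng.integers(4, 40))
        scores = list(rng.random(n).round(2))  # duplicates likely
        labels = list(rng.random(n) < rng.uniform(0.2, 0.8))
        if not any(labels):
            labels[0] = True
        if all(labels):
            labels[-1] = False
        assert roc_auc(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )

    def test_matches_scikit_learn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.Generator(np.random.PCG64(11))
        for _ in range(20):
            scores = list(rng.random(30).round(2))
            labels = list(rng.random(30) < 0.5)
            if not any(labels):
                labels[0] = True
            if all(labels):
                labels[-1] = False
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestPredictCohort:
    def test_advanced_case_recommends_cemiplimab(self, reference_model):
        preds = predict_cohort(reference_model, [_record("p1", ADVANCED, cemiplimab=True)])
        assert preds[0].ok
        assert preds[0].recommendation.primary == "Cemiplimab"

    def test_empty_cohort(self, reference_model):
        assert predict_cohort(reference_model, []) == []

    def test_malformed_record_error_is_isolated(self, reference_model):
        records = [
            _record("good", EARLY, surgery=True),
            _record("bad", CaseEvidence("cSCC", "T1", "N9", "M0"), surgery=True),
            _record("good2", ADVANCED, cemiplimab=True),
        ]
        preds = predict_cohort(reference_model, records)
        assert preds[0].ok and preds[2].ok
        assert not preds[1].ok and "N9" in preds[1].error


class TestConfusion:
    def test_all_correct_four_record_fixture(self, reference_model):
        records = [
            _record("p1", ADVANCED, cemiplimab=True),
            _record("p2", EARLY, surgery=True),
            _record("p3", CaseEvidence("cSCC", "T2", "N0", "M0"), surgery=True),
            _record("p4", CaseEvidence("BCC", "T1", "N0", "M0"), surgery=True),
        ]
        preds = predict_cohort(reference_model, records)
        cm = confusion_for_node(preds, records, "Cemiplimab")
        assert cm.tp + cm.tn == 4 and cm.fp == cm.fn == 0

    def test_threshold_zero_predicts_everything_positive(self, reference_model):
        records = [
            _record("p1", ADVANCED, cemiplimab=True),
            _record("p2", EARLY, surgery=True),
        ]
        preds = predict_cohort(reference_model, records)
        cm = confusion_for_node(preds, records, "Cemiplimab", mode="threshold", threshold=0.0)
        assert cm.fn == cm.tn == 0
        m = compute_metrics(cm)
        assert m.specificity == 0.0

    def test_unknown_node_rejected(self, reference_model):
        with pytest.raises(ModelError):
            confusion_for_node([], [], "Radiotherapy")


class TestConcordance:
    def test_all_agree_fixture(self, reference_model):
        records = [_record(f"p{i}", EARLY, surgery=True) for i in range(5)]
        preds = predict_cohort(reference_model, records)
        result = concordance(preds, records)
        assert result.matched == 5 and result.discordant == []

    def test_audited_discordant_patient_is_reported_with_posteriors(self, reference_model):
        # cSCC T2 N0 M0, PD-L1 unknown, administered Cemiplimab: the model
        # backs surgery at 90% vs Cemiplimab 5%, so the record is discordant
        rec = _record("A", CaseEvidence("cSCC", "T2", "N0", "M0"), cemiplimab=True)
        preds = predict_cohort(reference_model, [rec])
        result = concordance(preds, [rec])
        assert result.matched == 0 and len(result.discordant) == 1
        audit = result.discordant[0]
        assert audit["model_primary"] == "Surgery"
        assert audit["surgery_percent"] == 90
        assert audit["cemiplimab_percent"] == 5

    def test_both_flags_count_first_line_surgery(self, reference_model):
        # surgery first, systemic therapy later: first-line is surgery
        rec = _record("C", CaseEvidence("cSCC", "T3", "N2", "M0"), surgery=True, cemiplimab=True)
        preds = predict_cohort(reference_model, [rec])
        result = concordance(preds, [rec])
        # model prefers Cemiplimab (80% vs 70%): discordant with first-line surgery
        assert result.matched == 0
        assert result.discordant[0]["administered_first_line"] == "Surgery"

    def test_empty_cohort(self):
        result = concordance([], [])
        assert result.matched == 0 and result.discordant == []


class TestMetricsReport:
    def test_report_shape_and_consistency(self, reference_model):
        records = [
            _record("p1", ADVANCED, cemiplimab=True),
            _record("p2", EARLY, surgery=True),
            _record("p3", CaseEvidence("cSCC", "T2", "N0", "M0"), surgery=True),
        ]
        report = metrics_report(reference_model, records)
        assert report["n_records"] == 3 and report["n_errors"] == 0
        assert report["Cemiplimab"]["tp"] == 1
        assert report["overall_accuracy"] == 1.0
        assert report["cemiplimab_auc"] == 1.0
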