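"""Confusion-matrix metrics, ROC/AUC/Youden, and the two-level evaluation.

ROC and Youden are checked against exhaustive pairwise-comparison and
brute-force J-maximization oracles, and cross-checked against
scikit-learn's independent implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from lorenzaf import (BeatClass, ConfusionMatrix, RecordAggregation,
                      RecordClass, ThresholdSet, auc, calibrate_thresholds,
                      classification_metrics, classify_record,
                      confusion_matrix, evaluate_two_level, record_score,
                      roc_curve, youden_cutoff)

# The published validation confusion matrices this implementation must
# reproduce metric-for-metric at 3-decimal rounding.
INTERNAL_CM = ConfusionMatrix(tp=66509, fn=514, fp=1791, tn=65771)
INTERNAL_ROW = dict(sensitivity=0.992, specificity=0.973, accuracy=0.983,
                    ppv=0.974, npv=0.992, lr_plus=37.434, lr_minus=0.008)
EXTERNAL_CM = ConfusionMatrix(tp=66492, fn=771, fp=6128, tn=134099)
EXTERNAL_ROW = dict(sensitivity=0.989, specificity=0.956, accuracy=0.967,
                    ppv=0.916, npv=0.994, lr_plus=22.621, lr_minus=0.012)


def pairwise_auc_oracle(scores, labels):
    """AUC as P(score_AF > score_nonAF) + 0.5*P(tie) over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Brute-force J maximization over candidate thresholds (observed
    scores plus the all-negative sentinel), in exact rational arithmetic;
    ties resolved toward the higher threshold."""
    from fractions import Fraction
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    best_j, best_t = None, None
    candidates = set(scores.tolist()) | {scores.max() + 1.0}   # all-negative rule
    for t in sorted(candidates, reverse=True):
        pred = scores >= t
        j = (Fraction(int((pred & labels).sum()), int(labels.sum()))
             + Fraction(int((~pred & ~labels).sum()), int((~labels).sum())) - 1)
        if best_j is None or j > best_j:
            best_j, best_t = j, t
    return best_t, float(best_j)


class TestConfusionMatrix:
    def test_counts_partition_input(self):
        t = [1, 1, 0, 0, 1, 0]
        p = [1, 0, 1, 0, 1, 0]
        cm = confusion_matrix(t, p)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)
        assert cm.total == 6

    def test_all_correct_has_no_errors(self):
        cm = confusion_matrix([BeatClass.AF, BeatClass.NON_AF],
                              [BeatClass.AF, BeatClass.NON_AF])
        assert cm.fn == cm.fp == 0

    def test_published_internal_matrix_from_label_vectors(self):
        t = [1] * (66509 + 514) + [0] * (1791 + 65771)
        p = [1] * 66509 + [0] * 514 + [1] * 1791 + [0] * 65771
        assert confusion_matrix(t, p) == INTERNAL_CM

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 0], [1])


class TestClassificationMetrics:
    @pytest.mark.parametrize("cm, row", [(INTERNAL_CM, INTERNAL_ROW),
                                         (EXTERNAL_CM, EXTERNAL_ROW)])
    def test_reproduces_published_validation_rows(self, cm, row):
        got = classification_metrics(cm).rounded(3)
        for key, want in row.items():
            assert got[key] == want, key

    def test_perfect_matrix_has_na_positive_lr(self):
        rep = classification_metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert rep.lr_plus is None          # NA: division by 1 - Spe = 0
        assert rep.lr_minus == 0.0

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_metric_identities(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        cm = ConfusionMatrix(tp, fn, fp, tn)
        rep = classification_metrics(cm)
        assert rep.accuracy == pytest.approx((tp + tn) / cm.total)
        if rep.lr_plus is not None:
            assert rep.lr_plus * (1 - rep.specificity) == pytest.approx(rep.sensitivity)
        if rep.lr_minus is not None and rep.sensitivity is not None:
            assert rep.lr_minus * rep.specificity == pytest.approx(1 - rep.sensitivity)


class TestROC:
    def test_perfect_separation_auc_one(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc(curve) == 1.0

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert auc(roc_curve(scores, labels)) == pytest.approx(0.5, abs=0.03)

    def test_six_point_hand_example_matches_pair_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert auc(roc_curve(scores, labels)) == pytest.approx(
            pairwise_auc_oracle(scores, labels), abs=1e-12)

    def test_matches_sklearn_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 10, n) / 10.0   # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(roc_curve(scores, labels)) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = rng.random(200) < 0.4
        a = auc(roc_curve(scores, labels))
        b = auc(roc_curve(np.exp(3 * scores), labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(3)
        curve = roc_curve(rng.random(100), rng.random(100) < 0.5)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)


class TestYouden:
    def test_perfect_separation_picks_largest_qualifying_threshold(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert youden_cutoff(curve) == 0.8   # smallest positive score

    def test_hand_example_matches_brute_force(self):
        scores = [0.05, 0.2, 0.3, 0.35, 0.5, 0.6, 0.8, 0.9]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        t_oracle, _ = youden_oracle(scores, labels)
        assert youden_cutoff(roc_curve(scores, labels)) == t_oracle

    def test_returned_cutoff_maximizes_j_everywhere(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 8, n) / 8.0
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = roc_curve(scores, labels)
            t = youden_cutoff(curve)
            j_at = curve.tpr - curve.fpr
            k = int(np.flatnonzero(curve.thresholds == t)[0])
            assert j_at[k] == pytest.approx(j_at.max(), abs=1e-12)
            t_oracle, j_oracle = youden_oracle(scores, labels)
            assert t == t_oracle and j_at[k] == pytest.approx(j_oracle, abs=1e-12)


class TestRecordDecision:
    def test_record_score_examples(self):
        assert record_score([0.1, 0.2, 0.3], 0.61) == 0.0
        assert record_score([0.9, 0.8, 0.7, 0.1], 0.61) == 0.75

    def test_record_score_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = rng.random(int(rng.integers(1, 30)))
            cut = float(rng.random())
            assert record_score(s, cut) == sum(1 for x in s if x >= cut) / len(s)

    def test_mean_score_aggregation_alternative(self):
        assert record_score([0.2, 0.4], 0.61, RecordAggregation.MEAN_SCORE) \
            == pytest.approx(0.3)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            record_score([], 0.5)

    def test_three_way_rule_with_published_cutoffs(self):
        """Half-open intervals: burden >= 0.007 is AF, >= 0.948 persistent."""
        ts = ThresholdSet(ls_cutoff=0.610, record_af_cutoff=0.007,
                          persistent_cutoff=0.948)
        assert classify_record(0.0, ts) is RecordClass.NON_AF
        assert classify_record(0.0069, ts) is RecordClass.NON_AF
        assert classify_record(0.007, ts) is RecordClass.PAROXYSMAL_AF
        assert classify_record(0.5, ts) is RecordClass.PAROXYSMAL_AF
        assert classify_record(0.948, ts) is RecordClass.PERSISTENT_AF
        assert classify_record(1.0, ts) is RecordClass.PERSISTENT_AF

    def test_out_of_range_fraction_rejected(self):
        ts = ThresholdSet(0.5, 0.1, 0.9)
        with pytest.raises(ValueError):
            classify_record(1.2, ts)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ThresholdSet(ls_cutoff=0.5, record_af_cutoff=0.9, persistent_cutoff=0.3)


class TestCalibration:
    def disjoint_setup(self):
        """Image scores and record fractions with fully disjoint classes."""
        img_scores = [0.9, 0.85, 0.8, 0.15, 0.1, 0.05]
        img_labels = [1, 1, 1, 0, 0, 0]
        truths = [RecordClass.NON_AF, RecordClass.NON_AF,
                  RecordClass.PAROXYSMAL_AF, RecordClass.PAROXYSMAL_AF,
                  RecordClass.PERSISTENT_AF, RecordClass.PERSISTENT_AF]
        fractions = [0.0, 0.02, 0.4, 0.5, 0.97, 1.0]
        return img_scores, img_labels, fractions, truths

    def test_recovers_separating_thresholds(self):
        img_scores, img_labels, fractions, truths = self.disjoint_setup()
        ts = calibrate_thresholds(img_scores, img_labels,
                                  lambda cut: fractions, truths)
        assert 0.15 < ts.ls_cutoff <= 0.8
        assert 0.02 < ts.record_af_cutoff <= 0.4
        assert 0.5 < ts.persistent_cutoff <= 0.97
        assert ts.record_af_cutoff <= ts.persistent_cutoff
        # recovered thresholds separate the records perfectly
        preds = [classify_record(f, ts) for f in fractions]
        assert preds == truths

    def test_single_class_at_record_level_rejected(self):
        img_scores, img_labels, fractions, _ = self.disjoint_setup()
        with pytest.raises(ValueError):
            calibrate_thresholds(img_scores, img_labels, lambda cut: fractions,
                                 [RecordClass.PERSISTENT_AF] * 6)


class TestTwoLevel:
    def test_published_internal_matrix_yields_published_row(self):
        """Scores/labels constructed to reproduce the internal validation
        confusion matrix must give back the published image-level row."""
        cm = INTERNAL_CM
        labels = np.concatenate([np.ones(cm.tp + cm.fn), np.zeros(cm.fp + cm.tn)])
        scores = np.concatenate([
            np.full(cm.tp, 0.99), np.full(cm.fn, 0.01),
            np.full(cm.fp, 0.99), np.full(cm.tn, 0.01)])
        ts = ThresholdSet(0.61, 0.007, 0.948)
        report = evaluate_two_level(
            scores, labels, ts,
            record_scores={"a": [0.9], "b": [0.01]},
            record_truths={"a": RecordClass.PERSISTENT_AF,
                           "b": RecordClass.NON_AF})
        got = report.image_level.rounded(3)
        for key, want in INTERNAL_ROW.items():
            assert got[key] == want, key
        assert report.image_level.confusion == cm

    def test_one_vs_rest_counts_sum_to_n_records(self):
        ts = ThresholdSet(0.5, 0.1, 0.9)
        rec_scores = {f"r{i}": [0.9] * i + [0.1] * (10 - i) for i in range(11)}
        truths = {f"r{i}": (RecordClass.NON_AF if i == 0 else
                            RecordClass.PERSISTENT_AF if i >= 9 else
                            RecordClass.PAROXYSMAL_AF) for i in range(11)}
        scores = [0.9, 0.1]
        labels = [1, 0]
        report = evaluate_two_level(scores, labels, ts, rec_scores, truths)
        for rep in report.record_level.values():
            assert rep.confusion.total == 11
        assert 0.0 <= report.record_accuracy <= 1.0

    def test_empty_evaluation_rejected(self):
        ts = ThresholdSet(0.5, 0.1, 0.9)
        with pytest.raises(ValueError):
            evaluate_two_level([], [], ts, {}, {})
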