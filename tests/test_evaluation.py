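"""Metric and bootstrap contracts, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fedbench as fb
from fedbench.evaluation import (
    UndefinedMetricError,
    auprc,
    auroc,
    bootstrap_ci,
    bootstrap_report,
    evaluate,
    prf_confusion,
    write_report,
)


def _auroc_pairs(scores, labels):
    """Independent oracle: pairwise concordance with ties counting 1/2."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


def _auprc_thresholds(scores, labels):
    """Independent oracle: step-wise integration over every score threshold."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    n_pos = labels.sum()
    cut_scores = scores[order]
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and cut_scores[j] == cut_scores[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_no_signal_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(auroc(scores, labels) - 0.5) < 0.03

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        scores = np.round(rng.random(n), 1)  # coarse grid provokes ties
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        assert auroc(scores, labels) == pytest.approx(_auroc_pairs(scores, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        assert auroc(np.exp(5 * scores), labels) == pytest.approx(auroc(scores, labels))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])


class TestPrf:
    def test_identity_predictions_all_ones(self):
        labels = np.array([0, 1, 2, 2, 1, 0])
        out = prf_confusion(labels, labels, n_classes=3)
        assert np.array_equal(out["confusion_matrix"], np.diag([2, 2, 2]))
        assert out["macro_f1"] == out["macro_precision"] == out["macro_recall"] == 1.0

    def test_hand_computed_binary_counts(self):
        # TP=3, FP=1, FN=2, TN=4 for the positive class
        labels = np.array([1] * 5 + [0] * 5)
        pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        out = prf_confusion(pred, labels, n_classes=2)
        per = out["per_class"].loc[1]
        assert per["precision"] == pytest.approx(0.75)
        assert per["recall"] == pytest.approx(0.6)
        assert per["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_confusion_matrix_conserves_count(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(1, 60)), int(rng.integers(2, 6))
        labels = rng.integers(0, k, n)
        pred = rng.integers(0, k, n)
        out = prf_confusion(pred, labels, n_classes=k)
        assert out["confusion_matrix"].sum() == n

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        perm = np.array([2, 3, 0, 1])
        a = prf_confusion(pred, labels, n_classes=4)["macro_f1"]
        b = prf_confusion(perm[pred], perm[labels], n_classes=4)["macro_f1"]
        assert a == pytest.approx(b)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(2)
        n, p = 5000, 0.2
        labels = (rng.random(n) < p).astype(int)
        assert abs(auprc(rng.random(n), labels) - p) < 0.05

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_threshold_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        scores = rng.random(n)
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 2)] = 1
        rng.shuffle(labels)
        assert auprc(scores, labels) == pytest.approx(_auprc_thresholds(scores, labels))

    def test_no_positive_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auprc([0.5, 0.6], [0, 0])


def _accuracy(scores, labels):
    return float((np.asarray(scores).argmax(axis=1) == np.asarray(labels)).mean())


class TestBootstrap:
    def test_exactly_k_replicates_recorded(self):
        rng = np.random.default_rng(0)
        scores = rng.random((40, 2))
        labels = rng.integers(0, 2, 40)
        b = bootstrap_ci(_accuracy, scores, labels, K=100, seed=1)
        assert b.K == 100 and len(b.replicates) == 100
        assert b.ci_low <= b.ci_high

    def test_constant_metric_collapses_interval(self):
        scores = np.tile([0.2, 0.8], (10, 1))
        labels = np.ones(10, dtype=int)
        b = bootstrap_ci(_accuracy, scores, labels, K=50, seed=0)
        assert b.ci_low == b.ci_high == b.point == 1.0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        scores = rng.random((30, 2))
        labels = rng.integers(0, 2, 30)
        a = bootstrap_ci(_accuracy, scores, labels, K=64, seed=9)
        b = bootstrap_ci(_accuracy, scores, labels, K=64, seed=9)
        assert np.array_equal(a.replicates, b.replicates)

    def test_degenerate_resamples_are_redrawn(self):
        """With one positive in 12 records, many resamples drop the positive
        class entirely; AUROC bootstrap must still complete by redrawing."""
        rng = np.random.default_rng(5)
        scores = rng.random(12)
        labels = np.zeros(12, dtype=int)
        labels[3] = 1
        b = bootstrap_ci(lambda s, l: auroc(s, l), scores, labels, K=200, seed=2)
        assert len(b.replicates) == 200
        assert np.isfinite(b.replicates).all()

    def test_coverage_of_bernoulli_accuracy(self):
        """Percentile-CI coverage of a known true accuracy stays near the
        nominal 95% (Monte-Carlo band for 300 repetitions)."""
        p_true, n, reps = 0.9, 100, 300
        rng = np.random.default_rng(123)
        scores = np.tile([0.0, 1.0], (n, 1))  # always predicts class 1
        cover = 0
        for r in range(reps):
            labels = (rng.random(n) < p_true).astype(int)
            b = bootstrap_ci(_accuracy, scores, labels, K=199, seed=r)
            cover += b.ci_low <= p_true <= b.ci_high
        assert 0.89 <= cover / reps <= 0.995


def test_evaluate_full_report_and_writer(tmp_path):
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 2, 120)
    scores = np.column_stack([1 - labels * 0.6 - 0.2, labels * 0.6 + 0.2])
    scores += rng.normal(0, 0.05, scores.shape)
    scores = np.abs(scores)
    scores /= scores.sum(axis=1, keepdims=True)
    report = evaluate(scores, labels, n_classes=2)
    assert report.confusion_matrix.sum() == 120
    assert 0 <= report.macro_f1 <= 1 and 0 <= report.auroc_macro <= 1
    assert report.auprc is not None
    boots = bootstrap_report(scores, labels, K=25, seed=0)
    assert set(boots) == {"auroc", "macro_f1", "accuracy", "auprc"}
    assert all(b.K == 25 for b in boots.values())
    write_report(tmp_path, report, boots)
    assert (tmp_path / "metrics.json").exists()
    assert (tmp_path / "metrics.csv").exists()
    assert (tmp_path / "confusion_matrix.csv").exists()
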