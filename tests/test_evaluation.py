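"""Metric suite: pixel metrics, ROC-AUC, IoU, average precision, RMSE."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hyotrack import (average_precision, distance_rmse, iou,
                      mean_average_precision, pixel_metrics, roc_auc)
from hyotrack.evaluation import PixelConfusion, metrics_from_confusion


class TestPixelMetrics:
    def test_identical_masks_all_ones(self):
        m = np.random.default_rng(0).integers(0, 4, (3, 16, 16))
        out = pixel_metrics(m, m)
        for cls in ("hyoid", "spine", "coin", "pooled"):
            for v in out[cls].values():
                assert v == pytest.approx(1.0)

    def test_disjoint_positives_zero_overlap(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[:4] = 1
        pred = np.zeros((8, 8), np.uint8)
        pred[4:] = 1
        out = pixel_metrics(pred, truth)["hyoid"]
        assert out["recall"] == out["precision"] == out["dice"] == 0.0

    def test_counting_oracle_half_overlap(self):
        # truth: 100 positives; prediction covers 50 of them plus 50 FP
        truth = np.zeros((20, 20), np.uint8)
        truth.ravel()[:100] = 1
        pred = np.zeros((20, 20), np.uint8)
        pred.ravel()[50:150] = 1
        out = pixel_metrics(pred, truth)["hyoid"]
        assert out["recall"] == pytest.approx(0.5)
        assert out["precision"] == pytest.approx(0.5)
        assert out["dice"] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_empty_class_sentinels(self):
        empty = np.zeros((4, 4), np.uint8)
        out = pixel_metrics(empty, empty)["hyoid"]
        assert out["recall"] == out["precision"] == out["dice"] == 1.0

    @given(tp=st.integers(1, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_dice_is_harmonic_mean_of_precision_recall(self, tp, fp, fn):
        m = metrics_from_confusion(PixelConfusion(tp=tp, fp=fp, fn=fn, tn=10))
        p, r = m["precision"], m["recall"]
        assert m["dice"] == pytest.approx(2 * p * r / (p + r))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1])) == 1.0

    def test_constant_scores_are_chance(self):
        assert roc_auc(np.full(10, 0.5), np.arange(10) % 2) == pytest.approx(0.5)

    def test_four_point_pair_enumeration_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # independent oracle: count concordant positive-negative pairs
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(0.5 if p == n else float(p > n)
                   for p, n in itertools.product(pos, neg))
        expected = wins / (len(pos) * len(neg))
        assert expected == 0.75
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_inverted_scores_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        a = roc_auc(scores, labels)
        b = roc_auc(-scores, labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_one_seventh_overlap(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_degenerate_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert iou((0, 0, 0, 4), (0, 0, 2, 2)) == 0.0


class TestAveragePrecision:
    def test_perfect_detections(self):
        dets = [(t, (0, 0, 4, 4), 0.9) for t in range(5)]
        truths = [(t, (0, 0, 4, 4)) for t in range(5)]
        assert average_precision(dets, truths) == pytest.approx(1.0)

    def test_no_detections_zero(self):
        assert average_precision([], [(0, (0, 0, 4, 4))]) == 0.0

    def test_one_truth_miss_then_hit(self):
        # higher-confidence detection misses (IoU < 0.5), lower one hits
        truths = [(0, (0, 0, 10, 10))]
        dets = [(0, (20, 20, 30, 30), 0.9), (0, (0, 0, 10, 10), 0.6)]
        assert average_precision(dets, truths) == pytest.approx(0.5)

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            average_precision([(0, (0, 0, 1, 1), 0.5)], [])

    def test_duplicate_detection_counts_once(self):
        truths = [(0, (0, 0, 10, 10))]
        dets = [(0, (0, 0, 10, 10), 0.9), (0, (0, 0, 10, 10), 0.8)]
        # second detection cannot re-claim the matched truth -> one TP, one FP
        assert average_precision(dets, truths) == pytest.approx(1.0)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-2.0, 2.0))
    def test_invariant_to_monotone_confidence_transform(self, a, b):
        truths = [(t, (0, 0, 10, 10)) for t in range(4)]
        dets = [(0, (0, 0, 10, 10), 0.9), (1, (30, 30, 40, 40), 0.7),
                (2, (0, 0, 10, 10), 0.5), (3, (0, 1, 10, 11), 0.3)]
        transformed = [(t, box, a * c + b) for t, box, c in dets]
        assert (average_precision(dets, truths)
                == pytest.approx(average_precision(transformed, truths)))

    def test_map_is_mean_of_class_aps(self):
        truths = {1: [(0, (0, 0, 10, 10))], 2: [(0, (20, 0, 40, 30))],
                  3: [(0, (50, 50, 60, 60))]}
        dets = {1: [(0, (0, 0, 10, 10), 0.9)],
                2: [(0, (25, 0, 45, 30), 0.8)],
                3: []}
        m, per_class = mean_average_precision(dets, truths)
        assert m == pytest.approx(np.mean(list(per_class.values())))
        assert per_class["hyoid"] == pytest.approx(1.0)
        assert per_class["coin"] == 0.0


class TestDistanceRmse:
    def test_identical_zero(self):
        assert distance_rmse([0, 1, 2], [1.0, 2.0, 3.0], [0, 1, 2], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        pred = [3.0, 4.0, 5.0]
        truth = [1.0, 2.0, 3.0]
        assert distance_rmse([0, 1, 2], pred, [0, 1, 2], truth) == pytest.approx(2.0)

    def test_two_frame_arithmetic_oracle(self):
        got = distance_rmse([0, 1], [3.0, -4.0], [0, 1], [0.0, 0.0])
        assert got == pytest.approx(np.sqrt(25 / 2), abs=1e-9)

    def test_alignment_uses_frame_intersection(self):
        got = distance_rmse([0, 2, 5], [1.0, 2.0, 9.0], [2, 5, 7], [2.0, 5.0, 0.0])
        assert got == pytest.approx(np.sqrt((0 ** 2 + 4 ** 2) / 2))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            distance_rmse([0, 1], [1.0, 2.0], [2, 3], [1.0, 2.0])
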