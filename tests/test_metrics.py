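import itertools

import pytest

from grapedet.boxes import BoundingBox
from grapedet.inference import Detection
from grapedet.metrics import (area_under_points, average_precision, evaluate,
                              match_detections, pr_curve_points, precision_recall_f1)

# printed fog-scene confusion counts and scores for nine detectors:
# (TP, FP, FN) -> precision %, recall %, F1 %
FOG_TABLE = [
    (21, 0, 3, 100.00, 87.50, 93.33),
    (16, 3, 8, 84.21, 66.67, 74.42),
    (11, 0, 13, 100.00, 45.83, 62.86),
    (11, 0, 13, 100.00, 45.83, 62.86),
    (10, 0, 14, 100.00, 41.67, 58.82),
    (12, 5, 12, 70.59, 50.00, 58.54),
    (11, 7, 13, 61.11, 45.83, 52.38),
    (8, 0, 16, 100.00, 33.33, 50.00),
    (7, 1, 17, 87.50, 29.17, 43.75),
]


def _det(x, y, w, h, score):
    return Detection(BoundingBox(x, y, x + w, y + h), score)


def _gt(x, y, w, h):
    return BoundingBox(x, y, x + w, y + h)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize("tp,fp,fn,p,r,f1", FOG_TABLE)
    def test_published_confusion_counts_reproduce_metrics(self, tp, fp, fn, p, r, f1):
        P, R, F1 = precision_recall_f1(tp, fp, fn)
        assert round(P * 100, 2) == p
        assert round(R * 100, 2) == r
        assert round(F1 * 100, 2) == f1

    def test_all_missed(self):
        P, R, F1 = precision_recall_f1(0, 5, 5, zero_division=0.0)
        assert (P, R, F1) == (0.0, 0.0, 0.0)

    def test_zero_denominator_raises_without_policy(self):
        with pytest.raises(ZeroDivisionError):
            precision_recall_f1(0, 0, 5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)


class TestMatching:
    def test_perfect_detections(self):
        gts = [_gt(0, 0, 10, 10), _gt(30, 30, 10, 10)]
        dets = [_det(0, 0, 10, 10, 0.9), _det(30, 30, 10, 10, 0.8)]
        res = match_detections(dets, gts)
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)

    def test_no_detections(self):
        res = match_detections([], [_gt(0, 0, 10, 10)])
        assert (res.tp, res.fp, res.fn) == (0, 0, 1)

    def test_duplicate_detection_penalized(self):
        gts = [_gt(0, 0, 10, 10)]
        dets = [_det(0, 0, 10, 10, 0.9), _det(0.5, 0, 10.5, 10, 0.8)]
        res = match_detections(dets, gts)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_class_aware(self):
        gts = [BoundingBox(0, 0, 10, 10, "syrah")]
        dets = [Detection(BoundingBox(0, 0, 10, 10, "chardonnay"), 0.9, "chardonnay")]
        res = match_detections(dets, gts)
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)


def ap_by_hand(flags, n_gt):
    """Independent all-point-interpolated AP from an ordered TP/FP sequence."""
    best = 0.0
    ap = 0.0
    tp = 0
    points = []
    for rank, flag in enumerate(flags, 1):
        tp += int(flag)
        points.append((tp / n_gt, tp / rank))
    prev_recall = 0.0
    for recall, _ in points:
        precision_at_least = max(p for r, p in points if r >= recall - 1e-12)
        ap += (recall - prev_recall) * precision_at_least
        prev_recall = recall
    return ap


class TestAveragePrecision:
    def test_single_correct_detection(self):
        dets = {"im": [_det(0, 0, 10, 10, 0.9)]}
        gts = {"im": [_gt(0, 0, 10, 10)]}
        assert average_precision(dets, gts) == pytest.approx(1.0)

    def test_tp_fp_tp_rank_pattern(self):
        """Ranks [TP, FP, TP] over 2 GTs: AP = 0.5*1 + 0.5*(2/3)."""
        dets = {"im": [
            _det(0, 0, 10, 10, 0.9),      # TP
            _det(60, 60, 10, 10, 0.8),    # FP (no GT there)
            _det(30, 30, 10, 10, 0.7),    # TP
        ]}
        gts = {"im": [_gt(0, 0, 10, 10), _gt(30, 30, 10, 10)]}
        assert average_precision(dets, gts) == pytest.approx(0.5 + 0.5 * 2 / 3)
        assert average_precision(dets, gts) == pytest.approx(0.8333, abs=5e-5)

    def test_matches_exhaustive_ordering_oracle(self, rng):
        """Every permutation of <=5 detections agrees with a hand-rolled AP."""
        gts = {"im": [_gt(i * 20, 0, 10, 10) for i in range(3)]}
        base = [(0, True), (1, True), (60, False), (2, True), (75, False)]
        for perm in itertools.permutations(range(5)):
            dets = []
            for rank, idx in enumerate(perm):
                pos, is_tp = base[idx]
                x = pos * 20 if is_tp else pos
                dets.append(_det(x, 0, 10, 10, 0.9 - 0.1 * rank))
            got = average_precision({"im": dets}, gts)
            flags = [base[idx][1] for idx in perm]
            assert got == pytest.approx(ap_by_hand(flags, 3), abs=1e-12)

    def test_invariant_to_image_partitioning(self):
        dets = [_det(0, 0, 10, 10, 0.9), _det(30, 30, 10, 10, 0.7),
                _det(60, 60, 10, 10, 0.5)]
        gts = [_gt(0, 0, 10, 10), _gt(30, 30, 10, 10), _gt(90, 90, 10, 10)]
        one = average_precision({"a": dets}, {"a": gts})
        two = average_precision({"a": dets[:2], "b": dets[2:]},
                                {"a": gts[:2], "b": gts[2:]})
        assert one == pytest.approx(two)

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision({"im": []}, {"im": []})


class TestPrCurve:
    def test_perfect_detector_single_point(self):
        dets = {"im": [_det(0, 0, 10, 10, 0.9)]}
        gts = {"im": [_gt(0, 0, 10, 10)]}
        assert pr_curve_points(dets, gts) == [(1.0, 1.0)]

    def test_recall_nondecreasing(self, rng):
        gts = {"im": [_gt(i * 20, 0, 10, 10) for i in range(5)]}
        dets = {"im": [_det(i * 20 + rng.uniform(-3, 3), 0, 10, 10,
                            float(rng.uniform(0.3, 1))) for i in range(8)]}
        points = pr_curve_points(dets, gts)
        recalls = [r for r, _ in points]
        assert recalls == sorted(recalls)

    def test_area_under_curve_equals_ap(self, rng):
        gts = {"im": [_gt(5 + i * 25, 5, 12, 12) for i in range(4)]}
        dets = {"im": [_det(5 + i * 25 + rng.uniform(-4, 4), 5 + rng.uniform(-2, 2),
                            12, 12, float(rng.uniform(0.2, 1))) for i in range(7)]}
        ap = average_precision(dets, gts)
        area = area_under_points(pr_curve_points(dets, gts))
        assert area == pytest.approx(ap, abs=1e-9)


class TestEvaluateReport:
    def test_single_class_report(self):
        gts = {"im": [_gt(0, 0, 10, 10), _gt(30, 30, 10, 10)]}
        dets = {"im": [_det(0, 0, 10, 10, 0.9)]}
        report = evaluate(dets, gts)
        assert report["tp"] == 1 and report["fn"] == 1 and report["fp"] == 0
        assert report["map"] == pytest.approx(0.5)

    def test_multiclass_map_unweighted(self):
        gts = {"im": [BoundingBox(0, 0, 10, 10, "a"), BoundingBox(30, 30, 40, 40, "b")]}
        dets = {"im": [Detection(BoundingBox(0, 0, 10, 10, "a"), 0.9, "a")]}
        report = evaluate(dets, gts)
        assert report["classes"]["a"]["ap"] == pytest.approx(1.0)
        assert report["classes"]["b"]["ap"] == pytest.approx(0.0)
        assert report["map"] == pytest.approx(0.5)
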