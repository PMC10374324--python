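import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grapedet import nn
from grapedet.anchors import AnchorBox, AnchorSet
from grapedet.boxes import BoundingBox, ImageAnnotation
from grapedet.losses import (FocalConfig, LossConfig, build_targets, ciou_loss,
                             ciou_loss_xywh, classification_loss, confidence_loss,
                             focal_bce, total_loss)


def _bce(p, y):
    return -(y * math.log(p) + (1 - y) * math.log(1 - p))


class TestFocalBce:
    def test_perfect_prediction_near_zero(self):
        assert float(focal_bce(1 - 1e-7, 1)) == pytest.approx(0.0, abs=1e-5)
        assert float(focal_bce(1e-7, 0)) == pytest.approx(0.0, abs=1e-5)

    def test_hand_example(self):
        # y=1, p=0.5, alpha=0.75, gamma=2 -> 0.75 * 0.25 * ln 2
        v = float(focal_bce(0.5, 1, FocalConfig(alpha=0.75, gamma=2)))
        assert v == pytest.approx(0.75 * 0.25 * math.log(2), abs=1e-9)
        assert v == pytest.approx(0.1300, abs=5e-5)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99])
    @pytest.mark.parametrize("y", [0, 1])
    def test_gamma_zero_alpha_half_is_half_bce(self, p, y):
        v = float(focal_bce(p, y, FocalConfig(alpha=0.5, gamma=0)))
        assert v == pytest.approx(0.5 * _bce(p, y), rel=1e-9)

    def test_easy_examples_downweighted_more(self):
        cfg = FocalConfig(alpha=0.75, gamma=2)
        easy = float(focal_bce(0.9, 1, cfg)) / _bce(0.9, 1)
        hard = float(focal_bce(0.6, 1, cfg)) / _bce(0.6, 1)
        assert easy < hard

    def test_disabled_gives_plain_bce(self):
        cfg = FocalConfig(enabled=False)
        assert float(focal_bce(0.3, 1, cfg)) == pytest.approx(_bce(0.3, 1), rel=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FocalConfig(alpha=1.5)
        with pytest.raises(ValueError):
            FocalConfig(gamma=-1)


class TestCiou:
    def test_identical_boxes_zero(self):
        b = BoundingBox(3, 4, 30, 44)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # IoU = 1/7, rho^2 = 2, c^2 = 18, nu = 0 (same aspect)
        v = ciou_loss(BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 3, 3))
        assert v == pytest.approx(1 - 1 / 7 + 2 / 18, abs=1e-9)
        assert v == pytest.approx(0.9683, abs=5e-5)

    def test_same_aspect_ratio_drops_nu_term(self):
        pred = BoundingBox(0, 0, 10, 20)
        gt = BoundingBox(30, 30, 35, 40)  # both 1:2
        from grapedet.boxes import iou as iou_fn
        v = ciou_loss(pred, gt)
        rho2 = (5 - 32.5) ** 2 + (10 - 35) ** 2
        c2 = 35 ** 2 + 40 ** 2
        assert v == pytest.approx(1 - iou_fn(pred, gt) + rho2 / c2, abs=1e-9)

    @settings(max_examples=150, deadline=None)
    @given(px=st.floats(0, 50), py=st.floats(0, 50), pw=st.floats(1, 40), ph=st.floats(1, 40),
           gx=st.floats(0, 50), gy=st.floats(0, 50), gw=st.floats(1, 40), gh=st.floats(1, 40))
    def test_lower_bounded_by_iou_complement(self, px, py, pw, ph, gx, gy, gw, gh):
        v = float(ciou_loss_xywh(px, py, pw, ph, gx, gy, gw, gh))
        iw = max(min(px + pw / 2, gx + gw / 2) - max(px - pw / 2, gx - gw / 2), 0)
        ih = max(min(py + ph / 2, gy + gh / 2) - max(py - ph / 2, gy - gh / 2), 0)
        iou = iw * ih / (pw * ph + gw * gh - iw * ih)
        assert v >= 1 - iou - 1e-9

    def test_gradient_descent_converges_to_high_iou(self):
        """Optimizing one box toward a target reaches IoU > 0.99 in 500 steps."""
        from grapedet.boxes import iou as iou_fn
        params = [nn.Parameter(np.array(v)) for v in (10.0, 12.0, 8.0, 6.0)]
        gt = (30.0, 28.0, 14.0, 22.0)
        opt = nn.Adam(params, lr=0.1)
        for _ in range(500):
            opt.zero_grad()
            ciou_loss_xywh(*params, *gt).backward()
            opt.step()
        px, py, pw, ph = (float(p.data) for p in params)
        pred = BoundingBox(px - pw / 2, py - ph / 2, px + pw / 2, py + ph / 2)
        target = BoundingBox(23, 17, 37, 39)
        assert iou_fn(pred, target) > 0.99

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss(BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 1, 3))


class TestConfidenceLoss:
    def test_perfect_predictions_near_zero(self):
        obj = np.zeros((1, 1, 2, 2), dtype=bool)
        obj[0, 0, 0, 0] = True
        noobj = ~obj
        pred = np.where(obj, 1 - 1e-7, 1e-7)
        assert float(confidence_loss(nn.Tensor(pred), obj, noobj)) == pytest.approx(0, abs=1e-4)

    def test_empty_image_noobj_only(self, rng):
        obj = np.zeros((1, 1, 2, 2), dtype=bool)
        pred = rng.uniform(0.1, 0.9, size=(1, 1, 2, 2))
        full = float(confidence_loss(nn.Tensor(pred), obj, ~obj))
        manual = sum(float(focal_bce(p, 0)) for p in pred.ravel())
        assert full == pytest.approx(manual, rel=1e-9)

    def test_matches_explicit_loop_on_toy_grid(self, rng):
        obj = np.zeros((1, 1, 2, 2), dtype=bool)
        obj[0, 0, 1, 0] = True
        noobj = ~obj
        noobj[0, 0, 0, 1] = False  # one ignored cell
        pred = rng.uniform(0.05, 0.95, size=(1, 1, 2, 2))
        total = float(confidence_loss(nn.Tensor(pred), obj, noobj))
        manual = 0.0
        for j in range(2):
            for i in range(2):
                if obj[0, 0, j, i]:
                    manual += float(focal_bce(pred[0, 0, j, i], 1))
                elif noobj[0, 0, j, i]:
                    manual += float(focal_bce(pred[0, 0, j, i], 0))
        assert total == pytest.approx(manual, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confidence_loss(nn.Tensor(np.zeros((1, 1, 2, 2))),
                            np.zeros((1, 1, 3, 3), dtype=bool),
                            np.zeros((1, 1, 3, 3), dtype=bool))


class TestClassificationLoss:
    def test_smoothed_positive_target(self):
        eps = 0.005
        assert 1 * (1 - eps) + 0.5 * eps == pytest.approx(0.9975)

    def test_zero_obj_cells_zero_loss(self, rng):
        obj = np.zeros((1, 1, 2, 2), dtype=bool)
        pred = rng.uniform(0.1, 0.9, size=(1, 1, 2, 2, 3))
        onehot = np.zeros((1, 1, 2, 2, 3))
        assert float(classification_loss(nn.Tensor(pred), obj, onehot)) == 0.0

    def test_no_smoothing_reduces_to_focal_bce(self, rng):
        obj = np.ones((1, 1, 1, 1), dtype=bool)
        p = 0.7
        pred = np.full((1, 1, 1, 1, 2), p)
        onehot = np.array([1.0, 0.0]).reshape(1, 1, 1, 1, 2)
        v = float(classification_loss(nn.Tensor(pred), obj, onehot, label_smoothing=0.0))
        assert v == pytest.approx(float(focal_bce(p, 1)) + float(focal_bce(p, 0)), rel=1e-9)


class TestTotalLoss:
    def test_zero_components(self):
        comps = [{"conf": 0.0, "cls": 0.0, "loc": 0.0}] * 3
        total, breakdown = total_loss(comps, LossConfig(), batch_size=4)
        assert float(total) == 0.0 and breakdown == {"conf": 0, "cls": 0, "loc": 0}

    def test_lambda_loc_zero_removes_location_term(self):
        comps = [{"conf": 1.0, "cls": 2.0, "loc": 7.0}]
        total, _ = total_loss(comps, LossConfig(lambda_loc=0.0), batch_size=1)
        assert float(total) == pytest.approx(3.0)

    def test_compositional_over_scales_and_batch(self):
        comps = [{"conf": 1.0, "cls": 0.5, "loc": 2.0},
                 {"conf": 3.0, "cls": 1.5, "loc": 0.5},
                 {"conf": 0.25, "cls": 0.25, "loc": 1.0}]
        total, breakdown = total_loss(comps, LossConfig(), batch_size=2)
        expected = sum(sum(c.values()) for c in comps) / 2
        assert float(total) == pytest.approx(expected)
        assert sum(breakdown.values()) == pytest.approx(expected)


class TestBuildTargets:
    @pytest.fixture()
    def anchors(self):
        whs = [(10, 14), (16, 20), (20, 28), (28, 36), (36, 48),
               (48, 64), (64, 80), (80, 100), (100, 120)]
        boxes = tuple(AnchorBox(w, h) for w, h in whs)
        return AnchorSet(boxes, accuracy=1.0)

    @pytest.fixture()
    def spec(self, tiny_spec):
        return tiny_spec

    def test_single_box_gets_exactly_one_obj_cell(self, anchors, spec):
        ann = ImageAnnotation("a", 128, 128, [BoundingBox(40, 40, 68, 76)])
        t = build_targets([ann], anchors, spec)
        assert sum(int(m.sum()) for m in t.obj_mask) == 1

    def test_empty_annotation_all_noobj(self, anchors, spec):
        ann = ImageAnnotation("a", 128, 128, [])
        t = build_targets([ann], anchors, spec)
        assert all(m.sum() == 0 for m in t.obj_mask)
        assert all(m.all() for m in t.noobj_mask)

    def test_two_boxes_two_disjoint_entries(self, anchors, spec):
        ann = ImageAnnotation("a", 128, 128, [
            BoundingBox(8, 8, 24, 28), BoundingBox(80, 80, 124, 126)])
        t = build_targets([ann], anchors, spec)
        assert sum(int(m.sum()) for m in t.obj_mask) == 2

    def test_obj_and_noobj_disjoint(self, anchors, spec):
        ann = ImageAnnotation("a", 128, 128, [BoundingBox(30, 30, 70, 80)])
        t = build_targets([ann], anchors, spec)
        for o, n in zip(t.obj_mask, t.noobj_mask):
            assert not np.any(o & n)

    def test_center_outside_input_rejected(self, anchors, spec):
        ann = ImageAnnotation("a", 400, 400, [BoundingBox(300, 300, 390, 390)])
        with pytest.raises(ValueError):
            build_targets([ann], anchors, spec)
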