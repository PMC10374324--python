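"""Decoding raw head grids into scored detections, NMS, and the full
image -> detections pipeline (letterbox resize, forward, decode, filter)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .anchors import AnchorSet, assign_anchors_to_scales
from .architecture import ArchitectureSpec, YoloV4Plus
from .boxes import BoundingBox, iou

__all__ = ["Detection", "decode_grid", "nms", "letterbox", "unletterbox_box", "detect"]


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    score: float
    class_name: str = "grape"

    def to_dict(self, image_id: str = "") -> dict:
        return {
            "image_id": image_id,
            "class": self.class_name,
            "score": round(self.score, 6),
            "xmin": self.box.xmin, "ymin": self.box.ymin,
            "xmax": self.box.xmax, "ymax": self.box.ymax,
        }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def decode_grid(raw: np.ndarray, scale_anchors, stride: int,
                classes: list[str], input_size: int,
                score_floor: float = 0.0) -> list[Detection]:
    """Decode one raw head grid ``(3*(5+C), H, W)`` into detections.

    Center: ``(sigmoid(t_xy) + cell) * stride``; size: ``anchor * exp(t_wh)``;
    score: ``sigmoid(obj) * sigmoid(class)``.
    """
    num_classes = len(classes)
    expected = 3 * (5 + num_classes)
    if raw.shape[0] != expected:
        raise ValueError(f"expected {expected} channels, got {raw.shape[0]}")
    _, h, w = raw.shape
    raw = raw.reshape(3, 5 + num_classes, h, w)
    anchor_wh = np.array([[a.width, a.height] for a in scale_anchors])  # (3, 2)

    cx = (_sigmoid(raw[:, 0]) + np.arange(w)[None, None, :]) * stride
    cy = (_sigmoid(raw[:, 1]) + np.arange(h)[None, :, None]) * stride
    # same smooth bound on log-size offsets as the training-time decode
    bw = anchor_wh[:, 0, None, None] * np.exp(4.0 * np.tanh(raw[:, 2] * 0.25))
    bh = anchor_wh[:, 1, None, None] * np.exp(4.0 * np.tanh(raw[:, 3] * 0.25))
    obj = _sigmoid(raw[:, 4])
    cls = _sigmoid(raw[:, 5:])                      # (3, C, h, w)
    best_cls = cls.argmax(axis=1)                   # (3, h, w)
    score = obj * np.take_along_axis(cls, best_cls[:, None], axis=1)[:, 0]

    dets: list[Detection] = []
    for a, j, i in zip(*np.nonzero(score >= score_floor)):
        xmin = max(0.0, cx[a, j, i] - bw[a, j, i] / 2)
        ymin = max(0.0, cy[a, j, i] - bh[a, j, i] / 2)
        xmax = min(float(input_size), cx[a, j, i] + bw[a, j, i] / 2)
        ymax = min(float(input_size), cy[a, j, i] + bh[a, j, i] / 2)
        if xmax <= xmin or ymax <= ymin:
            continue
        dets.append(Detection(
            BoundingBox(xmin, ymin, xmax, ymax, classes[best_cls[a, j, i]]),
            float(score[a, j, i]),
        ))
    return dets


def nms(detections: list[Detection], iou_threshold: float = 0.45,
        score_threshold: float = 0.5) -> list[Detection]:
    """Per-class greedy non-maximum suppression; result sorted by score."""
    kept: list[Detection] = []
    by_class: dict[str, list[Detection]] = {}
    for d in detections:
        if d.score >= score_threshold:
            by_class.setdefault(d.class_name, []).append(d)
    for dets in by_class.values():
        dets.sort(key=lambda d: -d.score)
        while dets:
            best = dets.pop(0)
            kept.append(best)
            dets = [d for d in dets if iou(d.box, best.box) <= iou_threshold]
    kept.sort(key=lambda d: -d.score)
    return kept


def letterbox(image: np.ndarray, size: int, fill: int = 128) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Aspect-preserving resize onto a ``size`` x ``size`` canvas.

    Returns ``(canvas, scale, (pad_x, pad_y))`` with pads in canvas pixels.
    """
    h, w = image.shape[:2]
    scale = min(size / w, size / h)
    nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), fill, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, nw / w, (float(px), float(py))


def unletterbox_box(box: BoundingBox, scale: float, pad: tuple[float, float],
                    orig_w: int, orig_h: int) -> BoundingBox | None:
    """Map a canvas-space box back to original image coordinates."""
    xmin = np.clip((box.xmin - pad[0]) / scale, 0, orig_w)
    xmax = np.clip((box.xmax - pad[0]) / scale, 0, orig_w)
    ymin = np.clip((box.ymin - pad[1]) / scale, 0, orig_h)
    ymax = np.clip((box.ymax - pad[1]) / scale, 0, orig_h)
    if xmax <= xmin or ymax <= ymin:
        return None
    return BoundingBox(float(xmin), float(ymin), float(xmax), float(ymax), box.class_name)


def detect(image: np.ndarray, model: YoloV4Plus, anchors: AnchorSet,
           classes: list[str] | None = None, conf_threshold: float = 0.5,
           nms_threshold: float = 0.45) -> list[Detection]:
    """Run the full detection pipeline on one HxWx3 uint8 image."""
    classes = classes or ["grape"]
    spec: ArchitectureSpec = model.spec
    canvas, scale, pad = letterbox(image, spec.input_size)
    x = canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    model.eval()
    outputs = model(x)
    per_scale = assign_anchors_to_scales(anchors.anchors)
    dets: list[Detection] = []
    for out, group, stride in zip(outputs, per_scale, spec.strides):
        dets.extend(decode_grid(out.data[0], group, stride, classes,
                                spec.input_size, score_floor=conf_threshold))
    dets = nms(dets, iou_threshold=nms_threshold, score_threshold=conf_threshold)
    h, w = image.shape[:2]
    mapped = []
    for d in dets:
        box = unletterbox_box(d.box, scale, pad, w, h)
        if box is not None:
            mapped.append(Detection(box, d.score, d.class_name))
    return mapped
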