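"""Detection scoring: greedy TP/FP/FN matching, P/R/F1, and average precision
as the area under the precision-recall curve (all-point interpolation by
default, the 11-point variant behind a flag)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BoundingBox, iou
from .inference import Detection

__all__ = [
    "DetectionMatchResult", "match_detections", "precision_recall_f1",
    "average_precision", "pr_curve_points", "evaluate",
]


@dataclass(frozen=True)
class DetectionMatchResult:
    tp: int
    fp: int
    fn: int
    flags: tuple[bool, ...]  # per detection, in descending-score order

    def __post_init__(self) -> None:
        assert self.tp + self.fp == len(self.flags)


def match_detections(dets: list[Detection], gts: list[BoundingBox],
                     iou_thresh: float = 0.5) -> DetectionMatchResult:
    """VOC-protocol greedy matching within one image and class.

    Detections are visited in descending score; each claims the unmatched
    ground truth of highest IoU if that IoU >= ``iou_thresh`` (TP), else it is
    an FP.  Each ground truth matches at most once, so duplicates are FPs.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(gts)
    flags = []
    for i in order:
        det = dets[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if taken[j] or gt.class_name != det.class_name:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            taken[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return DetectionMatchResult(tp, len(flags) - tp, len(gts) - tp, tuple(flags))


def precision_recall_f1(tp: int, fp: int, fn: int,
                        zero_division: float | None = None) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    With ``tp + fp == 0`` or ``tp + fn == 0`` the corresponding ratio is
    undefined; pass ``zero_division`` to substitute a value instead of
    raising.  F1 is defined as 0 when P = R = 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if (tp + fp == 0 or tp + fn == 0) and zero_division is None:
        raise ZeroDivisionError("precision/recall undefined for empty denominator")
    p = tp / (tp + fp) if tp + fp else zero_division
    r = tp / (tp + fn) if tp + fn else zero_division
    f1 = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return p, r, f1


def _ranked_flags(dets_by_image: dict[str, list[Detection]],
                  gts_by_image: dict[str, list[BoundingBox]],
                  iou_thresh: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Dataset-wide (scores, tp_flags, n_gt), matching per image."""
    scores: list[float] = []
    flags: list[bool] = []
    n_gt = 0
    for image_id, gts in gts_by_image.items():
        n_gt += len(gts)
    for image_id, dets in dets_by_image.items():
        gts = gts_by_image.get(image_id, [])
        result = match_detections(dets, gts, iou_thresh)
        ordered = sorted(dets, key=lambda d: -d.score)
        scores.extend(d.score for d in ordered)
        flags.extend(result.flags)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    return np.asarray(scores, float)[order], np.asarray(flags, bool)[order], n_gt


def average_precision(dets_by_image: dict[str, list[Detection]],
                      gts_by_image: dict[str, list[BoundingBox]],
                      iou_thresh: float = 0.5, eleven_point: bool = False) -> float:
    """AP = area under the P-R curve for one class over a dataset."""
    _, flags, n_gt = _ranked_flags(dets_by_image, gts_by_image, iou_thresh)
    if n_gt == 0:
        raise ValueError("average precision undefined with zero ground-truth boxes")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / n_gt
    # envelope: interpolated precision at recall r is max precision at >= r
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    if eleven_point:
        pts = []
        for r in np.linspace(0, 1, 11):
            mask = recall >= r - 1e-12
            pts.append(interp[mask][0] if mask.any() else 0.0)
        return float(np.mean(pts))
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, interp):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def pr_curve_points(dets_by_image: dict[str, list[Detection]],
                    gts_by_image: dict[str, list[BoundingBox]],
                    iou_thresh: float = 0.5) -> list[tuple[float, float]]:
    """(recall, interpolated precision) at each detection rank.

    Recall is non-decreasing; the trapezoid-free step-sum over these points
    equals :func:`average_precision` exactly.
    """
    _, flags, n_gt = _ranked_flags(dets_by_image, gts_by_image, iou_thresh)
    if n_gt == 0:
        raise ValueError("P-R curve undefined with zero ground-truth boxes")
    tp_cum = np.cumsum(flags)
    precision = tp_cum / np.arange(1, len(flags) + 1)
    recall = tp_cum / n_gt
    interp = np.maximum.accumulate(precision[::-1])[::-1]
    return list(zip(recall.tolist(), interp.tolist()))


def area_under_points(points: list[tuple[float, float]]) -> float:
    """Step-function area under (recall, precision) points."""
    ap, prev_r = 0.0, 0.0
    for r, p in points:
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def evaluate(dets_by_image: dict[str, list[Detection]],
             gts_by_image: dict[str, list[BoundingBox]],
             iou_thresh: float = 0.5) -> dict:
    """Per-class AP plus overall P/R/F1 at the supplied detections.

    Multi-class AP is averaged unweighted over classes (mAP).
    """
    classes = sorted({g.class_name for gts in gts_by_image.values() for g in gts})
    report: dict = {"classes": {}}
    tp = fp = fn = 0
    for image_id, gts in gts_by_image.items():
        res = match_detections(dets_by_image.get(image_id, []), gts, iou_thresh)
        tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
    p, r, f1 = precision_recall_f1(tp, fp, fn, zero_division=0.0)
    report.update(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)
    aps = []
    for cls in classes:
        cls_dets = {k: [d for d in v if d.class_name == cls] for k, v in dets_by_image.items()}
        cls_gts = {k: [g for g in v if g.class_name == cls] for k, v in gts_by_image.items()}
        ap = average_precision(cls_dets, cls_gts, iou_thresh)
        report["classes"][cls] = {"ap": ap}
        aps.append(ap)
    report["map"] = float(np.mean(aps)) if aps else 0.0
    return report
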