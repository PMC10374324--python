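"""Composite detection loss: focal BCE for confidence/class, CIoU for location.

Total loss over the three prediction scales s:

    L = sum_s [ l_conf_fl(s) + l_cls_fl(s) + l_loc(s) ] / batch_size

* confidence: binary cross-entropy over object and no-object cells, focal
  modulated (alpha = 0.75, gamma = 2 by default);
* classification: BCE over object cells with symmetric label smoothing
  (positive target 1 - eps/2, negative eps/2, eps = 0.005), focal modulated;
* location: CIoU = 1 - IoU + rho^2/c^2 + alpha*nu over object cells, where rho
  is the center distance, c the diagonal of the smallest enclosing box and nu
  the aspect-ratio consistency term.  CIoU carries no focal modulation.

Natural logarithms throughout; predicted probabilities are clamped to
[1e-7, 1 - 1e-7].  All formulas are written against the dispatching math
helpers so they evaluate identically on numpy arrays and autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .anchors import AnchorSet, assign_anchors_to_scales
from .architecture import ArchitectureSpec
from .boxes import BoundingBox, ImageAnnotation

__all__ = [
    "FocalConfig", "LossConfig", "TargetAssignment",
    "focal_bce", "ciou_loss", "ciou_loss_xywh",
    "build_targets", "confidence_loss", "classification_loss", "total_loss",
]

P_CLAMP = 1e-7


@dataclass(frozen=True)
class FocalConfig:
    alpha: float = 0.75
    gamma: float = 2.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class LossConfig:
    lambda_conf: float = 1.0
    lambda_cls: float = 1.0
    lambda_loc: float = 1.0
    label_smoothing: float = 0.005
    ignore_iou: float = 0.5

    def __post_init__(self) -> None:
        if min(self.lambda_conf, self.lambda_cls, self.lambda_loc) < 0:
            raise ValueError("balance coefficients must be >= 0")


def focal_bce(p, y, cfg: FocalConfig = FocalConfig()):
    """Focal-modulated binary cross-entropy, elementwise.

    ``y = 1``: -alpha (1-p)^gamma ln p;  ``y = 0``: -(1-alpha) p^gamma ln(1-p).
    With gamma = 0 and alpha = 0.5 this is half the standard BCE.
    """
    p = nn.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    y = np.asarray(y, dtype=float)
    if not cfg.enabled:
        return -(y * nn.log(p) + (1.0 - y) * nn.log(1.0 - p))
    pos = -cfg.alpha * (1.0 - p) ** cfg.gamma * nn.log(p)
    neg = -(1.0 - cfg.alpha) * p**cfg.gamma * nn.log(1.0 - p)
    return y * pos + (1.0 - y) * neg


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    """CIoU loss between two corner-parameterized boxes."""
    px, py = pred.center
    gx, gy = gt.center
    return float(
        ciou_loss_xywh(
            np.array(px), np.array(py), np.array(pred.width), np.array(pred.height),
            np.array(gx), np.array(gy), np.array(gt.width), np.array(gt.height),
        )
    )


def ciou_loss_xywh(px, py, pw, ph, gx, gy, gw, gh):
    """CIoU on center/size parameters; differentiable when given tensors."""
    p_x1, p_y1 = px - pw * 0.5, py - ph * 0.5
    p_x2, p_y2 = px + pw * 0.5, py + ph * 0.5
    g_x1, g_y1 = gx - gw * 0.5, gy - gh * 0.5
    g_x2, g_y2 = gx + gw * 0.5, gy + gh * 0.5

    iw = nn.maximum(nn.minimum(p_x2, g_x2) - nn.maximum(p_x1, g_x1), 0.0)
    ih = nn.maximum(nn.minimum(p_y2, g_y2) - nn.maximum(p_y1, g_y1), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou = inter / union

    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    cw = nn.maximum(p_x2, g_x2) - nn.minimum(p_x1, g_x1)
    chh = nn.maximum(p_y2, g_y2) - nn.minimum(p_y1, g_y1)
    c2 = cw**2 + chh**2

    nu = (4.0 / np.pi**2) * (nn.arctan(gw / gh) - nn.arctan(pw / ph)) ** 2
    # alpha is the standard trade-off weight, treated as a constant in autodiff
    nu_val = nu.data if isinstance(nu, nn.Tensor) else nu
    iou_val = iou.data if isinstance(iou, nn.Tensor) else iou
    alpha = nu_val / ((1.0 - iou_val) + nu_val + 1e-12)
    return 1.0 - iou + rho2 / c2 + alpha * nu


@dataclass
class TargetAssignment:
    """Per-scale supervision targets for one batch.

    For each scale s with grid S and 3 anchors: ``obj_mask``/``noobj_mask``
    are boolean ``(N, 3, S, S)`` arrays (disjoint; ignored anchors are in
    neither), ``tbox`` holds the matched ground-truth box as image-space
    (cx, cy, w, h) in ``(N, 3, S, S, 4)``, and ``tcls`` the target class
    index in ``(N, 3, S, S)``.
    """

    obj_mask: list[np.ndarray]
    noobj_mask: list[np.ndarray]
    tbox: list[np.ndarray]
    tcls: list[np.ndarray]

    @property
    def num_scales(self) -> int:
        return len(self.obj_mask)


def build_targets(annotations: list[ImageAnnotation], anchors: AnchorSet,
                  spec: ArchitectureSpec, classes: list[str] | None = None,
                  ignore_iou: float = 0.5) -> TargetAssignment:
    """Assign each ground-truth box to its best-IoU anchor at the grid cell
    containing the box center, on that anchor's scale.

    Anchors whose shape-IoU with some ground truth exceeds ``ignore_iou`` but
    that are not the best match drop out of the no-object mask (ignore
    region).  Annotations are expected in network input coordinates.
    """
    classes = classes or ["grape"]
    grids = spec.grid_sizes()
    strides = spec.strides
    n = len(annotations)
    obj = [np.zeros((n, 3, g, g), dtype=bool) for g in grids]
    noobj = [np.ones((n, 3, g, g), dtype=bool) for g in grids]
    tbox = [np.zeros((n, 3, g, g, 4), dtype=np.float64) for g in grids]
    tcls = [np.zeros((n, 3, g, g), dtype=np.int64) for g in grids]

    per_scale = assign_anchors_to_scales(anchors.anchors)
    flat = [a for group in per_scale for a in group]  # index = 3*scale + slot
    anchor_wh = np.array([[a.width, a.height] for a in flat])

    for img_idx, ann in enumerate(annotations):
        for box in ann.boxes:
            cx, cy = box.center
            if not (0 <= cx <= spec.input_size and 0 <= cy <= spec.input_size):
                raise ValueError(f"box center ({cx}, {cy}) outside the network input")
            wh = np.array([box.width, box.height])
            inter = np.minimum(anchor_wh, wh).prod(axis=1)
            ious = inter / (anchor_wh.prod(axis=1) + wh.prod() - inter)
            best = int(ious.argmax())
            s, slot = divmod(best, 3)
            gi = min(int(cx / strides[s]), grids[s] - 1)
            gj = min(int(cy / strides[s]), grids[s] - 1)
            obj[s][img_idx, slot, gj, gi] = True
            noobj[s][img_idx, slot, gj, gi] = False
            tbox[s][img_idx, slot, gj, gi] = (cx, cy, box.width, box.height)
            tcls[s][img_idx, slot, gj, gi] = classes.index(box.class_name)
            # ignore close-but-not-best anchors at the same location
            for j in np.flatnonzero((ious > ignore_iou)):
                if j == best:
                    continue
                s2, slot2 = divmod(int(j), 3)
                gi2 = min(int(cx / strides[s2]), grids[s2] - 1)
                gj2 = min(int(cy / strides[s2]), grids[s2] - 1)
                if not obj[s2][img_idx, slot2, gj2, gi2]:
                    noobj[s2][img_idx, slot2, gj2, gi2] = False
    return TargetAssignment(obj, noobj, tbox, tcls)


def confidence_loss(pred_conf, obj_mask: np.ndarray, noobj_mask: np.ndarray,
                    cfg: FocalConfig = FocalConfig()):
    """Focal BCE of objectness over object and no-object cells (sum reduction).

    ``pred_conf`` holds probabilities shaped like the masks.
    """
    if tuple(pred_conf.shape) != obj_mask.shape:
        raise ValueError("prediction/mask shape mismatch")
    per_cell = focal_bce(pred_conf, obj_mask.astype(float), cfg)
    keep = (obj_mask | noobj_mask).astype(float)
    return (per_cell * keep).sum()


def classification_loss(pred_class, obj_mask: np.ndarray, class_targets: np.ndarray,
                        focal: FocalConfig = FocalConfig(), label_smoothing: float = 0.005):
    """Focal BCE of per-class probabilities over object cells only.

    ``pred_class``: probabilities ``(..., C)``; ``class_targets``: one-hot
    ``(..., C)``.  Targets are smoothed symmetrically: positives to
    ``1 - eps/2``, negatives to ``eps/2``.
    """
    smoothed = class_targets * (1.0 - label_smoothing) + 0.5 * label_smoothing
    per_entry = focal_bce(pred_class, 1.0, focal) * smoothed + \
        focal_bce(pred_class, 0.0, focal) * (1.0 - smoothed)
    mask = obj_mask[..., None].astype(float)
    return (per_entry * mask).sum()


def total_loss(scale_components: list[dict], cfg: LossConfig, batch_size: int):
    """Combine per-scale {'conf', 'cls', 'loc'} terms into the training loss.

    Returns ``(total, breakdown)`` where breakdown maps each component name to
    its coefficient-weighted, batch-normalized contribution.
    """
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    conf = sum(c["conf"] for c in scale_components)
    cls = sum(c["cls"] for c in scale_components)
    loc = sum(c["loc"] for c in scale_components)
    total = (cfg.lambda_conf * conf + cfg.lambda_cls * cls + cfg.lambda_loc * loc) * (1.0 / batch_size)
    breakdown = {
        "conf": cfg.lambda_conf * _val(conf) / batch_size,
        "cls": cfg.lambda_cls * _val(cls) / batch_size,
        "loc": cfg.lambda_loc * _val(loc) / batch_size,
    }
    return total, breakdown


def _val(x) -> float:
    return float(x.data) if isinstance(x, nn.Tensor) else float(x)
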