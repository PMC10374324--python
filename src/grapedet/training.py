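"""Two-stage training recipe with cosine-annealed learning rate.

Stage 1 trains with the backbone frozen (transfer-learning style warm-up);
stage 2 fine-tunes every parameter at a lower learning rate.  The cosine
schedule restarts at each stage boundary.  Input images are letterboxed to
the network size and optionally shrunk by a random factor (default range
0.7-0.9) inside the canvas.

The differentiable loss glue (:func:`detection_loss`) decodes the raw head
grids in-graph — center ``(sigmoid(t_xy) + cell) * stride``, size
``anchor * exp(t_wh)`` — and feeds the focal/CIoU components defined in
:mod:`grapedet.losses`.

The optimizer is Adam (SGD available); the recipe assumes an optional
pretrained backbone checkpoint and falls back to seeded random
initialization.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .anchors import AnchorSet, assign_anchors_to_scales
from .architecture import ArchitectureSpec, YoloV4Plus
from .boxes import BoundingBox, ImageAnnotation
from .inference import letterbox
from .losses import (FocalConfig, LossConfig, TargetAssignment, build_targets,
                     ciou_loss_xywh, classification_loss, confidence_loss, total_loss)
from .nn import Adam, SGD, Tensor

__all__ = [
    "StageConfig", "TrainingSchedule", "cosine_lr", "random_scale_resize",
    "detection_loss", "fit",
]


@dataclass(frozen=True)
class StageConfig:
    epochs: int
    batch_size: int
    lr0: float
    backbone_frozen: bool

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("invalid stage configuration")


@dataclass(frozen=True)
class TrainingSchedule:
    stage1: StageConfig = StageConfig(epochs=30, batch_size=8, lr0=1e-3, backbone_frozen=True)
    stage2: StageConfig = StageConfig(epochs=10, batch_size=2, lr0=1e-4, backbone_frozen=False)
    scale_range: tuple[float, float] = (0.7, 0.9)
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("scale_range must lie within (0, 1]")


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float | None = None) -> float:
    """Cosine annealing from ``lr0`` to ``lr_min`` (default ``0.01 * lr0``)."""
    if lr_min is None:
        lr_min = 0.01 * lr0
    if step < 0:
        raise ValueError("step must be >= 0")
    if total_steps <= 0 or step >= total_steps:
        return lr_min
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * step / total_steps))


def random_scale_resize(image: np.ndarray, boxes: list[BoundingBox],
                        scale_range: tuple[float, float], seed: int = 0,
                        fill: int = 114) -> tuple[np.ndarray, list[BoundingBox]]:
    """Shrink the content by a random factor inside a same-size canvas.

    The content is resized by ``s ~ U(scale_range)`` and re-centered; boxes
    follow the same similarity transform (areas scale by s^2 exactly).
    """
    rng = np.random.default_rng(seed)
    s = float(rng.uniform(*scale_range))
    h, w = image.shape[:2]
    if s == 1.0:
        return image.copy(), list(boxes)
    nw, nh = max(1, round(w * s)), max(1, round(h * s))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    canvas = np.full_like(image, fill)
    ox, oy = (w - nw) // 2, (h - nh) // 2
    canvas[oy:oy + nh, ox:ox + nw] = resized
    sx, sy = nw / w, nh / h
    out_boxes = [
        BoundingBox(ox + b.xmin * sx, oy + b.ymin * sy,
                    ox + b.xmax * sx, oy + b.ymax * sy, b.class_name)
        for b in boxes
    ]
    return canvas, out_boxes


def detection_loss(outputs: list[Tensor], targets: TargetAssignment, anchors: AnchorSet,
                   spec: ArchitectureSpec, focal: FocalConfig = FocalConfig(),
                   cfg: LossConfig = LossConfig(), batch_size: int | None = None):
    """Differentiable total loss from the three raw head grids."""
    num_classes = spec.num_classes
    per_scale_anchors = assign_anchors_to_scales(anchors.anchors)
    components = []
    n = outputs[0].shape[0]
    batch_size = batch_size or n
    for s, (raw, group) in enumerate(zip(outputs, per_scale_anchors)):
        g = raw.shape[2]
        grid = raw.reshape(n, 3, 5 + num_classes, g, g)
        obj_mask, noobj_mask = targets.obj_mask[s], targets.noobj_mask[s]

        pred_conf = nn.sigmoid(grid[:, :, 4])
        conf = confidence_loss(pred_conf, obj_mask, noobj_mask, focal)

        if num_classes > 0 and obj_mask.any():
            pred_cls = nn.sigmoid(grid[:, :, 5:]).transpose(0, 1, 3, 4, 2)
            onehot = np.eye(num_classes)[targets.tcls[s]]
            cls = classification_loss(pred_cls, obj_mask, onehot, focal, cfg.label_smoothing)
        else:
            cls = nn.Tensor(np.zeros(()))

        if obj_mask.any():
            bi, ai, gj, gi = (idx for idx in np.nonzero(obj_mask))
            stride = spec.strides[s]
            anchor_wh = np.array([[a.width, a.height] for a in group])
            tx = grid[bi, ai, 0, gj, gi]
            ty = grid[bi, ai, 1, gj, gi]
            # smooth bound on the log-size offsets: keeps exp() finite while
            # preserving gradient everywhere (a hard clamp would zero the
            # gradient once an offset drifts past the bound and strand it)
            tw = 4.0 * nn.tanh(grid[bi, ai, 2, gj, gi] * 0.25)
            th = 4.0 * nn.tanh(grid[bi, ai, 3, gj, gi] * 0.25)
            px = (nn.sigmoid(tx) + gi) * stride
            py = (nn.sigmoid(ty) + gj) * stride
            pw = anchor_wh[ai, 0] * nn.exp(tw)
            ph = anchor_wh[ai, 1] * nn.exp(th)
            tb = targets.tbox[s][bi, ai, gj, gi]
            loc = ciou_loss_xywh(px, py, pw, ph,
                                 tb[:, 0], tb[:, 1], tb[:, 2], tb[:, 3]).sum()
        else:
            loc = nn.Tensor(np.zeros(()))
        components.append({"conf": conf, "cls": cls, "loc": loc})
    return total_loss(components, cfg, batch_size)


def _prepare(sample, spec: ArchitectureSpec, scale_range, rng) -> tuple[np.ndarray, ImageAnnotation]:
    """Letterbox one (image, annotation) pair to the network input, then apply
    the random-scale strategy."""
    image, ann = sample
    canvas, s, (px, py) = letterbox(image, spec.input_size)
    boxes = []
    for b in ann.boxes:
        boxes.append(BoundingBox(b.xmin * s + px, b.ymin * s + py,
                                 b.xmax * s + px, b.ymax * s + py, b.class_name))
    if scale_range != (1.0, 1.0):
        canvas, boxes = random_scale_resize(canvas, boxes, scale_range,
                                            seed=int(rng.integers(0, 2**31 - 1)))
    return canvas, ImageAnnotation(ann.image_id, spec.input_size, spec.input_size, boxes)


def mosaic_batch(samples, spec: ArchitectureSpec, rng) -> tuple[np.ndarray, ImageAnnotation]:
    """Optional 4-image composite: each image shrinks into one quadrant."""
    size = spec.input_size
    half = size // 2
    canvas = np.full((size, size, 3), 114, dtype=np.uint8)
    boxes: list[BoundingBox] = []
    picks = [samples[int(rng.integers(0, len(samples)))] for _ in range(4)]
    for q, (image, ann) in enumerate(picks):
        oy, ox = (q // 2) * half, (q % 2) * half
        img = np.asarray(Image.fromarray(image).resize((half, half), Image.BILINEAR))
        canvas[oy:oy + half, ox:ox + half] = img
        sx, sy = half / image.shape[1], half / image.shape[0]
        for b in ann.boxes:
            boxes.append(BoundingBox(ox + b.xmin * sx, oy + b.ymin * sy,
                                     ox + b.xmax * sx, oy + b.ymax * sy, b.class_name))
    return canvas, ImageAnnotation("mosaic", size, size, boxes)


def fit(model: YoloV4Plus, dataset, schedule: TrainingSchedule, anchors: AnchorSet,
        focal: FocalConfig = FocalConfig(), loss_cfg: LossConfig = LossConfig(),
        classes: list[str] | None = None, out_dir: str | Path | None = None,
        backbone_checkpoint: str | Path | None = None) -> list[dict]:
    """Run the two-stage schedule; returns the per-epoch loss history.

    ``dataset`` is a list of ``(uint8 HxWx3 image, ImageAnnotation)`` pairs in
    original image coordinates.  Backbone parameters have their gradients
    disabled during any stage with ``backbone_frozen=True``.  Checkpoints are
    written per stage when ``out_dir`` is given.
    """
    if not dataset:
        raise ValueError("empty dataset")
    classes = classes or ["grape"]
    spec = model.spec
    if backbone_checkpoint is not None:
        model.backbone.load(backbone_checkpoint)
    rng = np.random.default_rng(schedule.seed)
    history: list[dict] = []

    for stage_idx, stage in enumerate((schedule.stage1, schedule.stage2), start=1):
        if stage.epochs == 0:
            continue
        for p in model.backbone.parameters():
            p.requires_grad = not stage.backbone_frozen
        params = model.parameters()
        if schedule.optimizer == "adam":
            opt = Adam(params, lr=stage.lr0)
        else:
            opt = SGD(params, lr=stage.lr0)
        n_batches = math.ceil(len(dataset) / stage.batch_size)
        total_steps = stage.epochs * n_batches
        step = 0
        model.train()
        for epoch in range(stage.epochs):
            order = rng.permutation(len(dataset))
            sums = {"total": 0.0, "conf": 0.0, "cls": 0.0, "loc": 0.0}
            for b in range(n_batches):
                idx = order[b * stage.batch_size:(b + 1) * stage.batch_size]
                pairs = [_prepare(dataset[i], spec, schedule.scale_range, rng) for i in idx]
                x = np.stack([img.astype(np.float32).transpose(2, 0, 1) / 255.0
                              for img, _ in pairs])
                anns = [ann for _, ann in pairs]
                targets = build_targets(anns, anchors, spec, classes, loss_cfg.ignore_iou)
                opt.lr = cosine_lr(step, total_steps, stage.lr0)
                opt.zero_grad()
                outputs = model(x)
                loss, breakdown = detection_loss(outputs, targets, anchors, spec,
                                                 focal, loss_cfg, batch_size=len(idx))
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at stage {stage_idx} epoch {epoch} step {step}: "
                        f"{breakdown}")
                loss.backward()
                opt.step()
                step += 1
                sums["total"] += float(loss.data)
                for k in ("conf", "cls", "loc"):
                    sums[k] += breakdown[k]
            history.append({
                "stage": stage_idx, "epoch": epoch,
                **{k: v / n_batches for k, v in sums.items()},
            })
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            model.save(out / f"stage{stage_idx}.npz")
    if out_dir is not None:
        with open(Path(out_dir) / "loss_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["stage", "epoch", "total", "conf", "cls", "loc"])
            writer.writeheader()
            writer.writerows(history)
    model.eval()
    return history
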