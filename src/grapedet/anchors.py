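"""Anchor-box K-means on ground-truth (width, height) pairs.

Boxes are anchored at a common corner so that the distance between a box and
a cluster center reduces to ``1 - IoU(wh_box, wh_center)`` — the standard
metric for YOLO anchor clustering and the one consistent with reporting an
IoU-style clustering accuracy.  Plain Euclidean distance on (w, h) is
available behind ``metric="euclidean"``.

The quality score ``accuracy`` is the mean, over boxes, of the best IoU to
any anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnchorBox", "AnchorSet", "kmeans_anchors", "anchor_accuracy", "assign_anchors_to_scales"]


@dataclass(frozen=True)
class AnchorBox:
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("anchor sides must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class AnchorSet:
    """Anchors sorted by area ascending, plus the mean-best-IoU accuracy."""

    anchors: tuple[AnchorBox, ...]
    accuracy: float

    def __post_init__(self) -> None:
        areas = [a.area for a in self.anchors]
        if list(areas) != sorted(areas):
            raise ValueError("anchors must be sorted by area ascending")

    def as_array(self) -> np.ndarray:
        return np.array([[a.width, a.height] for a in self.anchors], dtype=np.float64)

    @property
    def per_scale(self) -> tuple[tuple[AnchorBox, ...], ...]:
        return assign_anchors_to_scales(self.anchors)


def _wh_iou(boxes: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU of corner-anchored boxes: (n, 2) x (k, 2) -> (n, k)."""
    inter = np.minimum(boxes[:, None, 0], centers[None, :, 0]) * np.minimum(
        boxes[:, None, 1], centers[None, :, 1]
    )
    union = (boxes[:, 0] * boxes[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / union


def _distances(boxes: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    if metric == "iou":
        return 1.0 - _wh_iou(boxes, centers)
    if metric == "euclidean":
        # squared distance: the per-cluster mean is then the exact minimizer,
        # making each Lloyd step provably non-increasing
        return ((boxes[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def _lloyd(boxes: np.ndarray, k: int, rng: np.random.Generator, metric: str,
           max_iter: int, tol: float) -> tuple[np.ndarray, float, list[float]]:
    n = len(boxes)
    centers = boxes[rng.choice(n, size=k, replace=False)].astype(np.float64)
    assign = np.full(n, -1)
    history: list[tuple[float, bool]] = []  # (total distance, reseeded?)
    reseeded = False
    for _ in range(max_iter):
        dist = _distances(boxes, centers, metric)
        new_assign = dist.argmin(axis=1)
        history.append((float(dist[np.arange(n), new_assign].sum()), reseeded))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        reseeded = False
        for j in range(k):
            members = boxes[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                # reseed an empty cluster from the worst-fitted box
                worst = dist[np.arange(n), assign].argmax()
                centers[j] = boxes[worst]
                reseeded = True
        if len(history) >= 2 and abs(history[-2][0] - history[-1][0]) < tol:
            break
    dist = _distances(boxes, centers, metric)
    total = float(dist[np.arange(n), dist.argmin(axis=1)].sum())
    return centers, total, history


def kmeans_anchors(boxes, k: int = 9, seed: int = 0, max_iter: int = 300,
                   tol: float = 1e-6, metric: str = "iou", restarts: int = 10) -> AnchorSet:
    """Cluster (w, h) pairs into ``k`` anchors; best of ``restarts`` seeded runs."""
    arr = np.asarray([(b.width, b.height) if isinstance(b, AnchorBox) else tuple(b) for b in boxes],
                     dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("boxes must be (w, h) pairs")
    if np.any(arr <= 0):
        raise ValueError("box sides must be positive")
    distinct = np.unique(arr, axis=0)
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct boxes, got {len(distinct)}")
    root = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for sub in root.spawn(restarts):
        centers, total, history = _lloyd(arr, k, sub, metric, max_iter, tol)
        # Mean updates make each plain Lloyd step non-increasing under the
        # Euclidean metric; under 1 - IoU the mean is only a heuristic center,
        # so the guarantee (and the check) applies to Euclidean runs.
        # Empty-cluster reseeds may deliberately raise the total and are exempt.
        if metric == "euclidean":
            assert all(b <= a + 1e-6 for (a, _), (b, res) in zip(history, history[1:])
                       if not res), "within-cluster distance increased during Lloyd iteration"
        if best is None or total < best[1]:
            best = (centers, total)
    centers = best[0][np.argsort(best[0].prod(axis=1), kind="stable")]
    anchors = tuple(AnchorBox(w, h) for w, h in centers)
    return AnchorSet(anchors, accuracy=anchor_accuracy(arr, anchors))


def anchor_accuracy(boxes, anchors) -> float:
    """Mean over boxes of the best IoU to any anchor (corner-anchored)."""
    arr = np.asarray([(b.width, b.height) if isinstance(b, AnchorBox) else tuple(b) for b in boxes],
                     dtype=np.float64)
    anc = np.asarray([(a.width, a.height) if isinstance(a, AnchorBox) else tuple(a) for a in anchors],
                     dtype=np.float64)
    if len(arr) == 0 or len(anc) == 0:
        raise ValueError("boxes and anchors must be non-empty")
    return float(_wh_iou(arr, anc).max(axis=1).mean())


def assign_anchors_to_scales(anchors) -> tuple[tuple[AnchorBox, ...], ...]:
    """Split 9 anchors into 3 per-scale triples, smallest areas first.

    The smallest triple serves the finest (stride-8) grid, the largest the
    coarsest (stride-32) grid.  Ties in area break by width.
    """
    anc = [a if isinstance(a, AnchorBox) else AnchorBox(*a) for a in anchors]
    if len(anc) != 9:
        raise ValueError(f"expected 9 anchors, got {len(anc)}")
    ordered = sorted(anc, key=lambda a: (a.area, a.width))
    return tuple(tuple(ordered[i:i + 3]) for i in range(0, 9, 3))
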