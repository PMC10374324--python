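"""Seeded synthetic orchard scenes for testing the detection stack offline.

Scenes emulate the stressors a vineyard detector faces: grape bunches are
clusters of overlapping shaded ellipses ("berries") with a stem, rendered on
a leafy cluttered background; leaf-shaped occluders can cover a requested
fraction of each bunch (the ground-truth box always spans the *full* bunch,
occluded or not, mirroring how whole clusters are annotated in field
datasets); global illumination modes approximate front light, backlight and
low light.  Rendering is a pure function of :class:`SceneSpec`.

These are deliberately schematic, not photorealistic: enough structure for
overfit/recovery smoke tests and pixel-accurate occlusion bookkeeping, not a
substitute for real orchard imagery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import disk, ellipse

from .boxes import BoundingBox, ImageAnnotation, write_voc_xml
from .metrics import match_detections

__all__ = ["SceneSpec", "generate_scene", "generate_dataset", "planted_recovery_check"]


@dataclass(frozen=True)
class SceneSpec:
    image_size: int = 256
    n_bunches: int = 3
    occlusion_fraction: float = 0.0
    illumination: str = "front"            # front | back | low
    background_clutter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occlusion_fraction <= 0.8):
            raise ValueError("occlusion_fraction must lie in [0, 0.8]")
        if self.illumination not in ("front", "back", "low"):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if not (0.0 <= self.background_clutter <= 1.0):
            raise ValueError("background_clutter must lie in [0, 1]")


_ILLUMINATION_GAIN = {"front": 1.0, "back": 0.62, "low": 0.45}


def _background(size: int, clutter: float, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float64)
    base = np.array([52.0, 84.0, 42.0])
    img[:] = base
    img += rng.normal(0, 6, (size, size, 3))
    n_leaves = int(clutter * size * size / 900)
    for _ in range(n_leaves):
        cy, cx = rng.uniform(0, size, 2)
        ry = rng.uniform(size / 40, size / 12)
        rx = ry * rng.uniform(0.4, 0.9)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(size, size), rotation=rot)
        shade = rng.uniform(0.65, 1.45)
        img[rr, cc] = base * shade + rng.normal(0, 4, 3)
    img = ndimage.gaussian_filter(img, sigma=(1.0, 1.0, 0))
    return img


def _render_bunch(img: np.ndarray, mask: np.ndarray, cy: float, cx: float,
                  bh: float, bw: float, rng: np.random.Generator) -> None:
    """Draw one bunch (berry cluster + stem) and record its pixel mask."""
    size = img.shape[0]
    berry_r = max(2.0, bw / 5.5)
    n_berries = max(8, int(bh * bw / (berry_r**2 * 1.4)))
    base_col = np.array([88.0, 34.0, 104.0])  # ripe purple-blue
    for _ in range(n_berries):
        # berries fill a vertically elongated, downward-tapering region
        v = rng.beta(1.6, 1.6)
        y = cy - bh / 2 + v * bh
        taper = 1.0 - 0.65 * v
        x = cx + rng.uniform(-0.5, 0.5) * bw * taper
        r = berry_r * rng.uniform(0.75, 1.1)
        rr, cc = disk((y, x), r, shape=(size, size))
        shade = rng.uniform(0.75, 1.2)
        img[rr, cc] = base_col * shade
        mask[rr, cc] = True
        # specular highlight
        hr, hc = disk((y - r * 0.3, x - r * 0.3), max(1.0, r * 0.3), shape=(size, size))
        img[hr, hc] = np.minimum(img[hr, hc] + 70, 255)
    # stem
    top = int(max(0, cy - bh / 2 - bh * 0.12))
    for y in range(top, int(cy - bh / 2) + 1):
        x = int(round(cx + rng.normal(0, 0.4)))
        if 0 <= x < size and 0 <= y < size:
            img[y, max(0, x - 1):x + 1] = (92, 66, 32)


def _occlude(img: np.ndarray, bunch_mask: np.ndarray, fraction: float,
             rng: np.random.Generator) -> float:
    """Cover ``fraction`` of the bunch mask with leaf ellipses; returns the
    measured coverage."""
    size = img.shape[0]
    total = int(bunch_mask.sum())
    if total == 0 or fraction <= 0:
        return 0.0
    covered = np.zeros_like(bunch_mask)
    ys, xs = np.nonzero(bunch_mask)
    leaf_col = np.array([60.0, 104.0, 48.0])
    for _ in range(400):
        frac = covered[bunch_mask].mean()
        if frac >= fraction - 0.02:
            break
        i = rng.integers(0, len(ys))
        ry = rng.uniform(3, max(4.0, np.sqrt(total) * 0.35))
        rx = ry * rng.uniform(0.5, 1.0)
        rr, cc = ellipse(ys[i], xs[i], ry, rx, shape=(size, size),
                         rotation=rng.uniform(0, np.pi))
        would = covered.copy()
        would[rr, cc] = True
        if would[bunch_mask].mean() > fraction + 0.03:
            continue
        covered = would
        img[rr, cc] = leaf_col * rng.uniform(0.8, 1.2)
    return float(covered[bunch_mask].mean())


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, ImageAnnotation, dict]:
    """Render one scene.

    Returns ``(image, annotation, info)`` where ``info`` records the measured
    occlusion per bunch.  Raises when the requested bunches cannot be placed
    inside the frame.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(size, spec.background_clutter, rng)

    boxes: list[BoundingBox] = []
    occlusions: list[float] = []
    margin = size * 0.05
    placed: list[tuple[float, float, float, float]] = []
    for _ in range(spec.n_bunches):
        for attempt in range(200):
            bh = rng.uniform(size * 0.18, size * 0.32)
            bw = bh * rng.uniform(0.55, 0.8)
            cy = rng.uniform(margin + bh / 2, size - margin - bh / 2)
            cx = rng.uniform(margin + bw / 2, size - margin - bw / 2)
            if all(abs(cy - py) > (bh + ph) / 2.4 or abs(cx - px) > (bw + pw) / 2.4
                   for py, px, ph, pw in placed):
                break
        else:
            raise ValueError(
                f"could not place {spec.n_bunches} bunches of this size in a "
                f"{size}x{size} frame")
        placed.append((cy, cx, bh, bw))
        mask = np.zeros((size, size), dtype=bool)
        _render_bunch(img, mask, cy, cx, bh, bw, rng)
        occlusions.append(_occlude(img, mask, spec.occlusion_fraction, rng))
        ys, xs = np.nonzero(mask)
        boxes.append(BoundingBox(float(xs.min()), float(ys.min()),
                                 float(xs.max() + 1), float(ys.max() + 1)))

    gain = _ILLUMINATION_GAIN[spec.illumination]
    if spec.illumination == "back":
        # bright sky gradient from the top
        grad = np.linspace(70, 0, size)[:, None, None]
        img = img * gain + grad
    else:
        img = img * gain
    image = np.clip(img, 0, 255).astype(np.uint8)
    ann = ImageAnnotation(f"scene_{spec.seed:06d}", size, size, boxes)
    return image, ann, {"occlusion_measured": occlusions, "spec": asdict(spec)}


def generate_dataset(n_images: int, out_dir: str | Path, seed: int = 0,
                     spec_template: SceneSpec = SceneSpec(),
                     val_fraction: float = 0.2) -> list[dict]:
    """Write a VOC-layout dataset of synthetic scenes; returns the manifest."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out = Path(out_dir)
    (out / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (out / "Annotations").mkdir(parents=True, exist_ok=True)
    (out / "ImageSets" / "Main").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = []
    ids = []
    for i in range(n_images):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = SceneSpec(**{**asdict(spec_template), "seed": sub_seed})
        image, ann, info = generate_scene(spec)
        image_id = f"scene_{i:04d}"
        ann.image_id = image_id
        ids.append(image_id)
        Image.fromarray(image).save(out / "JPEGImages" / f"{image_id}.png")
        write_voc_xml(ann, out / "Annotations" / f"{image_id}.xml")
        manifest.append({"image_id": image_id, "n_boxes": len(ann.boxes), **info})
    n_val = max(1, int(round(val_fraction * n_images))) if n_images > 1 else 0
    (out / "ImageSets" / "Main" / "train.txt").write_text("\n".join(ids[:n_images - n_val]) + "\n")
    (out / "ImageSets" / "Main" / "val.txt").write_text("\n".join(ids[n_images - n_val:]) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def planted_recovery_check(dets_by_image: dict, gts_by_image: dict,
                           iou: float = 0.5) -> float:
    """Fraction of planted bunches matched by a detection at IoU >= ``iou``."""
    missing = set(dets_by_image) - set(gts_by_image)
    if missing:
        raise KeyError(f"detections reference unknown images: {sorted(missing)}")
    tp = n_gt = 0
    for image_id, gts in gts_by_image.items():
        res = match_detections(dets_by_image.get(image_id, []), gts, iou_thresh=iou)
        tp += res.tp
        n_gt += len(gts)
    if n_gt == 0:
        raise ValueError("no planted bunches to recover")
    return tp / n_gt
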