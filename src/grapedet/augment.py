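"""Box-aware dataset-expansion operators.

Five operators mirror the field-robustness augmentations used for orchard
imagery — brightness gain, Gaussian blur, bounded affine warp, horizontal
mirror, raindrop streak overlay — plus a fog transform for weather stress
tests.  :func:`expand_dataset` applies all five to every input sample and
keeps the originals, multiplying the dataset size by exactly six.

Every operator is a pure function of (input, parameters, seed).  Photometric
operators leave annotations untouched; geometric operators push each box's
four corners through the same transform and take the axis-aligned hull,
dropping boxes whose visible area falls below a configurable fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .boxes import BoundingBox, ImageAnnotation, write_voc_xml

__all__ = [
    "AugmentedSample", "photometric_transform", "geometric_transform",
    "weather_overlay", "expand_dataset", "DEFAULT_OPERATORS",
]

FOG_AIRLIGHT = 240.0
MIN_VISIBLE_FRACTION = 0.25


@dataclass
class AugmentedSample:
    image: np.ndarray                      # HxWx3 uint8
    annotation: ImageAnnotation
    provenance: dict = field(default_factory=dict)


def photometric_transform(image: np.ndarray, mode: str, strength: float,
                          seed: int = 0) -> np.ndarray:
    """Brightness gain (``mode='brightness'``) or Gaussian blur (``'blur'``).

    ``strength`` is the multiplicative gain (> 0) or the blur sigma (> 0);
    sigma below 0.1 degenerates to the identity.  Boxes are unaffected.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    img = np.asarray(image)
    if mode == "brightness":
        return np.clip(img.astype(np.float64) * strength, 0, 255).astype(np.uint8)
    if mode == "blur":
        if strength < 0.1:
            return img.copy()
        out = np.stack(
            [ndimage.gaussian_filter(img[..., c].astype(np.float64), strength, mode="nearest")
             for c in range(img.shape[2])], axis=-1)
        return np.clip(out, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown photometric mode {mode!r}")


def _affine_params(rng: np.random.Generator, limits: dict) -> dict:
    return {
        "angle_deg": rng.uniform(-limits.get("max_rotation", 15.0), limits.get("max_rotation", 15.0)),
        "scale": rng.uniform(*limits.get("scale_range", (0.8, 1.2))),
        "tx_frac": rng.uniform(-limits.get("max_translation", 0.1), limits.get("max_translation", 0.1)),
        "ty_frac": rng.uniform(-limits.get("max_translation", 0.1), limits.get("max_translation", 0.1)),
    }


def _affine_matrix(params: dict, w: int, h: int) -> np.ndarray:
    """Forward 3x3 matrix: rotation+scale about the image center + translation."""
    theta = np.deg2rad(params["angle_deg"])
    s = params["scale"]
    cx, cy = w / 2.0, h / 2.0
    tx, ty = params["tx_frac"] * w, params["ty_frac"] * h
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[s * c, -s * sn, 0], [s * sn, s * c, 0], [0, 0, 1]])
    to_origin = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]])
    back = np.array([[1, 0, cx + tx], [0, 1, cy + ty], [0, 0, 1]])
    return back @ rot @ to_origin


def transform_box(box: BoundingBox, matrix: np.ndarray, width: int, height: int,
                  min_visible: float = MIN_VISIBLE_FRACTION) -> BoundingBox | None:
    """Axis-aligned hull of the transformed corners, clipped to the image.

    Returns ``None`` when the clipped area is below ``min_visible`` of the
    full transformed hull (degenerate sliver suppression).
    """
    corners = np.array([
        [box.xmin, box.ymin, 1], [box.xmax, box.ymin, 1],
        [box.xmax, box.ymax, 1], [box.xmin, box.ymax, 1],
    ]).T
    tx = matrix @ corners
    xs, ys = tx[0], tx[1]
    hull = (xs.max() - xs.min()) * (ys.max() - ys.min())
    xmin, xmax = np.clip([xs.min(), xs.max()], 0, width)
    ymin, ymax = np.clip([ys.min(), ys.max()], 0, height)
    if xmax <= xmin or ymax <= ymin:
        return None
    if (xmax - xmin) * (ymax - ymin) < min_visible * hull:
        return None
    return BoundingBox(float(xmin), float(ymin), float(xmax), float(ymax), box.class_name)


def geometric_transform(sample: AugmentedSample, mode: str, params: dict | None = None,
                        seed: int = 0) -> AugmentedSample:
    """Affine warp (``mode='affine'``) or horizontal mirror (``'mirror'``).

    The same transform is applied to pixels and boxes; an affine warp that
    pushes every box out of frame yields a sample with zero boxes.
    """
    img = sample.image
    ann = sample.annotation
    h, w = img.shape[:2]
    if mode == "mirror":
        out = img[:, ::-1].copy()
        boxes = [BoundingBox(w - b.xmax, b.ymin, w - b.xmin, b.ymax, b.class_name)
                 for b in ann.boxes]
        return AugmentedSample(out, ImageAnnotation(ann.image_id, w, h, boxes),
                               {"op": "mirror", "seed": seed})
    if mode != "affine":
        raise ValueError(f"unknown geometric mode {mode!r}")
    rng = np.random.default_rng(seed)
    params = params if params is not None else _affine_params(rng, {})
    matrix = _affine_matrix(params, w, h)
    inv = np.linalg.inv(matrix)
    out = np.stack(
        [ndimage.affine_transform(img[..., c].astype(np.float64), inv[:2, :2],
                                  offset=inv[:2, 2], order=1, cval=114.0)
         for c in range(img.shape[2])], axis=-1).clip(0, 255).astype(np.uint8)
    boxes = [tb for b in ann.boxes if (tb := transform_box(b, matrix, w, h)) is not None]
    return AugmentedSample(out, ImageAnnotation(ann.image_id, w, h, boxes),
                           {"op": "affine", "params": params, "seed": seed})


def weather_overlay(image: np.ndarray, mode: str, intensity: float, seed: int = 0,
                    fog_field: np.ndarray | None = None) -> np.ndarray:
    """Raindrop streaks or fog, with strength ``intensity`` in [0, 1].

    Fog blends toward a bright airlight A = 240 with transmission
    ``t = 1 - intensity * g(x, y)`` where ``g`` is a smooth random field in
    (0, 1] (injectable through ``fog_field``).  Raindrops draw
    ``round(200 * intensity)`` translucent near-vertical streaks.
    """
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must lie in [0, 1]")
    img = np.asarray(image)
    if intensity == 0.0:
        return img.copy()
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed)
    if mode == "fog":
        if fog_field is None:
            noise = rng.random((h, w))
            g = ndimage.gaussian_filter(noise, sigma=max(h, w) / 8, mode="nearest")
            lo, hi = g.min(), g.max()
            g = 0.6 + 0.4 * (g - lo) / (hi - lo) if hi > lo else np.full((h, w), 0.8)
        else:
            g = np.asarray(fog_field, dtype=np.float64)
        t = 1.0 - intensity * g
        out = img.astype(np.float64) * t[..., None] + FOG_AIRLIGHT * (1.0 - t[..., None])
        return np.clip(out, 0, 255).astype(np.uint8)
    if mode == "raindrop":
        out = img.astype(np.float64)
        n_drops = round(200 * intensity)
        for _ in range(n_drops):
            x0 = rng.uniform(0, w)
            y0 = rng.uniform(0, h)
            length = rng.uniform(8, 25)
            angle = np.deg2rad(rng.uniform(75, 105))
            alpha = rng.uniform(0.25, 0.55)
            shade = rng.uniform(190, 245)
            steps = int(length)
            xs = (x0 + np.cos(angle) * np.arange(steps)).round().astype(int)
            ys = (y0 + np.sin(angle) * np.arange(steps)).round().astype(int)
            ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
            out[ys[ok], xs[ok]] = (1 - alpha) * out[ys[ok], xs[ok]] + alpha * shade
        return np.clip(out, 0, 255).astype(np.uint8)
    raise ValueError(f"unknown weather mode {mode!r}")


DEFAULT_OPERATORS = ("brightness", "blur", "affine", "mirror", "raindrop")


def _apply_operator(sample: AugmentedSample, op: str, rng: np.random.Generator) -> AugmentedSample:
    seed = int(rng.integers(0, 2**31 - 1))
    sub = np.random.default_rng(seed)
    if op == "brightness":
        gain = float(sub.uniform(0.6, 1.4))
        img = photometric_transform(sample.image, "brightness", gain)
        prov = {"op": op, "gain": gain, "seed": seed}
        return AugmentedSample(img, sample.annotation, prov)
    if op == "blur":
        sigma = float(sub.uniform(1.0, 3.0))
        img = photometric_transform(sample.image, "blur", sigma)
        return AugmentedSample(img, sample.annotation, {"op": op, "sigma": sigma, "seed": seed})
    if op in ("affine", "mirror"):
        out = geometric_transform(sample, op, seed=seed)
        return out
    if op == "raindrop":
        intensity = float(sub.uniform(0.3, 0.8))
        img = weather_overlay(sample.image, "raindrop", intensity, seed=seed)
        return AugmentedSample(img, sample.annotation, {"op": op, "intensity": intensity, "seed": seed})
    if op == "fog":
        intensity = float(sub.uniform(0.3, 0.8))
        img = weather_overlay(sample.image, "fog", intensity, seed=seed)
        return AugmentedSample(img, sample.annotation, {"op": op, "intensity": intensity, "seed": seed})
    raise ValueError(f"unknown operator {op!r}")


def expand_dataset(samples: list[AugmentedSample], output_dir: str | Path,
                   seed: int = 0, operators: tuple[str, ...] = DEFAULT_OPERATORS) -> list[dict]:
    """Write originals plus one variant per operator per sample.

    With the default five operators the output is exactly ``6 * len(samples)``
    image/annotation pairs.  Returns the manifest (also written as JSON).
    """
    if not samples:
        raise ValueError("expand_dataset needs at least one input sample")
    out = Path(output_dir)
    (out / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (out / "Annotations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: list[dict] = []

    def _emit(sample: AugmentedSample, name: str, provenance: dict):
        ann = ImageAnnotation(name, sample.annotation.width, sample.annotation.height,
                              sample.annotation.boxes)
        Image.fromarray(sample.image).save(out / "JPEGImages" / f"{name}.png")
        write_voc_xml(ann, out / "Annotations" / f"{name}.xml")
        manifest.append({"image_id": name, "n_boxes": len(ann.boxes), **provenance})

    for sample in samples:
        base = sample.annotation.image_id
        _emit(sample, base, {"op": "original"})
        for op in operators:
            variant = _apply_operator(sample, op, rng)
            _emit(variant, f"{base}_{op}", variant.provenance)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
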