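"""Bounding-box geometry and annotation I/O.

Boxes are axis-aligned, in continuous 0-based pixel-edge coordinates.  Two
on-disk label dialects are supported losslessly:

* YOLO text labels: one ``class_index cx cy w h`` line per box, all four
  geometry fields normalized to the image size;
* Pascal VOC XML: ``annotation/size`` plus one ``object/bndbox`` node per box
  with corner coordinates in pixels.

The VOC writer rounds coordinates half-up to integers; the reader accepts both
0- and 1-based files verbatim (no ±1 shift is applied).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = [
    "BoundingBox",
    "YoloRecord",
    "ImageAnnotation",
    "iou",
    "box_to_yolo",
    "yolo_to_box",
    "read_yolo_labels",
    "write_yolo_labels",
    "read_voc_xml",
    "write_voc_xml",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with corners ``(xmin, ymin)`` / ``(xmax, ymax)``."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    class_name: str = "grape"

    def __post_init__(self) -> None:
        for v in (self.xmin, self.ymin, self.xmax, self.ymax):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"coordinates must be finite and >= 0, got {v!r}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))


@dataclass(frozen=True)
class YoloRecord:
    """One YOLO label line: class index plus normalized center/size."""

    class_index: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_index < 0:
            raise ValueError("class_index must be non-negative")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"center ({self.cx}, {self.cy}) outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"size ({self.w}, {self.h}) outside (0, 1]")


@dataclass
class ImageAnnotation:
    """All ground-truth boxes of one image."""

    image_id: str
    width: int
    height: int
    boxes: list[BoundingBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        for b in self.boxes:
            if b.xmax > self.width or b.ymax > self.height:
                raise ValueError(f"box {b} exceeds image bounds {self.width}x{self.height}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def yolo_to_box(rec: YoloRecord, width: int, height: int, classes: Sequence[str]) -> BoundingBox:
    """Denormalize a YOLO record to pixel corners, clipping to image bounds.

    Out-of-bounds extents are clipped rather than rejected: augmentation can
    legitimately push boxes onto the image border.
    """
    if rec.class_index >= len(classes):
        raise IndexError(f"class_index {rec.class_index} out of range for {len(classes)} classes")
    xmin = max(0.0, (rec.cx - rec.w / 2) * width)
    xmax = min(float(width), (rec.cx + rec.w / 2) * width)
    ymin = max(0.0, (rec.cy - rec.h / 2) * height)
    ymax = min(float(height), (rec.cy + rec.h / 2) * height)
    return BoundingBox(xmin, ymin, xmax, ymax, classes[rec.class_index])


def box_to_yolo(box: BoundingBox, width: int, height: int, classes: Sequence[str]) -> YoloRecord:
    """Inverse of :func:`yolo_to_box` for in-bounds boxes."""
    cx, cy = box.center
    return YoloRecord(
        class_index=list(classes).index(box.class_name),
        cx=cx / width,
        cy=cy / height,
        w=box.width / width,
        h=box.height / height,
    )


def read_yolo_labels(
    path: str | Path,
    image_size: tuple[int, int],
    classes: Sequence[str],
    image_id: str | None = None,
) -> ImageAnnotation:
    """Parse a YOLO ``.txt`` label file into an :class:`ImageAnnotation`.

    ``image_size`` is ``(width, height)``.  A malformed line raises with its
    1-based line number; an empty file yields an empty annotation.
    """
    path = Path(path)
    width, height = image_size
    boxes: list[BoundingBox] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            rec = YoloRecord(int(fields[0]), *(float(f) for f in fields[1:]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        boxes.append(yolo_to_box(rec, width, height, classes))
    return ImageAnnotation(image_id or path.stem, width, height, boxes)


def write_yolo_labels(ann: ImageAnnotation, path: str | Path, classes: Sequence[str]) -> None:
    lines = []
    for box in ann.boxes:
        r = box_to_yolo(box, ann.width, ann.height, classes)
        lines.append(f"{r.class_index} {r.cx:.9f} {r.cy:.9f} {r.w:.9f} {r.h:.9f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def write_voc_xml(ann: ImageAnnotation, path: str | Path) -> None:
    """Serialize an annotation as Pascal VOC XML (integer pixel corners)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    for box in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.class_name
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(_round_half_up(box.xmin))
        ET.SubElement(bnd, "ymin").text = str(_round_half_up(box.ymin))
        ET.SubElement(bnd, "xmax").text = str(max(_round_half_up(box.xmax), _round_half_up(box.xmin) + 1))
        ET.SubElement(bnd, "ymax").text = str(max(_round_half_up(box.ymax), _round_half_up(box.ymin) + 1))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=False)


def _req(node: ET.Element, tag: str) -> ET.Element:
    child = node.find(tag)
    if child is None:
        raise ValueError(f"VOC XML missing <{tag}> under <{node.tag}>")
    return child


def _num(node: ET.Element, tag: str) -> float:
    text = (_req(node, tag).text or "").strip()
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"non-numeric <{tag}> value {text!r}") from exc


def read_voc_xml(path: str | Path) -> ImageAnnotation:
    """Parse a Pascal VOC XML annotation.

    Coordinates are taken verbatim (both 0- and 1-based files are accepted).
    A file with ``xmin >= xmax`` fails box validation.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    size = _req(root, "size")
    width = int(_num(size, "width"))
    height = int(_num(size, "height"))
    filename = root.findtext("filename") or path.stem
    image_id = Path(filename).stem
    boxes = []
    for obj in root.iter("object"):
        name = (_req(obj, "name").text or "").strip()
        bnd = _req(obj, "bndbox")
        boxes.append(
            BoundingBox(
                _num(bnd, "xmin"), _num(bnd, "ymin"),
                _num(bnd, "xmax"), _num(bnd, "ymax"),
                class_name=name,
            )
        )
    return ImageAnnotation(image_id, width, height, boxes)
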