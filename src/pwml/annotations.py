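"""Annotation / detection I-O and the train-validation split.

Formats
-------
Pascal VOC XML
    The labelImg dialect: 1-based *closed* integer corners.  Internally
    boxes are 0-based half-open, so ``xmin_voc = x_min + 1`` and
    ``xmax_voc = x_max`` (likewise for y); the round trip is exact.
YOLO darknet txt
    One line per box: ``class x_center y_center width height`` normalized to
    [0, 1] with six decimals; corners survive the round trip to within 1 px
    on a 256-px canvas.
Detections JSON
    ``[{"image_id": ..., "box": [x_min, y_min, x_max, y_max],
    "probability_percent": ...}, ...]`` with probabilities validated in
    [0, 100].
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rng import substream
from .types import BoundingBox, Detection


class FormatError(ValueError):
    """Malformed annotation or detection file."""


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------

def write_voc(
    path: str | Path,
    image_id: str,
    image_size: tuple[int, int],
    boxes: list[BoundingBox],
) -> None:
    """Write one VOC XML annotation file; ``image_size`` is (width, height)."""
    w, h = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "1"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.label
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = str(b.x_min + 1)
        ET.SubElement(bb, "ymin").text = str(b.y_min + 1)
        ET.SubElement(bb, "xmax").text = str(b.x_max)
        ET.SubElement(bb, "ymax").text = str(b.y_max)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


def read_voc(path: str | Path) -> tuple[str, tuple[int, int], list[BoundingBox]]:
    """Read a VOC XML file -> (image_id, (width, height), boxes)."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML in {path}: {exc}") from exc
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise FormatError(f"{path}: missing size element")
    w = int(size.findtext("width"))
    h = int(size.findtext("height"))
    image_id = Path(root.findtext("filename", default=Path(path).stem)).stem
    boxes = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        if bb is None:
            raise FormatError(f"{path}: object without bndbox")
        try:
            boxes.append(
                BoundingBox(
                    x_min=int(bb.findtext("xmin")) - 1,
                    y_min=int(bb.findtext("ymin")) - 1,
                    x_max=int(bb.findtext("xmax")),
                    y_max=int(bb.findtext("ymax")),
                    label=obj.findtext("name", default="PWML"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad bndbox: {exc}") from exc
    return image_id, (w, h), boxes


# ---------------------------------------------------------------------------
# YOLO darknet txt
# ---------------------------------------------------------------------------

def write_yolo(
    path: str | Path,
    image_size: tuple[int, int],
    boxes: list[BoundingBox],
    class_map: dict[str, int] | None = None,
) -> None:
    w, h = image_size
    class_map = class_map or {"PWML": 0}
    lines = []
    for b in boxes:
        xc = (b.x_min + b.x_max) / 2.0 / w
        yc = (b.y_min + b.y_max) / 2.0 / h
        bw = b.width / w
        bh = b.height / h
        for v in (xc, yc, bw, bh):
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"normalized value outside [0,1]: {v}")
        lines.append(f"{class_map[b.label]} {xc:.6f} {yc:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo(
    path: str | Path,
    image_size: tuple[int, int],
    class_map: dict[str, int] | None = None,
) -> list[BoundingBox]:
    w, h = image_size
    inv = {v: k for k, v in (class_map or {"PWML": 0}).items()}
    boxes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"{path}:{ln}: expected 5 fields")
        cls = int(parts[0])
        xc, yc, bw, bh = (float(p) for p in parts[1:])
        for v in (xc, yc, bw, bh):
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"{path}:{ln}: value outside [0,1]: {v}")
        x0 = int(round(xc * w - bw * w / 2.0))
        y0 = int(round(yc * h - bh * h / 2.0))
        x1 = int(round(xc * w + bw * w / 2.0))
        y1 = int(round(yc * h + bh * h / 2.0))
        boxes.append(BoundingBox(x0, y0, max(x1, x0 + 1), max(y1, y0 + 1),
                                 inv.get(cls, str(cls))))
    return boxes


# ---------------------------------------------------------------------------
# detections JSON
# ---------------------------------------------------------------------------

def write_detections(path: str | Path, detections: list[Detection]) -> None:
    payload = [
        {
            "image_id": d.image_id,
            "box": [d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max],
            "probability_percent": d.probability_percent,
        }
        for d in detections
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections(path: str | Path) -> list[Detection]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    out = []
    for i, item in enumerate(payload):
        try:
            box = item["box"]
            b = BoundingBox(int(box[0]), int(box[1]), int(box[2]), int(box[3]))
            p = float(item["probability_percent"])
            if not (0.0 <= p <= 100.0):
                raise ValueError(f"probability outside [0,100]: {p}")
            out.append(Detection(str(item["image_id"]), b, p))
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: entry {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# train / validation split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    train_frac: float
    seed: int


def split_dataset(ids: list[str], train_frac: float = 0.8,
                  seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled partition with ``|train| = floor(frac * N)``."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    if len(ids) < 2:
        raise ValueError("need at least two ids to split")
    rng = substream(seed, "split")
    order = np.array(ids, dtype=object)
    rng.shuffle(order)
    n_train = int(math.floor(train_frac * len(ids)))
    return DatasetSplit(
        train_ids=tuple(order[:n_train]),
        val_ids=tuple(order[n_train:]),
        train_frac=train_frac,
        seed=seed,
    )
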