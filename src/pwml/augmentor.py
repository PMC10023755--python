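"""Geometric augmentation: identity, left-right flip, +-5% scale, +-15 deg rotation.

Each input image becomes exactly six (the original is kept alongside five
transforms).  Scaling and rotation act about the canvas center, preserve the
canvas size (content is cropped or padded with ``fill_value``), and resample
bilinearly.  Bounding boxes are transformed with the *same* affine map: the
four corners are mapped, their axis-aligned hull is taken (standard practice
for rotated boxes), and the result is clipped to the canvas; boxes clipped
away entirely are dropped with a warning.

Coordinates: a pixel ``(row r, col c)`` covers the square
``[c, c+1) x [r, r+1)`` in continuous (x, y) edge coordinates, so box edges
sit on integer coordinates and the canvas center is ``(W/2, H/2)``.
Positive rotation angles turn counter-clockwise in display orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import BoundingBox, CompositeRecord, ImageSlice, TissueMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentationOp:
    name: str
    kind: str          # identity | hflip | scale | rotate
    value: float = 0.0

    def matrix(self, width: int, height: int) -> np.ndarray:
        """3x3 homogeneous forward map in (x, y) edge coordinates."""
        cx, cy = width / 2.0, height / 2.0
        if self.kind == "identity":
            a = np.eye(2)
        elif self.kind == "hflip":
            a = np.diag([-1.0, 1.0])
        elif self.kind == "scale":
            a = np.diag([self.value, self.value])
        elif self.kind == "rotate":
            # y grows downward; this matrix turns counter-clockwise on screen
            t = math.radians(self.value)
            a = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
        else:
            raise ValueError(f"unknown op kind {self.kind!r}")
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = np.array([cx, cy]) - a @ np.array([cx, cy])
        return m


DEFAULT_OPS: tuple[AugmentationOp, ...] = (
    AugmentationOp("orig", "identity"),
    AugmentationOp("hflip", "hflip"),
    AugmentationOp("scale095", "scale", 0.95),
    AugmentationOp("scale105", "scale", 1.05),
    AugmentationOp("rot+15", "rotate", 15.0),
    AugmentationOp("rot-15", "rotate", -15.0),
)


@dataclass(frozen=True)
class AugmentationSpec:
    ops: tuple[AugmentationOp, ...] = DEFAULT_OPS
    interpolation_order: int = 1   # bilinear
    fill_value: float = 0.0


_P = np.array([[0.0, 1.0], [1.0, 0.0]])  # (x,y) <-> (col,row) swap


def _index_inverse(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse map in (row, col) pixel-center coordinates for ndimage."""
    a_inv = np.linalg.inv(m[:2, :2])
    b = m[:2, 2]
    h = np.array([0.5, 0.5])  # pixel-center offset: x = col + 0.5
    mat = _P @ a_inv @ _P
    off = _P @ (a_inv @ (h - b) - h)
    return mat, off


def transform_image(
    image: ImageSlice,
    op: AugmentationOp,
    spec: AugmentationSpec = AugmentationSpec(),
) -> ImageSlice:
    """Apply one op; output canvas matches the input canvas exactly."""
    if op.kind == "identity":
        return image.copy()
    if op.kind == "hflip":
        return ImageSlice(np.fliplr(image.pixels).copy(),
                          image.pixel_size_mm, image.image_id)
    m = op.matrix(image.width, image.height)
    mat, off = _index_inverse(m)
    out = ndimage.affine_transform(
        image.pixels.astype(float),
        matrix=mat,
        offset=off,
        output_shape=image.shape,
        order=spec.interpolation_order,
        mode="constant",
        cval=spec.fill_value,
    )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return ImageSlice(out, image.pixel_size_mm, image.image_id)


def transform_tissue(tissue: TissueMask, op: AugmentationOp,
                     spec: AugmentationSpec = AugmentationSpec()) -> TissueMask:
    """Transform a label map with nearest-neighbor resampling."""
    if op.kind == "identity":
        return tissue.copy()
    if op.kind == "hflip":
        return TissueMask(np.fliplr(tissue.labels).copy())
    h, w = tissue.shape
    mat, off = _index_inverse(op.matrix(w, h))
    out = ndimage.affine_transform(
        tissue.labels, matrix=mat, offset=off, output_shape=tissue.shape,
        order=0, mode="constant", cval=0,
    )
    return TissueMask(out)


def transform_box(
    box: BoundingBox,
    op: AugmentationOp,
    image_size: tuple[int, int],
) -> BoundingBox | None:
    """Map a box through an op: corner transform, axis-aligned hull, clip.

    ``image_size`` is (width, height).  Returns None when the box is clipped
    away entirely (or collapses below one pixel).
    """
    w, h = image_size
    if op.kind == "identity":
        return box.clip(w, h)
    if op.kind == "hflip":
        return BoundingBox(
            w - box.x_max, box.y_min, w - box.x_min, box.y_max, box.label
        ).clip(w, h)
    m = op.matrix(w, h)
    pts = np.hstack([box.corners(), np.ones((4, 1))]) @ m.T
    u, v = pts[:, 0], pts[:, 1]
    x0, x1 = math.floor(u.min() + 1e-9), math.ceil(u.max() - 1e-9)
    y0, y1 = math.floor(v.min() + 1e-9), math.ceil(v.max() - 1e-9)
    if x1 <= x0 or y1 <= y0:
        return None
    try:
        return BoundingBox(x0, y0, x1, y1, box.label).clip(w, h)
    except ValueError:
        return None


def augment_record(
    record: CompositeRecord,
    op: AugmentationOp,
    spec: AugmentationSpec = AugmentationSpec(),
) -> CompositeRecord:
    size = (record.image.width, record.image.height)
    boxes: list[BoundingBox] = []
    for b in record.boxes:
        tb = transform_box(b, op, size)
        if tb is None:
            logger.warning(
                "box %s dropped by op %s on %s", b, op.name, record.image_id
            )
            continue
        boxes.append(tb)
    return CompositeRecord(
        image=transform_image(record.image, op, spec),
        boxes=boxes,
        background_id=record.background_id,
        lesion_slice_id=record.lesion_slice_id,
        transform_tag=op.name,
        tissue=None if record.tissue is None else transform_tissue(record.tissue, op, spec),
    )


def augment_set(
    records: list[CompositeRecord],
    spec: AugmentationSpec = AugmentationSpec(),
) -> list[CompositeRecord]:
    """Expand every record into ``len(spec.ops)`` records (6 by default)."""
    if not records:
        raise ValueError("augment_set requires a non-empty input")
    out: list[CompositeRecord] = []
    for rec in records:
        for op in spec.ops:
            out.append(augment_record(rec, op, spec))
    return out
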