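"""Core value types shared by every stage.

Conventions
-----------
* Images are 2-D ``uint8`` arrays indexed ``[row, col]`` = ``[y, x]``.
* Bounding boxes are 0-based **half-open** pixel rectangles
  ``[x_min, x_max) x [y_min, y_max)``; a box therefore covers
  ``(x_max - x_min) * (y_max - y_min)`` pixels.  The Pascal VOC writer
  converts to the 1-based closed convention at the file boundary.
* Tissue maps label every pixel with one of BACKGROUND / CORTEX /
  WHITE_MATTER / VENTRICLE.
* Detection confidences are stored in percent, 0-100, matching the
  probability-threshold sweep (20/30/40/50 %).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

# Tissue labels
BACKGROUND = 0
CORTEX = 1
WHITE_MATTER = 2
VENTRICLE = 3

TISSUE_NAMES = {
    BACKGROUND: "background",
    CORTEX: "cerebral_cortex",
    WHITE_MATTER: "cerebral_white_matter",
    VENTRICLE: "ventricle",
}

DEFAULT_LABEL = "PWML"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    label: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) of the box center in continuous edge coordinates."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting the box pixels in an array."""
        return slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)

    def corners(self) -> np.ndarray:
        """4x2 array of (x, y) corner coordinates on the box edges."""
        return np.array(
            [
                (self.x_min, self.y_min),
                (self.x_max, self.y_min),
                (self.x_min, self.y_max),
                (self.x_max, self.y_max),
            ],
            dtype=float,
        )

    def iou(self, other: "BoundingBox") -> float:
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / float(self.area + other.area - inter)

    def contains_point(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def shift(self, dx: int, dy: int) -> "BoundingBox":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def clip(self, width: int, height: int) -> "BoundingBox | None":
        """Clip to a ``width x height`` canvas; None when nothing remains."""
        x0, y0 = max(self.x_min, 0), max(self.y_min, 0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    @classmethod
    def from_mask(cls, mask: np.ndarray, label: str = DEFAULT_LABEL) -> "BoundingBox":
        """Tight box around the True pixels of a 2-D boolean mask."""
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise ValueError("empty mask has no bounding box")
        return cls(
            x_min=int(cols.min()),
            y_min=int(rows.min()),
            x_max=int(cols.max()) + 1,
            y_max=int(rows.max()) + 1,
            label=label,
        )


@dataclass
class ImageSlice:
    """A single 2-D grayscale slice with in-plane pixel size metadata."""

    pixels: np.ndarray
    pixel_size_mm: float = 0.83
    image_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.pixels)
        if a.ndim != 2:
            raise ValueError("ImageSlice requires a 2-D array")
        if a.dtype != np.uint8:
            a = np.clip(np.round(a), 0, 255).astype(np.uint8)
        self.pixels = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "ImageSlice":
        return ImageSlice(self.pixels.copy(), self.pixel_size_mm, self.image_id)


@dataclass
class TissueMask:
    """Per-pixel tissue label map aligned with one ImageSlice."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.labels)
        if a.ndim != 2:
            raise ValueError("TissueMask requires a 2-D array")
        self.labels = a.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region(self, label: int) -> np.ndarray:
        return self.labels == label

    def copy(self) -> "TissueMask":
        return TissueMask(self.labels.copy())


@dataclass
class LesionPatch:
    """A cropped lesion: raw intensities + binary lesion mask + provenance."""

    patch: np.ndarray          # uint8, shape (h, w)
    mask: np.ndarray           # bool, same shape
    source_id: str             # "case/slice" identifier
    bbox_in_source: BoundingBox
    centroid: tuple[float, float]  # (x, y) in source coordinates

    def __post_init__(self) -> None:
        if self.patch.shape != self.mask.shape:
            raise ValueError("patch and mask shapes differ")
        if not self.mask.any():
            raise ValueError("lesion mask is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass(frozen=True)
class Detection:
    """One scored detector box; probability expressed in percent."""

    image_id: str
    box: BoundingBox
    probability_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability_percent <= 100.0):
            raise ValueError(
                f"probability_percent outside [0, 100]: {self.probability_percent}"
            )


@dataclass
class CompositeRecord:
    """A (possibly augmented) composite slice with its ground-truth boxes."""

    image: ImageSlice
    boxes: list[BoundingBox]
    background_id: str = ""
    lesion_slice_id: str = ""
    transform_tag: str = "orig"
    tissue: TissueMask | None = None

    @property
    def image_id(self) -> str:
        base = f"{self.lesion_slice_id}__{self.background_id}"
        return f"{base}__{self.transform_tag}" if self.transform_tag else base


# Convenience alias: an annotated image is a composite record whose lesion
# provenance may be empty (e.g. a phantom slice with injected ground truth).
AnnotatedImage = CompositeRecord


def boxes_overlap(boxes: Sequence[BoundingBox]) -> bool:
    """True when any pair of boxes intersects (O(n^2); n is tiny here)."""
    for i, a in enumerate(boxes):
        for b in boxes[i + 1:]:
            if a.iou(b) > 0.0:
                return True
    return False


def iter_pixels(box: BoundingBox) -> Iterator[tuple[int, int]]:
    for y in range(box.y_min, box.y_max):
        for x in range(box.x_min, box.x_max):
            yield x, y
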