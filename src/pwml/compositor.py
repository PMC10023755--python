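"""Copy-paste compositing of lesion patches onto normal slices.

Each lesion-bearing source slice is paired with *every* normal background
slice (a full cross-product: L lesion slices x B backgrounds -> L*B
composites; 13 x 72 = 936 at the study scale).  Within one composite, every
patch of the source slice is placed once by rejection sampling under
anatomical constraints:

* the whole patch mask must land on white matter, at least ``margin`` px
  from any non-WM pixel;
* the white matter is split into three equal-height anterior-to-posterior
  bands, and a patch is confined to the band matching the anterior-posterior
  rank of its source centroid (coarse frontal-to-parietal placement);
* pasted patches never overlap each other.

Pasting is a direct mask copy with an optional 1-px feather: interior mask
pixels take the patch value, mask-boundary pixels the patch/background mean.
Pixels outside the mask are bit-identical to the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rng import substream
from .types import (
    WHITE_MATTER,
    BoundingBox,
    CompositeRecord,
    ImageSlice,
    LesionPatch,
    TissueMask,
)

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """A paste violated a constraint or rejection sampling gave up."""


@dataclass(frozen=True)
class PasteConstraints:
    allowed_tissue: int = WHITE_MATTER
    n_regions: int = 3          # anterior->posterior bands of the WM mask
    margin: int = 2             # px clearance from any non-allowed pixel
    max_attempts: int = 100
    feather: bool = True        # 1-px edge blend inside the mask

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


def clearance_map(tissue: TissueMask, constraints: PasteConstraints) -> np.ndarray:
    """Pixels of the allowed tissue at least ``margin`` px from non-allowed."""
    allowed = tissue.region(constraints.allowed_tissue)
    dist = ndimage.distance_transform_edt(allowed)
    return dist > constraints.margin


def region_bands(tissue: TissueMask, n_regions: int = 3) -> np.ndarray:
    """Band index (0..n-1) per pixel over the WM row extent; -1 elsewhere.

    Band 0 is the most anterior (lowest row index) third of the white-matter
    extent; bands have equal height.
    """
    wm = tissue.region(WHITE_MATTER)
    rows = np.nonzero(wm.any(axis=1))[0]
    out = np.full(wm.shape, -1, dtype=np.int8)
    if rows.size == 0:
        return out
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    edges = np.linspace(r0, r1, n_regions + 1)
    rr = np.arange(wm.shape[0])
    band_of_row = np.clip(np.searchsorted(edges, rr, side="right") - 1, 0, n_regions - 1)
    out[wm] = band_of_row[np.nonzero(wm)[0]]
    return out


def assign_bands(patches: list[LesionPatch], n_regions: int = 3) -> list[int]:
    """Band per patch from the anterior-posterior rank of its source centroid."""
    if not patches:
        return []
    order = np.argsort([p.centroid[1] for p in patches], kind="stable")
    bands = [0] * len(patches)
    for rank, idx in enumerate(order):
        bands[idx] = min(rank * n_regions // len(patches), n_regions - 1)
    return bands


def _blend(region: np.ndarray, patch: LesionPatch, feather: bool) -> np.ndarray:
    """Composite the patch onto one background window (returns float array)."""
    out = region.astype(float)
    mask = patch.mask
    if feather:
        inner = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
        ring = mask & ~inner
        out[inner] = patch.patch[inner]
        out[ring] = 0.5 * patch.patch[ring] + 0.5 * out[ring]
    else:
        out[mask] = patch.patch[mask]
    return out


def paste_lesion(
    background: ImageSlice,
    patch: LesionPatch,
    location: tuple[int, int],
    tissue: TissueMask,
    constraints: PasteConstraints = PasteConstraints(),
    _clearance: np.ndarray | None = None,
) -> tuple[ImageSlice, BoundingBox]:
    """Paste one patch with its top-left corner at ``location`` = (x, y).

    Raises :class:`PlacementError` naming the violated rule; on success
    returns the composited image and the tight box of the pasted mask.
    """
    x, y = location
    h, w = patch.shape
    H, W = background.shape
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise PlacementError("bounds: patch footprint leaves the canvas")
    clear = clearance_map(tissue, constraints) if _clearance is None else _clearance
    sl = (slice(y, y + h), slice(x, x + w))
    # the whole patch rectangle must clear the margin so that the returned
    # ground-truth box, not merely the mask, respects the constraint
    if not clear[sl].all():
        raise PlacementError(
            "tissue/margin: patch footprint touches non-allowed tissue or its margin"
        )
    out = background.pixels.copy()
    blended = _blend(out[sl], patch, constraints.feather)
    window = out[sl]
    window[patch.mask] = np.clip(np.round(blended[patch.mask]), 0, 255).astype(np.uint8)
    box = BoundingBox.from_mask(patch.mask).shift(x, y)
    return ImageSlice(out, background.pixel_size_mm, background.image_id), box


def build_composites(
    lesion_slices: list[tuple[str, list[LesionPatch]]],
    backgrounds: list[tuple[ImageSlice, TissueMask]],
    constraints: PasteConstraints = PasteConstraints(),
    seed: int = 0,
) -> list[CompositeRecord]:
    """Full cross-product compositing: one record per (lesion slice, background).

    Every patch of the source slice is placed once, by rejection sampling of
    a mask-center position inside its assigned anterior-posterior band.
    Deterministic for a fixed seed.
    """
    for sid, patches in lesion_slices:
        if not patches:
            raise ValueError(f"lesion slice {sid!r} has no patches")

    # per-background precomputation
    prepared = []
    for bg, tis in backgrounds:
        clear = clearance_map(tis, constraints)
        bands = region_bands(tis, constraints.n_regions)
        prepared.append((bg, tis, clear, bands))

    records: list[CompositeRecord] = []
    pair = 0
    for sid, patches in lesion_slices:
        patch_bands = assign_bands(patches, constraints.n_regions)
        for bg, tis, clear, bands in prepared:
            rng = substream(seed, "compose", pair)
            pair += 1
            canvas = bg.pixels.copy()
            occupied = np.zeros(bg.shape, dtype=bool)
            boxes: list[BoundingBox] = []
            for patch, band in zip(patches, patch_bands):
                h, w = patch.shape
                sel = clear & (bands == band)
                ys, xs = np.nonzero(sel)
                if ys.size == 0:
                    raise PlacementError(
                        f"pair {sid}x{bg.image_id}: band {band} has no clearance"
                    )
                placed = False
                for _ in range(constraints.max_attempts):
                    k = rng.integers(ys.size)
                    cy, cx = int(ys[k]), int(xs[k])
                    y0, x0 = cy - h // 2, cx - w // 2
                    if x0 < 0 or y0 < 0 or x0 + w > bg.width or y0 + h > bg.height:
                        continue
                    sl = (slice(y0, y0 + h), slice(x0, x0 + w))
                    if not clear[sl].all():
                        continue
                    if occupied[sl][patch.mask].any():
                        continue
                    blended = _blend(canvas[sl], patch, constraints.feather)
                    window = canvas[sl]
                    window[patch.mask] = np.clip(
                        np.round(blended[patch.mask]), 0, 255
                    ).astype(np.uint8)
                    occupied[sl] |= ndimage.binary_dilation(
                        patch.mask, structure=np.ones((3, 3))
                    )
                    boxes.append(BoundingBox.from_mask(patch.mask).shift(x0, y0))
                    placed = True
                    break
                if not placed:
                    raise PlacementError(
                        f"pair {sid}x{bg.image_id}: patch unplaceable after "
                        f"{constraints.max_attempts} attempts"
                    )
            records.append(
                CompositeRecord(
                    image=ImageSlice(canvas, bg.pixel_size_mm),
                    boxes=boxes,
                    background_id=bg.image_id,
                    lesion_slice_id=sid,
                    transform_tag="orig",
                    tissue=tis,
                )
            )
    logger.info(
        "built %d composites (%d lesion slices x %d backgrounds)",
        len(records), len(lesion_slices), len(backgrounds),
    )
    return records
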