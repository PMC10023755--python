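"""Punctate lesion extraction and the reusable patch bank.

Emulates interactive lesion selection with reproducible rules: a pixel is a
lesion candidate when it exceeds its local background mean by ``k_sigma``
local standard deviations; candidates are grouped into connected components
and filtered by the study's inclusion rules —

* area within ``[min_area, max_area]`` px ("widespread" lesions excluded),
* elongation (sqrt ratio of principal second central moments) at most
  ``max_elongation`` ("linear" lesions excluded),
* peak-above-local-mean at least ``min_contrast`` ("faint" signals excluded),
* centroid inside white matter when a tissue map is supplied.

Local statistics use a sliding ``local_window`` box, computed in two passes:
the second pass excludes first-pass candidate pixels (dilated by 1 px) so a
lesion does not inflate its own background estimate.  When a tissue map is
given the statistics are additionally restricted to white-matter pixels, so
tissue boundaries do not bleed into the background estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

from .types import WHITE_MATTER, BoundingBox, ImageSlice, LesionPatch, TissueMask

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class ExtractionParams:
    k_sigma: float = 3.0
    min_area: int = 3
    max_area: int = 40
    max_elongation: float = 3.0
    min_contrast: float = 10.0
    connectivity: int = 8        # 4 or 8
    local_window: int = 15       # sliding-window side for background stats
    delineation_level: float = 0.25  # mask grows to this fraction of peak-above-mean
    boundary_margin: int = 3     # px of WM eroded away to skip partial-volume rims

    def __post_init__(self) -> None:
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")
        if self.max_elongation < 1:
            raise ValueError("max_elongation must be >= 1")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.local_window < 3:
            raise ValueError("local_window must be >= 3")
        if not (0.0 < self.delineation_level < 1.0):
            raise ValueError("delineation_level must lie in (0, 1)")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")


def local_background_stats(
    img: np.ndarray,
    window: int,
    valid: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and SD over ``valid & ~exclude`` pixels.

    Pixels with no valid neighbors get mean 0 and a large SD so they can
    never become candidates.
    """
    f = img.astype(float)
    w = np.ones_like(f, dtype=bool) if valid is None else valid.copy()
    if exclude is not None:
        w &= ~exclude
    wf = w.astype(float)
    size = window
    cnt = ndimage.uniform_filter(wf, size=size)
    s1 = ndimage.uniform_filter(f * wf, size=size)
    s2 = ndimage.uniform_filter(f * f * wf, size=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > _EPS, s1 / np.maximum(cnt, _EPS), 0.0)
        var = np.where(cnt > _EPS, s2 / np.maximum(cnt, _EPS) - mean ** 2, np.inf)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[cnt <= _EPS] = np.inf
    return mean, sd


def component_elongation(mask: np.ndarray) -> float:
    """sqrt of the ratio of the principal second central moments.

    1.0 for an isotropic blob; infinity for a strictly collinear component.
    Single pixels are defined as elongation 1.
    """
    ys, xs = np.nonzero(mask)
    if ys.size <= 1:
        return 1.0
    cov = np.cov(np.vstack([xs, ys]).astype(float))
    ev = np.linalg.eigvalsh(cov)
    lo, hi = float(ev[0]), float(ev[1])
    if hi <= _EPS:
        return 1.0
    if lo <= _EPS:
        return math.inf
    return math.sqrt(hi / lo)


def extract_lesions(
    image: ImageSlice,
    tissue: TissueMask | None = None,
    params: ExtractionParams = ExtractionParams(),
    source_id: str = "",
) -> list[LesionPatch]:
    """Extract punctate lesion patches from one (normalized) slice.

    Returns an empty list when nothing passes the rules.
    """
    img = image.pixels.astype(float)
    valid = None
    if tissue is not None:
        valid = tissue.region(WHITE_MATTER)
        if params.boundary_margin > 0:
            # skip the partial-volume rim where cortex brightness bleeds in
            valid = ndimage.binary_erosion(
                valid, structure=np.ones((3, 3)), iterations=params.boundary_margin
            )

    # pass 1: provisional candidates from robust (median/MAD) local stats —
    # unlike mean/SD these are immune to the lesion's own pixels, which can
    # otherwise inflate the local SD enough to mask the lesion entirely
    med_bg = ndimage.median_filter(img, size=params.local_window)
    mad = ndimage.median_filter(np.abs(img - med_bg), size=params.local_window)
    robust_sd = 1.4826 * mad
    cand = img > med_bg + params.k_sigma * robust_sd
    if valid is not None:
        cand &= valid

    # pass 2: re-estimate background excluding candidates and a 3-px halo
    # (wide enough to cover lesion pixels the first pass missed, so a lesion
    # cannot inflate its own background statistics)
    halo = ndimage.binary_dilation(cand, structure=np.ones((3, 3)), iterations=3)
    mean2, sd2 = local_background_stats(img, params.local_window, valid, exclude=halo)
    final = img > mean2 + params.k_sigma * sd2
    if valid is not None:
        final &= valid

    conn = 1 if params.connectivity == 4 else 2
    labeled, n_comp = measure.label(final, connectivity=conn, return_num=True)
    # delineation field: a 3x3 median strips single-pixel noise excursions
    # while preserving multi-pixel punctate blobs
    med = ndimage.median_filter(img, size=3)

    patches: list[LesionPatch] = []
    for lab in range(1, n_comp + 1):
        comp = labeled == lab
        area = int(comp.sum())
        # the super-threshold core must already be punctate-sized: smaller
        # cores are indistinguishable from clustered noise at k_sigma ~ 3
        if not (params.min_area <= area <= params.max_area):
            continue
        ys, xs = np.nonzero(comp)
        peak_idx = np.argmax(img[ys, xs])
        py, px = int(ys[peak_idx]), int(xs[peak_idx])
        contrast = img[py, px] - mean2[py, px]
        if contrast < params.min_contrast:
            continue
        mask, level = _delineate(med, comp, mean2[py, px], valid, params, conn)
        if mask is None:
            continue  # widespread: delineation exceeded max_area
        if component_elongation(mask) > params.max_elongation:
            continue
        mys, mxs = np.nonzero(mask)
        cx, cy = float(mxs.mean()), float(mys.mean())
        if valid is not None and not valid[int(round(cy)), int(round(cx))]:
            continue
        bbox = BoundingBox.from_mask(mask)
        rs, cs = bbox.slices
        patches.append(
            LesionPatch(
                patch=image.pixels[rs, cs].copy(),
                mask=mask[rs, cs].copy(),
                source_id=source_id or image.image_id,
                bbox_in_source=bbox,
                centroid=(cx, cy),
            )
        )
    return patches


def _delineate(
    med: np.ndarray,
    core: np.ndarray,
    background_level: float,
    valid: np.ndarray | None,
    params: ExtractionParams,
    conn: int,
) -> tuple[np.ndarray | None, float]:
    """Grow a detection core down to its delineation level set.

    The mask is the connected level-set region seeded by the core: pixels of
    the median field strictly above ``background + delineation_level *
    (median_peak - background)`` — the tolerance semantics of interactive
    auto-selection, evaluated on the denoised field.  Returns ``(None,
    level)`` when no core pixel clears the level (pure noise core) or the
    grown region exceeds ``max_area`` ("widespread" lesions are excluded).
    """
    med_peak = float(med[core].max())
    level = background_level + params.delineation_level * (med_peak - background_level)
    above = med > level
    if valid is not None:
        above &= valid
    lab = measure.label(above, connectivity=conn)
    seeds = np.unique(lab[core & above])
    seeds = seeds[seeds > 0]
    if seeds.size == 0:
        return None, level
    region = np.isin(lab, seeds)
    if int(region.sum()) > params.max_area:
        return None, level
    return region, level


# ---------------------------------------------------------------------------
# bank persistence
# ---------------------------------------------------------------------------

def save_bank(patches: list[LesionPatch], out_dir: str | Path) -> Path:
    """Write patch/mask PNG pairs plus a ``bank.csv`` provenance table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        pid = f"patch_{i:04d}"
        Image.fromarray(p.patch).save(out / f"{pid}.png")
        Image.fromarray((p.mask * 255).astype(np.uint8)).save(out / f"{pid}_mask.png")
        b = p.bbox_in_source
        rows.append(
            {
                "patch_id": pid,
                "source_id": p.source_id,
                "x_min": b.x_min,
                "y_min": b.y_min,
                "x_max": b.x_max,
                "y_max": b.y_max,
                "area": p.area,
                "elongation": round(component_elongation(p.mask), 4),
                "centroid_x": p.centroid[0],
                "centroid_y": p.centroid[1],
            }
        )
    pd.DataFrame(rows).to_csv(out / "bank.csv", index=False)
    return out


def load_bank(bank_dir: str | Path) -> list[LesionPatch]:
    bank = Path(bank_dir)
    df = pd.read_csv(bank / "bank.csv")
    patches: list[LesionPatch] = []
    for _, row in df.iterrows():
        patch = np.asarray(Image.open(bank / f"{row.patch_id}.png"))
        mask = np.asarray(Image.open(bank / f"{row.patch_id}_mask.png")) > 127
        patches.append(
            LesionPatch(
                patch=patch,
                mask=mask,
                source_id=str(row.source_id),
                bbox_in_source=BoundingBox(
                    int(row.x_min), int(row.y_min), int(row.x_max), int(row.y_max)
                ),
                centroid=(float(row.centroid_x), float(row.centroid_y)),
            )
        )
    return patches
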