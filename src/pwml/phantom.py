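"""Synthetic infant-brain slice phantom.

Generates 2-D T1-like slices with a known tissue map (background, cortical
ribbon, white matter, two ventricles) and injects punctate hyperintense foci
into the white matter with exact ground-truth boxes.  The phantom stands in
for clinical images: it reproduces the *geometry of the task* (small bright
blobs inside WM, a bright cortex ribbon that can attract false positives)
rather than MR physics.

Geometry is a pair of concentric ellipses (brain outline and cortical ribbon
of fixed pixel thickness) with two crescent-shaped ventricles flanking the
midline.  Intensities follow the neonatal T1 ordering: cortex brighter than
unmyelinated white matter, CSF dark.  Lesions are isotropic Gaussian bumps
truncated at 2*sigma; the ground-truth mask is the bump's > 0.25*peak level
set (radius ``sqrt(2 ln 4) * sigma`` ~ 1.665 sigma), and the ground-truth box
is the tight half-open bounding box of that mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rng import substream
from .types import (
    BACKGROUND,
    CORTEX,
    VENTRICLE,
    WHITE_MATTER,
    BoundingBox,
    ImageSlice,
    TissueMask,
)

#: mask level-set radius in sigmas: the 0.25-of-peak isocontour of a Gaussian
MASK_RADIUS_SIGMAS = math.sqrt(2.0 * math.log(4.0))  # ~1.6651
#: bump truncation radius in sigmas
FOOTPRINT_RADIUS_SIGMAS = 2.0


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a lesion."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one synthetic slice."""

    image_size: int = 256
    cortex_thickness: int = 8          # ribbon width, px
    ventricle_scale: float = 0.22      # ventricle size, fraction of brain radius
    wm_mean: float = 120.0
    cortex_mean: float = 170.0
    ventricle_mean: float = 50.0
    background_mean: float = 12.0
    noise_sd: float = 5.0
    pixel_size_mm: float = 0.83
    edge_smooth_sigma: float = 1.0     # partial-volume-like boundary blur
    shape_jitter: float = 0.03         # relative jitter of the brain semi-axes

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("wm_mean", "cortex_mean", "ventricle_mean", "background_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} outside [0, 255]: {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cortex_thickness < 1:
            raise ValueError("cortex_thickness must be >= 1")
        # the cortex ribbon plus ventricles must leave room for white matter
        if self.image_size < 8 * self.cortex_thickness:
            raise ValueError("image too small for the requested cortex thickness")


@dataclass(frozen=True)
class LesionSpec:
    """How many punctate foci to inject and how they look."""

    count: int = 5
    diameter_px: tuple[float, float] = (2.0, 6.0)   # mask diameter range
    contrast: float = 50.0                          # peak offset over local WM
    wm_margin: int = 3                              # extra px of depth inside WM
    # per-case count sampling: truncated/rounded normal
    count_min: int = 1
    count_max: int = 19
    count_mean: float = 6.0
    count_sd: float = 5.4

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        lo, hi = self.diameter_px
        if not (1.0 <= lo <= hi <= 15.0):
            raise ValueError("diameter_px must lie within [1, 15]")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")


@dataclass(frozen=True)
class LesionInjection:
    """Provenance record of one injected focus (for oracles and audits)."""

    center: tuple[float, float]   # (x, y)
    sigma: float
    contrast: float
    box: BoundingBox
    mask_area: int


# ---------------------------------------------------------------------------
# slice generation
# ---------------------------------------------------------------------------

def _ellipse(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
             rx: float, ry: float, angle_deg: float = 0.0) -> np.ndarray:
    t = math.radians(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_slice(params: PhantomParams = PhantomParams(),
                   seed: int = 0) -> tuple[ImageSlice, TissueMask]:
    """Generate one phantom slice and its tissue label map.

    Deterministic for fixed ``(params, seed)``.  The label map partitions
    every pixel; white matter forms a single 8-connected component interior
    to the cortical ribbon (it rings the ventricles, so it is connected but
    not hole-free).
    """
    rng = substream(seed, "phantom-slice")
    n = params.image_size
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    j = params.shape_jitter
    rx = 0.40 * n * (1.0 + j * rng.uniform(-1, 1))
    ry = 0.34 * n * (1.0 + j * rng.uniform(-1, 1))

    brain = _ellipse(xx, yy, cx, cy, rx, ry)
    depth = ndimage.distance_transform_edt(brain)
    cortex = brain & (depth <= params.cortex_thickness)
    interior = brain & ~cortex

    # two crescent-ish ventricles flanking the midline, strictly interior
    vr = params.ventricle_scale * min(rx, ry)
    off = 0.22 * rx
    vent = np.zeros_like(brain)
    for side, tilt in ((-1.0, -12.0), (1.0, 12.0)):
        vcx = cx + side * off
        vent |= _ellipse(xx, yy, vcx, cy, 0.38 * vr, 1.15 * vr, tilt)
    vent &= ndimage.binary_erosion(interior, iterations=3)

    labels = np.full((n, n), BACKGROUND, dtype=np.uint8)
    labels[cortex] = CORTEX
    labels[interior] = WHITE_MATTER
    labels[vent] = VENTRICLE

    means = {
        BACKGROUND: params.background_mean,
        CORTEX: params.cortex_mean,
        WHITE_MATTER: params.wm_mean,
        VENTRICLE: params.ventricle_mean,
    }
    img = np.zeros((n, n), dtype=float)
    for lab, mu in means.items():
        img[labels == lab] = mu
    if params.edge_smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.edge_smooth_sigma)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return ImageSlice(img, params.pixel_size_mm), TissueMask(labels)


# ---------------------------------------------------------------------------
# lesion injection
# ---------------------------------------------------------------------------

def _bump(sigma: float, contrast: float) -> tuple[np.ndarray, np.ndarray]:
    """Truncated Gaussian bump and its >0.25*peak mask, both (2r+1)^2."""
    r = int(math.ceil(FOOTPRINT_RADIUS_SIGMAS * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    d2 = xx ** 2 + yy ** 2
    bump = contrast * np.exp(-d2 / (2.0 * sigma ** 2))
    bump[d2 > (FOOTPRINT_RADIUS_SIGMAS * sigma) ** 2] = 0.0
    mask = d2 <= (MASK_RADIUS_SIGMAS * sigma) ** 2
    return bump, mask


def sample_lesion_count(spec: LesionSpec, rng: np.random.Generator) -> int:
    """Draw a per-case lesion count: rounded normal clipped to [min, max]."""
    c = int(round(rng.normal(spec.count_mean, spec.count_sd)))
    return int(np.clip(c, spec.count_min, spec.count_max))


def inject_lesions_with_records(
    image: ImageSlice,
    tissue: TissueMask,
    spec: LesionSpec = LesionSpec(),
    seed: int = 0,
    max_attempts: int = 200,
) -> tuple[ImageSlice, list[LesionInjection]]:
    """Inject ``spec.count`` non-overlapping foci fully inside white matter.

    Returns the modified image and one provenance record per focus.  Pixels
    outside the (truncated) bump footprints are untouched.  Raises
    :class:`PlacementError` when the white matter cannot host another focus
    after ``max_attempts`` rejections.
    """
    if spec.count == 0:
        return image.copy(), []

    rng = substream(seed, "inject")
    wm = tissue.region(WHITE_MATTER)
    out = image.pixels.astype(float)
    occupied = np.zeros_like(wm)
    records: list[LesionInjection] = []

    n_rows, n_cols = wm.shape
    for _ in range(spec.count):
        diameter = rng.uniform(*spec.diameter_px)
        sigma = diameter / (2.0 * MASK_RADIUS_SIGMAS)
        bump, mask = _bump(sigma, spec.contrast)
        r = bump.shape[0] // 2

        # centers whose whole footprint sits inside WM, wm_margin px deep
        allowed = ndimage.binary_erosion(
            wm, structure=np.ones((3, 3)), iterations=max(r, 1) + spec.wm_margin
        )
        ys, xs = np.nonzero(allowed)
        if ys.size == 0:
            raise PlacementError("white matter too small for lesion footprint")

        placed = False
        for _ in range(max_attempts):
            k = rng.integers(ys.size)
            cy, cx = int(ys[k]), int(xs[k])
            sl = (slice(cy - r, cy + r + 1), slice(cx - r, cx + r + 1))
            if occupied[sl].any():
                continue
            if not wm[sl][mask].all():
                continue
            out[sl] += bump
            occupied[sl] |= mask
            box = BoundingBox.from_mask(mask).shift(cx - r, cy - r)
            records.append(
                LesionInjection(
                    center=(float(cx), float(cy)),
                    sigma=sigma,
                    contrast=spec.contrast,
                    box=box,
                    mask_area=int(mask.sum()),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place lesion {len(records)} after {max_attempts} attempts"
            )

    img = ImageSlice(
        np.clip(np.round(out), 0, 255).astype(np.uint8),
        image.pixel_size_mm,
        image.image_id,
    )
    return img, records


def inject_lesions(
    image: ImageSlice,
    tissue: TissueMask,
    spec: LesionSpec = LesionSpec(),
    seed: int = 0,
) -> tuple[ImageSlice, list[BoundingBox]]:
    """Spec-level interface: modified image plus ground-truth boxes only."""
    img, records = inject_lesions_with_records(image, tissue, spec, seed)
    return img, [r.box for r in records]


# ---------------------------------------------------------------------------
# cases and datasets
# ---------------------------------------------------------------------------

@dataclass
class LesionSlice:
    """A lesion-bearing phantom slice with full injection provenance."""

    slice_id: str
    image: ImageSlice
    tissue: TissueMask
    records: list[LesionInjection] = field(default_factory=list)

    @property
    def boxes(self) -> list[BoundingBox]:
        return [r.box for r in self.records]


def distribute_lesions(total: int, n_slices: int) -> list[int]:
    """Split ``total`` lesions over ``n_slices`` as evenly as possible."""
    if n_slices < 1 or total < n_slices:
        raise ValueError("need total >= n_slices >= 1")
    base, extra = divmod(total, n_slices)
    return [base + (1 if i < extra else 0) for i in range(n_slices)]


def generate_source_case(
    case_id: str,
    total_lesions: int,
    n_slices: int,
    params: PhantomParams = PhantomParams(),
    spec: LesionSpec = LesionSpec(),
    seed: int = 0,
) -> list[LesionSlice]:
    """One 'source case': a stack of lesion-bearing slices sharing a seed lineage."""
    slices: list[LesionSlice] = []
    for i, count in enumerate(distribute_lesions(total_lesions, n_slices)):
        sub = substream(seed, f"case-{case_id}", i)
        s_img = int(sub.integers(2 ** 31))
        s_inj = int(sub.integers(2 ** 31))
        img, tis = generate_slice(params, seed=s_img)
        per_slice = LesionSpec(
            count=count,
            diameter_px=spec.diameter_px,
            contrast=spec.contrast,
            count_min=spec.count_min,
            count_max=spec.count_max,
            count_mean=spec.count_mean,
            count_sd=spec.count_sd,
        )
        img, records = inject_lesions_with_records(img, tis, per_slice, seed=s_inj)
        sid = f"{case_id}-s{i:02d}"
        img.image_id = sid
        slices.append(LesionSlice(sid, img, tis, records))
    return slices


def generate_backgrounds(
    n: int,
    params: PhantomParams = PhantomParams(),
    seed: int = 0,
) -> list[tuple[ImageSlice, TissueMask]]:
    """``n`` normal (lesion-free) slices, each from its own substream."""
    out = []
    for i in range(n):
        sub = substream(seed, "background", i)
        img, tis = generate_slice(params, seed=int(sub.integers(2 ** 31)))
        img.image_id = f"bg-{i:03d}"
        out.append((img, tis))
    return out
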