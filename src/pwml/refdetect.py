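"""Reference blob detector: multiscale Laplacian-of-Gaussian maxima.

A deterministic classical detector producing probability-like scores so the
full compose -> annotate -> detect -> evaluate loop runs without a trained
network.  It is *not* a neural detector and its scores are not calibrated
probabilities: each detection's ``probability_percent`` is
``100 * response / max-response-in-image``, a crude but monotone map — a
higher-contrast blob never scores below a lower-contrast blob of the same
size in the same image.

Bright punctate foci give strong scale-normalized LoG responses; so do
small bright protrusions of the cortical ribbon, which is what makes the
false-positive localisation stage worth exercising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import MASK_RADIUS_SIGMAS
from .types import BoundingBox, Detection, ImageSlice


@dataclass(frozen=True)
class DetectorParams:
    scales_px: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0)  # blob radii
    response_floor: float = 0.05     # fraction of the per-image max response
    nms_iou: float = 0.3
    presmooth_sigma: float = 0.8     # denoising blur before the LoG bank
    max_candidates: int = 400        # pre-NMS cap, strongest responses first
    edge_ratio: float = 10.0         # Hessian tr^2/det edge rejection (SIFT-style)
    min_intensity_frac: float = 0.2  # of the image max: rejects near-air centers

    def __post_init__(self) -> None:
        if list(self.scales_px) != sorted(self.scales_px):
            raise ValueError("scales_px must be ascending")
        if not (0.0 <= self.nms_iou < 1.0):
            raise ValueError("nms_iou must lie in [0, 1)")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")


def _box_at(cx: int, cy: int, radius: float,
            width: int, height: int) -> BoundingBox | None:
    r = max(1, int(round(radius)))
    return BoundingBox(cx - r, cy - r, cx + r + 1, cy + r + 1).clip(width, height)


def greedy_nms(candidates: list[tuple[float, BoundingBox]],
               iou_threshold: float) -> list[tuple[float, BoundingBox]]:
    """Keep boxes in descending score order, suppressing IoU overlaps."""
    kept: list[tuple[float, BoundingBox]] = []
    for score, box in candidates:
        suppressed = any(
            (box.iou(kb) >= iou_threshold) if iou_threshold > 0.0 else (box.iou(kb) > 0.0)
            for _, kb in kept
        )
        if not suppressed:
            kept.append((score, box))
    return kept


def detect(image: ImageSlice,
           params: DetectorParams = DetectorParams()) -> list[Detection]:
    """Run the LoG detector on one grayscale slice (deterministic)."""
    img = image.pixels.astype(float)
    if params.presmooth_sigma > 0:
        img = ndimage.gaussian_filter(img, params.presmooth_sigma)
    h, w = img.shape
    responses = []
    blobness = []
    for r in params.scales_px:
        sigma = r / MASK_RADIUS_SIGMAS
        responses.append(-(sigma ** 2) * ndimage.gaussian_laplace(img, sigma))
        # Hessian edge rejection: ridges/edges have tr^2/det >> 4, blobs ~ 4
        hxx = ndimage.gaussian_filter(img, sigma, order=(0, 2))
        hyy = ndimage.gaussian_filter(img, sigma, order=(2, 0))
        hxy = ndimage.gaussian_filter(img, sigma, order=(1, 1))
        det = hxx * hyy - hxy ** 2
        tr2 = (hxx + hyy) ** 2
        limit = (params.edge_ratio + 1.0) ** 2 / params.edge_ratio
        blobness.append((det > 0) & (tr2 <= limit * det))
    cube = np.stack(responses)  # (S, H, W); positive at bright blobs
    bloblike = np.stack(blobness)

    local_max = cube == ndimage.maximum_filter(cube, size=(3, 3, 3), mode="nearest")
    # detections centred on near-air intensities are meaningless; the
    # absolute floor (0.5 intensity units) sits far below any real blob
    # response but above the truncated-kernel bias a flat image produces
    tissue_like = img >= params.min_intensity_frac * float(img.max())
    accepted = local_max & bloblike & (cube > 0.5) & tissue_like[None, :, :]
    if not accepted.any():
        return []
    max_resp = float(cube[accepted].max())  # normalise over accepted blobs
    strong = accepted & (cube >= params.response_floor * max_resp)
    ss, ys, xs = np.nonzero(strong)

    candidates: list[tuple[float, BoundingBox]] = []
    for s, y, x in zip(ss, ys, xs):
        box = _box_at(int(x), int(y), params.scales_px[s], w, h)
        if box is not None:
            candidates.append((float(cube[s, y, x]), box))
    # deterministic order: score desc, then position
    candidates.sort(key=lambda t: (-t[0], t[1].y_min, t[1].x_min))
    kept = greedy_nms(candidates[: params.max_candidates], params.nms_iou)

    return [
        Detection(
            image_id=image.image_id,
            box=box,
            probability_percent=min(100.0, 100.0 * score / max_resp),
        )
        for score, box in kept
    ]
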