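"""Intensity normalization: percentile-clipped linear contrast stretch.

Models the interactive auto-contrast/auto-tone adjustment applied to both
lesion-bearing and normal slices before compositing.  For a single-channel
image both commands reduce to the same operation: clip a small fraction of
pixels at each intensity tail and stretch the remainder linearly to the full
output range.  Output is re-quantized to 8 bits with round-half-away-from-
zero.  The mapping is monotone non-decreasing, idempotent (a stretched image
re-stretches to itself), and leaves constant images untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ImageSlice


@dataclass(frozen=True)
class NormalizeParams:
    clip_low: float = 0.001    # fraction of pixels clipped at the dark tail
    clip_high: float = 0.001   # fraction clipped at the bright tail
    out_min: int = 0
    out_max: int = 255

    def __post_init__(self) -> None:
        if self.clip_low < 0 or self.clip_high < 0 or self.clip_low + self.clip_high >= 1:
            raise ValueError("clip fractions must satisfy 0 <= low + high < 1")
        if self.out_min >= self.out_max:
            raise ValueError("out_min must be < out_max")


def stretch_endpoints(values: np.ndarray, clip_low: float,
                      clip_high: float) -> tuple[int, int]:
    """Dark/bright clip endpoints: order statistics at the clip counts.

    With ``n`` pixels, the dark endpoint is the ``floor(clip_low*n)``-th
    smallest value and the bright endpoint the ``floor(clip_high*n)``-th
    largest, so at least that many pixels saturate at each end.
    """
    v = np.sort(np.asarray(values).ravel())
    n = v.size
    k_lo = int(math.floor(clip_low * n))
    k_hi = int(math.floor(clip_high * n))
    return int(v[k_lo]), int(v[n - 1 - k_hi])


def auto_contrast(image: ImageSlice,
                  params: NormalizeParams = NormalizeParams()) -> ImageSlice:
    """Percentile-clipped linear stretch to ``[out_min, out_max]``.

    Degenerate inputs (constant, or clip endpoints that coincide) are
    returned unchanged.
    """
    px = image.pixels
    if px.size == 0:
        raise ValueError("empty image")
    lo, hi = stretch_endpoints(px, params.clip_low, params.clip_high)
    if hi <= lo:
        return image.copy()
    scale = (params.out_max - params.out_min) / float(hi - lo)
    out = (px.astype(float) - lo) * scale + params.out_min
    out = np.clip(out, params.out_min, params.out_max)
    # round half away from zero (values are non-negative here)
    out = np.floor(out + 0.5).astype(np.uint8)
    return ImageSlice(out, image.pixel_size_mm, image.image_id)
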