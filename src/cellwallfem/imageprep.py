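"""Micrograph preprocessing: 8-bit conversion, sharpening, contrast
windowing and repeated despeckling.

The chain mirrors the standard ImageJ workflow for stained stem sections:
convert to 8-bit, sharpen, stretch the display window so dark walls and
bright interiors separate, then run a 3×3 median ("despeckle") several times
to suppress sectioning debris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterImage

#: ImageJ "Sharpen": 3×3 convolution, centre 12, neighbours −1, divisor 4.
SHARPEN_KERNEL = np.array([[-1, -1, -1],
                           [-1, 12, -1],
                           [-1, -1, -1]], dtype=np.float64) / 4.0


@dataclass
class PrepParams:
    """Preprocessing parameters.

    ``display_min``/``display_max`` define the brightness/contrast window
    mapped onto [0, 255]; the minimum may be negative.  Defaults are the
    typical window for Safranin-O stained maize sections; individual images
    may need slight adjustment.
    """

    display_min: float = -10.0
    display_max: float = 127.0
    despeckle_repeats: int = 3
    sharpen: bool = True

    def __post_init__(self) -> None:
        if self.display_min >= self.display_max:
            raise ValueError("display_min must be < display_max")
        if self.despeckle_repeats < 0:
            raise ValueError("despeckle_repeats must be >= 0")


def to_8bit(img: RasterImage) -> RasterImage:
    """Convert to 8-bit by linearly mapping [min, max] onto [0, 255].

    Already-8-bit images pass through unchanged; a constant image maps to 0.
    """
    if img.bit_depth == 8:
        return img.with_pixels(img.pixels.copy())
    px = img.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = np.round(255.0 * (px - lo) / (hi - lo))
    return img.with_pixels(out, bit_depth=8)


def sharpen(img: RasterImage) -> RasterImage:
    """ImageJ-style sharpen; borders replicate edge pixels, output clipped."""
    px = img.pixels.astype(np.float64)
    out = ndimage.correlate(px, SHARPEN_KERNEL, mode="nearest")
    return img.with_pixels(np.clip(np.round(out), 0, 255))


def rescale_contrast(img: RasterImage, params: PrepParams) -> RasterImage:
    """Map the window [display_min, display_max] onto [0, 255] with clipping."""
    lo, hi = params.display_min, params.display_max
    px = img.pixels.astype(np.float64)
    out = np.clip(np.round(255.0 * (px - lo) / (hi - lo)), 0, 255)
    return img.with_pixels(out)


def despeckle(img: RasterImage, repeats: int = 3) -> RasterImage:
    """Apply a 3×3 median filter ``repeats`` times (edge replication)."""
    if repeats < 0:
        raise ValueError("repeats must be >= 0")
    px = img.pixels.astype(np.float64)
    for _ in range(repeats):
        px = ndimage.median_filter(px, size=3, mode="nearest")
    return img.with_pixels(px)


def preprocess(img: RasterImage, params: PrepParams | None = None) -> RasterImage:
    """Full chain: 8-bit → sharpen → contrast window → despeckle × n."""
    params = params or PrepParams()
    out = to_8bit(img)
    if params.sharpen:
        out = sharpen(out)
    out = rescale_contrast(out, params)
    return despeckle(out, params.despeckle_repeats)
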