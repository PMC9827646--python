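"""Raster image container and file I/O.

A micrograph is held as a 2-D intensity grid plus its bit depth and an
optional spatial calibration (micrometres per pixel).  Colour images are
collapsed to grayscale on load by an unweighted channel mean; all downstream
stages operate on single-channel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class RasterImage:
    """A 2-D grayscale raster with bit depth and optional μm/px scale.

    Parameters
    ----------
    pixels:
        2-D array of intensities, row 0 at the top.  Stored as float64 or an
        integer dtype; values must lie in ``[0, 2**bit_depth - 1]``.
    bit_depth:
        8 or 16.
    scale:
        Micrometres per pixel.  May be left ``None`` until the finite
        element stage, which requires calibrated geometry.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    scale: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        vmax = 2**self.bit_depth - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise ValueError(f"intensities outside [0, {vmax}]")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale (μm per pixel) must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, bit_depth: int | None = None) -> "RasterImage":
        """Copy carrying the calibration over to a new pixel grid."""
        return replace(self, pixels=pixels,
                       bit_depth=self.bit_depth if bit_depth is None else bit_depth)


def load_image(path: str | Path, scale: float | None = None) -> RasterImage:
    """Read a TIFF/PNG/JPEG raster; RGB collapses to the channel mean."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A): unweighted mean of the colour channels
        arr = arr[..., :3].astype(np.float64).mean(axis=2)
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        arr = arr.astype(np.float64)
        bit_depth = 8
    return RasterImage(np.asarray(arr, dtype=np.float64), bit_depth=bit_depth, scale=scale)


def save_image(img: RasterImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale (2-D) or RGB (H×W×3) PNG/TIFF."""
    arr = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def mask_to_png(mask: np.ndarray, path: str | Path) -> None:
    """Serialize a boolean mask as a 0/255 8-bit PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def png_to_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128
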