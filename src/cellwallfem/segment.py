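"""Wall segmentation: band thresholding with automated cleanup, a trainable
pixel classifier, the Euclidean distance map, and distance-based thinning.

Two interchangeable routes produce a binary wall mask from a preprocessed
micrograph:

* ``band_threshold`` + ``clean_mask`` — the manual-thresholding route.
  Dark cell walls fall inside an intensity band (default 0–175 on 8-bit
  data); speckles and enclosed holes below an area cutoff are removed.
* ``train_classifier`` + ``classify`` — a two-class trainable pixel
  classifier (wall vs interior) in the spirit of interactive machine-
  learning segmentation tools, using intensity, Gaussian-smoothed intensity
  and gradient-magnitude features at several scales.

The mask is then converted to a Euclidean distance map (each wall pixel
holds its exact distance to the nearest non-wall pixel) and thinned by
keeping only pixels at depth ``thin_keep_min`` or more, which separates
touching cells while preserving wall topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .raster import RasterImage


@dataclass
class ThresholdParams:
    """Band-threshold and cleanup parameters (intensities on the 8-bit scale,
    areas in pixels, distances in pixel units)."""

    lo: float = 0.0
    hi: float = 175.0
    thin_keep_min: float = 0.0
    min_speck_area: int = 0
    max_hole_area: int = 0

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("invalid band: lo > hi")
        if self.thin_keep_min < 0:
            raise ValueError("thin_keep_min must be >= 0")


def band_threshold(img: RasterImage, p: ThresholdParams) -> np.ndarray:
    """Wall mask: pixel is wall iff ``lo <= intensity <= hi`` (inclusive)."""
    if p.lo > p.hi:
        raise ValueError("invalid band: lo > hi")
    px = img.pixels
    return (px >= p.lo) & (px <= p.hi)


def clean_mask(mask: np.ndarray, p: ThresholdParams) -> np.ndarray:
    """Remove small wall specks, then fill small enclosed background holes.

    Wall components are 8-connected; holes are 4-connected background
    regions not touching the image border.  Components strictly below the
    respective area threshold are removed/filled.
    """
    out = np.asarray(mask, dtype=bool).copy()
    if p.min_speck_area > 0:
        lab, n = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(lab.ravel(), minlength=n + 1)
            small = areas < p.min_speck_area
            small[0] = False
            out &= ~np.isin(lab, np.flatnonzero(small))
    if p.max_hole_area > 0:
        lab, n = ndimage.label(~out,
                               structure=ndimage.generate_binary_structure(2, 1))
        if n:
            areas = np.bincount(lab.ravel(), minlength=n + 1)
            border = np.unique(np.concatenate(
                [lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
            small = areas < p.max_hole_area
            small[border] = False  # border-touching background is not a hole
            out |= np.isin(lab, np.flatnonzero(small))
    return out


def edm(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance map of a wall mask.

    Each wall pixel receives the Euclidean distance (pixel units,
    centre-to-centre) to the nearest background pixel; background pixels are
    0.  The image border is *not* treated as background, so walls touching
    the crop edge keep their full depth.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("EDM undefined: mask has no background pixels")
    return ndimage.distance_transform_edt(mask)


def thin_walls(mask: np.ndarray, d: np.ndarray, p: ThresholdParams) -> np.ndarray:
    """Keep wall pixels at EDM depth >= ``thin_keep_min``; a subset of mask."""
    return np.asarray(mask, dtype=bool) & (d >= p.thin_keep_min)


# ---------------------------------------------------------------------------
# Trainable pixel classifier
# ---------------------------------------------------------------------------

WALL_CLASS = 1
INTERIOR_CLASS = 2


@dataclass
class PixelClassifier:
    """A trained two-class (wall vs interior) pixel classifier."""

    scales: tuple[float, ...]
    model: RandomForestClassifier
    n_train: int
    seed: int

    def features(self, img: RasterImage) -> np.ndarray:
        return _feature_stack(img.pixels.astype(np.float64), self.scales)


def _feature_stack(px: np.ndarray, scales: tuple[float, ...]) -> np.ndarray:
    """Per-pixel feature bank: raw intensity plus, at each scale, the
    Gaussian-smoothed intensity and its gradient magnitude."""
    feats = [px]
    for s in scales:
        sm = ndimage.gaussian_filter(px, sigma=s, mode="nearest")
        gy = ndimage.sobel(sm, axis=0, mode="nearest")
        gx = ndimage.sobel(sm, axis=1, mode="nearest")
        feats.append(sm)
        feats.append(np.hypot(gx, gy))
    return np.stack(feats, axis=-1)


def train_classifier(img: RasterImage, scribbles: np.ndarray,
                     scales: tuple[float, ...] = (1.0, 2.0, 4.0),
                     seed: int = 0,
                     n_estimators: int = 100) -> PixelClassifier:
    """Train from a scribble raster (0 = unlabeled, 1 = wall, 2 = interior).

    Requires at least one labeled pixel of each class; training is
    deterministic under a fixed seed.
    """
    scribbles = np.asarray(scribbles)
    if scribbles.shape != img.shape:
        raise ValueError("scribble raster shape must match the image")
    wall_sel = scribbles == WALL_CLASS
    int_sel = scribbles == INTERIOR_CLASS
    if not wall_sel.any() or not int_sel.any():
        raise ValueError("insufficient training data: need >= 1 pixel per class")
    X = _feature_stack(img.pixels.astype(np.float64), tuple(scales))
    sel = wall_sel | int_sel
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                   n_jobs=1)
    model.fit(X[sel], scribbles[sel])
    return PixelClassifier(scales=tuple(scales), model=model,
                           n_train=int(sel.sum()), seed=seed)


def classify(img: RasterImage, clf: PixelClassifier) -> np.ndarray:
    """Per-pixel wall mask from a trained classifier; ties go to wall."""
    X = clf.features(img)
    h, w, f = X.shape
    proba = clf.model.predict_proba(X.reshape(-1, f))
    wall_col = list(clf.model.classes_).index(WALL_CLASS)
    return (proba[:, wall_col] >= 0.5).reshape(h, w)


def segment(img: RasterImage, p: ThresholdParams,
            classifier: PixelClassifier | None = None) -> np.ndarray:
    """One-call segmentation: threshold (or classify), clean, EDM-thin."""
    mask = classify(img, classifier) if classifier else band_threshold(img, p)
    mask = clean_mask(mask, p)
    if p.thin_keep_min > 0:
        mask = thin_walls(mask, edm(mask), p)
    return mask
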