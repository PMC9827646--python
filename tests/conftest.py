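"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive the filtered/distance/partition quantities by
direct enumeration so the vectorized implementations are checked against a
path they do not share.
"""

from __future__ import annotations

import numpy as np
import pytest

from cellwallfem.raster import RasterImage
from cellwallfem.synthfix import (HoneycombSpec, RenderSpec, honeycomb_graph,
                                  render_image)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_median3(arr: np.ndarray) -> np.ndarray:
    """3×3 median with edge replication, by direct neighbourhood collection."""
    h, w = arr.shape
    out = np.empty_like(arr, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            vals = [arr[min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)]
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
            out[r, c] = np.median(vals)
    return out


def brute_convolve3(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3×3 correlation with edge replication by direct summation."""
    h, w = arr.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    acc += arr[rr, cc] * kernel[dr + 1, dc + 1]
            out[r, c] = acc
    return out


def brute_edm(mask: np.ndarray) -> np.ndarray:
    """Exact EDM by all-pairs nearest-background search."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=np.float64)
    for r, c in np.argwhere(mask):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min())
    return out


def brute_voronoi(labels: np.ndarray) -> np.ndarray:
    """Nearest-particle-pixel partition, ties to the smaller label."""
    particles = [(int(k), np.argwhere(labels == k))
                 for k in np.unique(labels) if k > 0]
    out = np.zeros_like(labels)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            best_d2, best_k = None, 0
            for k, pix in particles:
                d2 = int(((pix[:, 0] - r) ** 2 + (pix[:, 1] - c) ** 2).min())
                if best_d2 is None or d2 < best_d2 or (d2 == best_d2 and k < best_k):
                    best_d2, best_k = d2, k
            out[r, c] = best_k
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def hex12():
    """3×4 regular honeycomb (l = 60 μm, t = 4.3 μm) with ground truth."""
    spec = HoneycombSpec(rows=3, cols=4, edge_len=60.0, wall_thickness=4.3)
    g, truth = honeycomb_graph(spec)
    return spec, g, truth


@pytest.fixture(scope="session")
def hex12_image(hex12):
    """Noise-free rendering of the 3×4 honeycomb."""
    _, g, truth = hex12
    img, gt = render_image(g, RenderSpec())
    return img, gt, truth


@pytest.fixture(scope="session")
def hex36():
    """6×6 honeycomb fixture used for the stiffness studies."""
    spec = HoneycombSpec(rows=6, cols=6, edge_len=60.0, wall_thickness=4.3)
    g, truth = honeycomb_graph(spec)
    return spec, g, truth


def rand_image(seed: int, shape=(8, 8), hi=255) -> RasterImage:
    rng = np.random.default_rng(seed)
    return RasterImage(rng.integers(0, hi + 1, size=shape).astype(np.float64))
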