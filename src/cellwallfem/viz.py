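"""Small shared colour utilities for rank/stress rendering."""

from __future__ import annotations

import numpy as np

# blue → cyan → green → yellow → red, endpoints pure blue / pure red
_ANCHORS = np.array([
    [0, 0, 255],
    [0, 255, 255],
    [0, 255, 0],
    [255, 255, 0],
    [255, 0, 0],
], dtype=np.float64)


def blue_red(values01: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] to RGB uint8 along a blue-to-red palette."""
    v = np.clip(np.asarray(values01, dtype=np.float64), 0.0, 1.0)
    pos = v * (len(_ANCHORS) - 1)
    i = np.minimum(pos.astype(int), len(_ANCHORS) - 2)
    frac = (pos - i)[..., None]
    rgb = _ANCHORS[i] * (1 - frac) + _ANCHORS[i + 1] * frac
    return np.round(rgb).astype(np.uint8)
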