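"""Cell morphometrics: counting, area quantification, normalized size
histograms and rank-colored size rendering."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .tessellate import LabelMap
from .viz import blue_red


@dataclass
class CellRecord:
    label: int
    area_px: int
    area_um2: float
    centroid: tuple[float, float]   # (x, y) in pixels
    border_touching: bool


@dataclass
class Histogram:
    bin_edges: np.ndarray
    frequencies: np.ndarray


def count_cells(partition: LabelMap) -> int:
    """Number of distinct nonzero labels in the partition."""
    vals = np.unique(partition.labels)
    return int((vals > 0).sum())


def cell_areas(partition: LabelMap, scale: float) -> list[CellRecord]:
    """Per-cell pixel and μm² areas with centroids; area_um2 = area_px·scale²."""
    if scale <= 0:
        raise ValueError("invalid calibration: scale must be > 0")
    lab = partition.labels
    labels = [int(v) for v in np.unique(lab) if v > 0]
    if not labels:
        return []
    counts = ndimage.sum_labels(np.ones_like(lab), lab, labels)
    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, labels)
    return [
        CellRecord(label=k, area_px=int(n), area_um2=float(n) * scale**2,
                   centroid=(float(c), float(r)),
                   border_touching=k in partition.border_touching)
        for k, n, (r, c) in zip(labels, counts, centroids)
    ]


def size_histogram(records: list[CellRecord], n_bins: int = 10,
                   unit: str = "um2") -> Histogram:
    """Equal-width histogram of cell areas, normalized to total cell count."""
    if not records:
        raise ValueError("nothing to histogram: no cell records")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    areas = np.array([r.area_um2 if unit == "um2" else r.area_px
                      for r in records], dtype=np.float64)
    counts, edges = np.histogram(areas, bins=n_bins)
    return Histogram(edges, counts / counts.sum())


def color_by_size(partition: LabelMap, records: list[CellRecord]) -> np.ndarray:
    """RGB rendering with cells colored blue (smallest) to red (largest).

    Colors follow the dense rank of the area, so ties share a color and a
    single outlier giant cell cannot wash out the palette; walls (label 0)
    are black.
    """
    lab = partition.labels
    by_label = {r.label: r.area_um2 for r in records}
    missing = (set(np.unique(lab)) - {0}) - set(by_label)
    if missing:
        raise ValueError(f"records missing for labels {sorted(missing)}")
    labels = sorted(by_label)
    areas = np.array([by_label[k] for k in labels])
    uniq = np.unique(areas)
    rank = np.searchsorted(uniq, areas)           # dense rank, ties share
    norm = rank / (len(uniq) - 1) if len(uniq) > 1 else np.zeros_like(rank, float)
    lut = np.zeros((int(lab.max()) + 1, 3), dtype=np.uint8)
    lut[labels] = blue_red(norm)
    return lut[lab]


def write_reports(partition: LabelMap, scale: float, out_dir: str | Path,
                  n_bins: int = 10) -> pd.DataFrame:
    """Write cells.csv and histogram.csv; returns the cell table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = cell_areas(partition, scale)
    df = pd.DataFrame([{
        "label": r.label, "area_px": r.area_px, "area_um2": r.area_um2,
        "centroid_x": r.centroid[0], "centroid_y": r.centroid[1],
        "border_touching": r.border_touching,
    } for r in records])
    df.to_csv(out / "cells.csv", index=False)
    h = size_histogram(records, n_bins=n_bins)
    pd.DataFrame({
        "bin_left_um2": h.bin_edges[:-1], "bin_right_um2": h.bin_edges[1:],
        "frequency": h.frequencies,
    }).to_csv(out / "histogram.csv", index=False)
    return df
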