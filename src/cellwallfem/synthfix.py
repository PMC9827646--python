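"""Synthetic honeycomb fixtures and analytic oracles.

No micrographs accompany the method, so validation runs on parametric
honeycomb tissue: a regular hexagon tiling with known edge length, wall
thickness and cell count, optionally jittered into irregular tissue-like
variants, and rendered into synthetic micrographs (bright cell interiors,
dark walls, Gaussian noise plus salt-and-pepper speckle) with exact
ground-truth cell labels.  The in-plane effective modulus of the regular
honeycomb has the Gibson–Ashby closed form, which serves as an independent
check on the beam-network solver.

Default fixture geometry: edge length l = 60 μm with wall thickness
t = 4.3 μm, placing t/l in the regime of parenchyma micrographs at 100×.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .fem import Material, apply_bcs, graph_to_mesh, solve, structural_stiffness
from .raster import RasterImage
from .tessellate import LabelMap, Wall, WallGraph, interior_labels


@dataclass
class HoneycombSpec:
    """Regular (optionally jittered) hexagon tiling: rows × cols cells of
    edge length ``edge_len`` μm, every wall ``wall_thickness`` μm thick."""

    rows: int = 6
    cols: int = 6
    edge_len: float = 60.0
    wall_thickness: float = 4.3
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 0 <= self.jitter < 0.3:
            raise ValueError("jitter must lie in [0, 0.3)")
        if self.edge_len <= 0:
            raise ValueError("edge_len must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def cell_area(self) -> float:
        """Analytic area of one regular hexagonal cell, 3√3·l²/2."""
        return 3.0 * np.sqrt(3.0) * self.edge_len**2 / 2.0


@dataclass
class RenderSpec:
    """Rasterization and noise model for synthetic micrographs."""

    px_per_um: float = 0.7
    wall_px: int = 3
    interior_intensity: float = 200.0
    wall_intensity: float = 60.0
    noise_sigma: float = 0.0
    speckle_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.interior_intensity, self.wall_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.interior_intensity <= self.wall_intensity:
            raise ValueError("interiors must be brighter than walls")


def honeycomb_graph(spec: HoneycombSpec) -> tuple[WallGraph, dict]:
    """Build the wall graph of a rows×cols regular-hexagon tiling.

    Pointy-top hexagons (vertical left/right edges) of circumradius
    ``edge_len``; odd rows offset by half a horizontal pitch.  Vertices
    shared between adjacent cells are merged exactly; ``jitter`` displaces
    each merged vertex by a seeded uniform offset of up to jitter·l per
    axis.  Returns the graph (scale 1 μm/unit) and a ground-truth dict with
    the cell count, cell centers and analytic cell area.
    """
    l = spec.edge_len
    dx, dy = np.sqrt(3.0) * l, 1.5 * l
    angles = np.deg2rad([90, 150, 210, 270, 330, 30])
    vert_ids: dict[tuple[int, int], int] = {}
    verts: list[tuple[float, float]] = []
    edges: set[tuple[int, int]] = set()
    centers = []

    def vid(x: float, y: float) -> int:
        key = (round(x * 1e6), round(y * 1e6))
        if key not in vert_ids:
            vert_ids[key] = len(verts)
            verts.append((x, y))
        return vert_ids[key]

    for r in range(spec.rows):
        for c in range(spec.cols):
            cx = c * dx + (dx / 2.0 if r % 2 else 0.0)
            cy = r * dy
            centers.append((cx, cy))
            ids = [vid(cx + l * np.cos(a), cy + l * np.sin(a)) for a in angles]
            for a, b in zip(ids, ids[1:] + ids[:1]):
                edges.add((min(a, b), max(a, b)))

    vxy = np.asarray(verts, dtype=float)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        vxy = vxy + rng.uniform(-spec.jitter * l, spec.jitter * l, size=vxy.shape)
    walls = [Wall(a, b, np.array([vxy[a], vxy[b]]), spec.wall_thickness)
             for a, b in sorted(edges)]
    g = WallGraph(vxy, walls, scale=1.0)
    truth = {
        "n_cells": spec.n_cells,
        "n_vertices": len(verts),
        "n_walls": len(walls),
        "cell_centers": centers,
        "cell_area_um2": spec.cell_area,
    }
    return g, truth


def render_image(g: WallGraph, rspec: RenderSpec) -> tuple[RasterImage, LabelMap]:
    """Rasterize a wall graph into a synthetic micrograph plus ground truth.

    Walls are drawn ``wall_px`` wide at ``wall_intensity`` over a uniform
    ``interior_intensity`` field; Gaussian noise then speckle are applied
    with the given seed.  Ground-truth labels are the 4-connected non-wall
    regions of the clean rendering (the surrounding exterior is the
    border-touching label).
    """
    scale = g.scale if g.scale is not None else 1.0
    pts = np.asarray(g.vertices, dtype=float) * scale
    margin = (rspec.wall_px + 4) / rspec.px_per_um
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    w = int(np.ceil((x1 - x0) * rspec.px_per_um)) + 1
    h = int(np.ceil((y1 - y0) * rspec.px_per_um)) + 1

    center = np.zeros((h, w), dtype=bool)
    for wall in g.walls:
        p = (np.asarray(wall.points, dtype=float) * scale - (x0, y0)) * rspec.px_per_um
        for (xa, ya), (xb, yb) in zip(p[:-1], p[1:]):
            rr, cc = draw_line(int(round(ya)), int(round(xa)),
                               int(round(yb)), int(round(xb)))
            center[np.clip(rr, 0, h - 1), np.clip(cc, 0, w - 1)] = True
    radius = (rspec.wall_px - 1) // 2
    wall_mask = (ndimage.binary_dilation(center, structure=disk(radius))
                 if radius > 0 else center)

    img = np.full((h, w), rspec.interior_intensity, dtype=np.float64)
    img[wall_mask] = rspec.wall_intensity
    truth = interior_labels(wall_mask)

    rng = np.random.default_rng(rspec.seed)
    if rspec.noise_sigma > 0:
        img = img + rng.normal(0.0, rspec.noise_sigma, size=img.shape)
    if rspec.speckle_fraction > 0:
        n = int(round(rspec.speckle_fraction * img.size))
        idx = rng.choice(img.size, size=n, replace=False)
        img.ravel()[idx] = rng.integers(0, 256, size=n)
    img = np.clip(np.round(img), 0, 255)
    return RasterImage(img, bit_depth=8, scale=1.0 / rspec.px_per_um), truth


def gibson_ashby_modulus(E_s: float, t: float, l: float) -> float:
    """In-plane effective modulus of a regular hexagonal honeycomb.

    E* = E_s·(t/l)³·cosθ/((h/l + sinθ)·sin²θ) with θ = 30°, h = l,
    which reduces to (4/√3)·E_s·(t/l)³.  Valid for thin walls (t << l).
    """
    if t >= l:
        raise ValueError("thick-wall regime: oracle requires t < l")
    return (4.0 / np.sqrt(3.0)) * E_s * (t / l) ** 3


def homogenized_modulus_x(g: WallGraph, mat: Material | None = None,
                          thickness: float | None = None,
                          seed_size: float = 1.0) -> float:
    """Effective x-direction modulus of a honeycomb specimen by FE.

    Runs the right-stretch tension test and converts the structural
    stiffness to a modulus via E* = K·W/(H·depth) with W, H the specimen's
    x and y extents.  Used to cross-check the solver against the
    Gibson–Ashby closed form.
    """
    mat = mat or Material()
    kwargs = {} if thickness is None else {"thickness": thickness}
    mesh = graph_to_mesh(g, seed_size=seed_size, **kwargs)
    bcs = apply_bcs(mesh, "right_stretch", stretch=1.0)
    K = structural_stiffness(solve(mesh, mat, bcs), bcs)
    W = mesh.nodes[:, 0].max() - mesh.nodes[:, 0].min()
    H = mesh.nodes[:, 1].max() - mesh.nodes[:, 1].min()
    depth = mesh.sections[0].depth
    return K * W / (H * depth)
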