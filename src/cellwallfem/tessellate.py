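"""Voronoi-based wall digitization.

From a thinned wall mask the tissue is decomposed into labeled cell
interiors; the plane is then partitioned by nearest-interior (Voronoi)
assignment, the inter-region boundary is reduced to a one-pixel-wide
skeleton, and the skeleton is vectorized into a planar *wall graph* of
junction vertices connected by polyline walls.  Short dangling spurs — the
triangular artifacts a Voronoi partition sheds at concave junctions — are
pruned iteratively.

Coordinates in a :class:`WallGraph` are (x, y) pairs in the source grid's
units, with ``scale`` holding micrometres per unit; the FE stage multiplies
through by ``scale`` to obtain calibrated geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import approximate_polygon

_N8 = np.ones((3, 3), dtype=int)


@dataclass
class LabelMap:
    """Integer region raster: 0 = wall/boundary, k >= 1 identifies a cell."""

    labels: np.ndarray
    border_touching: frozenset[int] = frozenset()

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def interior_labels_set(self) -> frozenset[int]:
        """Labels that do not touch the image edge."""
        present = set(np.unique(self.labels)) - {0}
        return frozenset(present - set(self.border_touching))


@dataclass
class SeedPoints:
    """Ultimate eroded points: per-cell EDM maxima, as (row, col, label)."""

    points: list[tuple[int, int, int]]


@dataclass
class Wall:
    """A polyline wall between two graph vertices.

    ``points`` is an (n, 2) array of (x, y) coordinates including both
    endpoints; ``thickness`` (μm) is optional and may be set per wall.
    """

    v1: int
    v2: int
    points: np.ndarray
    thickness: float | None = None

    def length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class WallGraph:
    """Junction vertices plus polyline walls; ``scale`` is μm per unit."""

    vertices: np.ndarray          # (V, 2) x, y
    walls: list[Wall]
    scale: float | None = None

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.vertices), dtype=int)
        for w in self.walls:
            deg[w.v1] += 1
            deg[w.v2] += 1
        return deg

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "scale_um_per_unit": self.scale,
            "vertices": np.asarray(self.vertices, dtype=float).tolist(),
            "walls": [
                {"v1": int(w.v1), "v2": int(w.v2),
                 "points": np.asarray(w.points, dtype=float).tolist(),
                 "thickness_um": w.thickness}
                for w in self.walls
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WallGraph":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        walls = [Wall(w["v1"], w["v2"], np.asarray(w["points"], dtype=float),
                      w.get("thickness_um"))
                 for w in obj["walls"]]
        return cls(np.asarray(obj["vertices"], dtype=float), walls,
                   obj.get("scale_um_per_unit"))


# ---------------------------------------------------------------------------
# Interiors, seeds, Voronoi
# ---------------------------------------------------------------------------

def interior_labels(thin_mask: np.ndarray) -> LabelMap:
    """Label 4-connected non-wall regions 1..N in raster-scan order.

    Regions touching the image edge are flagged; with a surrounding
    background, the flagged set is the non-cell exterior plus partially
    imaged border cells.
    """
    bg = ~np.asarray(thin_mask, dtype=bool)
    lab, n = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    if n == 0:
        raise ValueError("empty segmentation: no interior regions")
    # relabel by first pixel in raster order
    flat = lab.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # np.minimum.at over first occurrence
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[1 + order] = np.arange(1, n + 1)
    lab = remap[lab]
    border = set(np.unique(np.concatenate([
        lab[0], lab[-1], lab[:, 0], lab[:, -1]]))) - {0}
    return LabelMap(lab, frozenset(int(b) for b in border))


def ueps(interiors: LabelMap, mask: np.ndarray) -> SeedPoints:
    """Ultimate eroded points: regional EDM maxima of each cell interior.

    A connected plateau of equal maxima collapses to one point at its
    centroid, rounded to the nearest pixel inside the plateau.
    """
    lab = interiors.labels
    pts: list[tuple[int, int, int]] = []
    objects = ndimage.find_objects(lab)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        r0, c0 = sl[0].start, sl[1].start
        region = np.pad(lab[sl] == k, 1)
        d = ndimage.distance_transform_edt(region)
        maxima = morphology.local_maxima(d, connectivity=2) & region
        mlab, nm = ndimage.label(maxima, structure=_N8)
        for m in range(1, nm + 1):
            rows, cols = np.nonzero(mlab == m)
            cr, cc = rows.mean(), cols.mean()
            i = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
            pts.append((int(rows[i]) - 1 + r0, int(cols[i]) - 1 + c0, k))
    return SeedPoints(pts)


def voronoi_partition(interiors: LabelMap, shape: tuple[int, int] | None = None
                      ) -> LabelMap:
    """Assign every pixel to the label of its nearest interior pixel.

    Distance is Euclidean between pixel centres; ties go to the smaller
    label.  The per-label sweep uses integer squared distances, so the tie
    rule is exact.
    """
    lab = interiors.labels
    shape = shape or lab.shape
    labels_present = [int(v) for v in np.unique(lab) if v > 0]
    if not labels_present:
        raise ValueError("no labeled particles to partition from")
    rows, cols = np.indices(shape)
    best_d2 = np.full(shape, np.iinfo(np.int64).max, dtype=np.int64)
    out = np.zeros(shape, dtype=lab.dtype)
    for k in labels_present:  # increasing order: first (smaller) label wins ties
        ind = ndimage.distance_transform_edt(lab != k, return_distances=False,
                                             return_indices=True)
        d2 = (rows - ind[0]).astype(np.int64) ** 2 + (cols - ind[1]).astype(np.int64) ** 2
        take = d2 < best_d2
        best_d2[take] = d2[take]
        out[take] = k
    return LabelMap(out, interiors.border_touching)


def boundary_skeleton(partition: LabelMap) -> np.ndarray:
    """One-pixel-wide boundary network of a full partition.

    A pixel is boundary when its 8-neighbourhood contains a larger label
    (drawing each interface on the smaller-label side), then morphological
    thinning enforces unit width.
    """
    lab = partition.labels
    bigger = ndimage.maximum_filter(lab, footprint=_N8)
    boundary = bigger > lab
    return morphology.thin(boundary)


# ---------------------------------------------------------------------------
# Wall-graph extraction
# ---------------------------------------------------------------------------

def _neighbor_count(sk: np.ndarray) -> np.ndarray:
    kernel = _N8.copy()
    kernel[1, 1] = 0
    return ndimage.correlate(sk.astype(np.int8), kernel, mode="constant")


def _component_neighbors(pix_set: set[tuple[int, int]], p: tuple[int, int]):
    r, c = p
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pix_set:
                yield q


def _order_path(pixels: list[tuple[int, int]]) -> tuple[list[tuple[int, int]], bool]:
    """Order an arc/cycle component's pixels by walking; returns (order, is_cycle)."""
    pix_set = set(pixels)
    ends = sorted(p for p in pixels
                  if sum(1 for _ in _component_neighbors(pix_set, p)) <= 1)
    is_cycle = not ends
    start = ends[0] if ends else min(pixels)
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in _component_neighbors(pix_set, cur) if q not in seen]
        if not nxt:
            break
        # prefer 4-adjacent steps for a tight walk
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        order.append(cur)
        seen.add(cur)
    return order, is_cycle


def wall_graph(skeleton: np.ndarray, scale: float | None = None,
               simplify_tol: float = 0.75) -> WallGraph:
    """Vectorize a unit-width skeleton into junction vertices and walls.

    Junction pixels (>= 3 skeleton neighbours) merge into one vertex per
    8-connected cluster at the cluster centroid; free path ends become
    vertices; maximal paths between vertices become polyline walls
    simplified by Douglas–Peucker at ``simplify_tol`` pixels.  Closed loops
    without junctions become a single wall with a coincident end vertex.
    """
    sk = np.asarray(skeleton, dtype=bool)
    # unit-width check: no 2x2 block fully set
    if (sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]).any():
        raise ValueError("skeleton is not unit-width (thinning failure)")
    nb = _neighbor_count(sk)
    junction = sk & (nb >= 3)
    jlab, nj = ndimage.label(junction, structure=_N8)
    verts: list[tuple[float, float]] = []
    for j in range(1, nj + 1):
        rows, cols = np.nonzero(jlab == j)
        verts.append((cols.mean(), rows.mean()))  # (x, y)

    def new_vertex(xy: tuple[float, float]) -> int:
        verts.append(xy)
        return len(verts) - 1

    def adjacent_clusters(p: tuple[int, int]) -> list[int]:
        r, c = p
        out: list[int] = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < sk.shape[0] and 0 <= cc < sk.shape[1]:
                    j = jlab[rr, cc]
                    if j > 0 and j - 1 not in out:
                        out.append(j - 1)
        return out

    walls: list[Wall] = []

    def add_wall(v1: int, v2: int, pts: np.ndarray) -> None:
        # drop consecutive duplicates, simplify, reject zero length
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            return
        pts = approximate_polygon(pts, tolerance=simplify_tol)
        w = Wall(v1, v2, pts)
        if w.length() <= 0:
            return
        walls.append(w)

    path_px = sk & ~junction
    plab, nP = ndimage.label(path_px, structure=_N8)
    comp_pixels: list[list[tuple[int, int]]] = [[] for _ in range(nP)]
    for r, c in zip(*np.nonzero(plab)):
        comp_pixels[plab[r, c] - 1].append((int(r), int(c)))

    for pixels in comp_pixels:
        order, is_cycle = _order_path(pixels)
        coords = np.array([(c, r) for r, c in order], dtype=float)
        if is_cycle:
            v = new_vertex(tuple(coords[0]))
            add_wall(v, v, np.vstack([coords, coords[:1]]))
            continue
        first, last = order[0], order[-1]
        cl_first = adjacent_clusters(first)
        cl_last = adjacent_clusters(last)
        if len(order) == 1 and len(cl_first) >= 2:
            # lone pixel bridging two junction clusters
            v1, v2 = cl_first[0], cl_first[1]
        else:
            if len(order) > 1:
                cl_last = [j for j in cl_last if j not in cl_first] or cl_last
            v1 = cl_first[0] if cl_first else new_vertex(tuple(coords[0]))
            v2 = cl_last[0] if cl_last else new_vertex(tuple(coords[-1]))
        pts = np.vstack([[verts[v1]], coords, [verts[v2]]])
        add_wall(v1, v2, pts)

    # walls between directly adjacent junction clusters (no path pixels between)
    seen_pairs = set()
    for r, c in zip(*np.nonzero(junction)):
        j1 = jlab[r, c] - 1
        for j2 in adjacent_clusters((int(r), int(c))):
            if j2 != j1:
                pair = (min(j1, j2), max(j1, j2))
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    add_wall(pair[0], pair[1],
                             np.array([verts[pair[0]], verts[pair[1]]]))

    return WallGraph(np.asarray(verts, dtype=float), walls, scale)


def prune_spurs(g: WallGraph, max_len: float = 5.0) -> WallGraph:
    """Iteratively delete dangling walls shorter than ``max_len`` μm.

    A spur is a wall with a degree-1 endpoint and physical length
    (polyline length × scale) below ``max_len``.  Degree-2 vertices created
    by a deletion are dissolved by merging their two walls, so spur chains
    collapse over successive sweeps.  Terminates in at most E sweeps and is
    idempotent.
    """
    scale = g.scale if g.scale is not None else 1.0
    verts = np.asarray(g.vertices, dtype=float)
    walls = [Wall(w.v1, w.v2, np.asarray(w.points, dtype=float).copy(), w.thickness)
             for w in g.walls]

    def degrees() -> dict[int, int]:
        deg: dict[int, int] = {}
        for w in walls:
            deg[w.v1] = deg.get(w.v1, 0) + 1
            deg[w.v2] = deg.get(w.v2, 0) + 1
        return deg

    for _ in range(len(walls) + 1):
        deg = degrees()
        spurs = [w for w in walls
                 if w.v1 != w.v2
                 and (deg.get(w.v1, 0) == 1 or deg.get(w.v2, 0) == 1)
                 and w.length() * scale < max_len]
        if not spurs:
            break
        touched: set[int] = set()
        for w in spurs:
            walls.remove(w)
            touched.update((w.v1, w.v2))
        # dissolve degree-2 vertices created by the deletions
        deg = degrees()
        for v in sorted(touched):
            if deg.get(v, 0) != 2:
                continue
            pair = [w for w in walls if v in (w.v1, w.v2)]
            if len(pair) != 2 or pair[0] is pair[1]:
                continue
            a, b = pair
            pa = a.points if a.v2 == v else a.points[::-1]
            pb = b.points if b.v1 == v else b.points[::-1]
            va = a.v1 if a.v2 == v else a.v2
            vb = b.v2 if b.v1 == v else b.v1
            la, lb = a.length(), b.length()
            if a.thickness is not None and b.thickness is not None:
                t = (a.thickness * la + b.thickness * lb) / (la + lb)
            else:
                t = a.thickness if a.thickness is not None else b.thickness
            walls.remove(a)
            walls.remove(b)
            walls.append(Wall(va, vb, np.vstack([pa, pb[1:]]), t))
            deg = degrees()

    # compact vertex ids
    used = sorted({w.v1 for w in walls} | {w.v2 for w in walls})
    remap = {old: new for new, old in enumerate(used)}
    new_walls = [Wall(remap[w.v1], remap[w.v2], w.points, w.thickness)
                 for w in walls]
    new_verts = verts[used] if used else np.empty((0, 2))
    return WallGraph(new_verts, new_walls, g.scale)
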