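"""Beam-network finite element model of the cell-wall geometry.

Each wall polyline is meshed with 2-node, shear-flexible (Timoshenko) beam
elements — the 2-D analogue of the B21 element — at a target seed size of
1 μm.  Walls carry a rectangular cross-section of thickness ``t`` and unit
out-of-plane depth (the plane-stress idealization), so A = t·d and
I = d·t³/12 with shear factor κ = 5/6.  Nodes have three degrees of
freedom (u_x, u_y, θ).  Tissue stiffness is the total reaction force on
the displacement-driven boundary divided by the prescribed stretch, and
per-element von Mises stress combines axial-plus-bending fiber stress with
transverse shear.

Units: lengths in μm, the elastic modulus in force/μm², hence forces in the
same force unit; all reported stiffnesses are per unit out-of-plane depth.
The normalized sensitivities downstream are dimensionless and independent
of this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from skimage.draw import line as draw_line

from .raster import RasterImage
from .tessellate import WallGraph
from .viz import blue_red

KAPPA = 5.0 / 6.0  # shear correction factor, rectangular section


@dataclass(frozen=True)
class Material:
    """Linear-elastic isotropic wall material (E in force/μm²)."""

    E: float = 1.0
    nu: float = 0.3

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (-1, 0.5)")

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass(frozen=True)
class Section:
    """Rectangular beam section: wall thickness t and out-of-plane depth."""

    t: float
    depth: float = 1.0

    def __post_init__(self) -> None:
        if self.t <= 0 or self.depth <= 0:
            raise ValueError("section dimensions must be positive")

    @property
    def A(self) -> float:
        return self.t * self.depth

    @property
    def I(self) -> float:
        return self.depth * self.t**3 / 12.0

    @property
    def A_s(self) -> float:
        return KAPPA * self.A


def section_properties(t: float, depth: float = 1.0) -> tuple[float, float, float]:
    """(A, I, A_s) of a rectangular wall section."""
    s = Section(t, depth)
    return s.A, s.I, s.A_s


@dataclass
class FEMesh:
    """Nodes (μm), 2-node beam elements, and per-wall sections."""

    nodes: np.ndarray           # (N, 2) x, y in μm
    elements: np.ndarray        # (E, 2) node indices
    element_wall: np.ndarray    # (E,) wall index per element
    sections: list[Section]     # indexed by wall
    seed_size: float = 1.0

    @property
    def n_dof(self) -> int:
        return 3 * len(self.nodes)

    def element_lengths(self) -> np.ndarray:
        d = self.nodes[self.elements[:, 1]] - self.nodes[self.elements[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def with_sections(self, sections: list[Section]) -> "FEMesh":
        return replace(self, sections=sections)


def graph_to_mesh(g: WallGraph, seed_size: float = 1.0,
                  thickness: float = 4.3, depth: float = 1.0) -> FEMesh:
    """Mesh a wall graph with ~``seed_size`` μm beam elements.

    Each wall is split into ``ceil(length/seed_size)`` equal-arclength
    elements along its polyline; junction vertices become nodes shared by
    every incident wall.  Walls without an explicit thickness use the
    ``thickness`` default (the 4.3 μm literature average for maize).
    """
    if g.scale is None:
        raise ValueError("uncalibrated geometry: wall graph has no μm scale")
    if seed_size <= 0:
        raise ValueError("seed_size must be positive")
    scale = g.scale
    verts_um = np.asarray(g.vertices, dtype=float) * scale

    nodes: list[tuple[float, float]] = [tuple(v) for v in verts_um]
    elements: list[tuple[int, int]] = []
    element_wall: list[int] = []
    sections: list[Section] = []

    for wid, w in enumerate(g.walls):
        pts = np.asarray(w.points, dtype=float) * scale
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        L = seglen.sum()
        if L <= 0:
            raise ValueError(f"zero-length wall {wid}")
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        n = max(1, int(np.ceil(L / seed_size)))
        si = np.linspace(0.0, L, n + 1)
        xs = np.interp(si, s, pts[:, 0])
        ys = np.interp(si, s, pts[:, 1])
        ids = [w.v1]
        for i in range(1, n):
            nodes.append((float(xs[i]), float(ys[i])))
            ids.append(len(nodes) - 1)
        ids.append(w.v2)
        for a, b in zip(ids[:-1], ids[1:]):
            elements.append((a, b))
            element_wall.append(wid)
        sections.append(Section(w.thickness if w.thickness is not None else thickness,
                                depth))

    mesh = FEMesh(np.asarray(nodes, dtype=float),
                  np.asarray(elements, dtype=np.int64),
                  np.asarray(element_wall, dtype=np.int64),
                  sections, seed_size)
    if (mesh.element_lengths() <= 0).any():
        raise ValueError("meshing produced a zero-length element")
    return mesh


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------

UX, UY, ROT = 0, 1, 2


@dataclass
class BCSpec:
    """Boundary conditions: fixed (zero) and prescribed (driven) DOFs."""

    preset: str
    fixed: list[tuple[int, int]]                 # (node, dof)
    prescribed: list[tuple[int, int, float]]     # (node, dof, value μm)
    stretch: float = 1.0

    def __post_init__(self) -> None:
        fset = set(self.fixed)
        pset = {(n, d) for n, d, _ in self.prescribed}
        if fset & pset:
            raise ValueError("a DOF is both fixed and prescribed")
        if len(fset) + len(pset) < 3:
            raise ValueError("degenerate BCs: fewer than 3 constrained DOFs")


def apply_bcs(mesh: FEMesh, preset: str = "right_stretch",
              stretch: float = 1.0, band: float | None = None) -> BCSpec:
    """Build a boundary-condition preset from mesh extremes.

    ``right_stretch`` (the tension test of the sensitivity study): nodes
    within ``band`` of min-x are fixed in u_x, the lowest-leftmost of them
    also in u_y, and nodes within ``band`` of max-x are driven +``stretch``
    in x.  ``top_stretch``: bottom nodes fixed in u_y, left/right nodes
    fixed in u_x, top nodes driven +``stretch`` in y.  Rotations are never
    constrained.  ``band`` defaults to seed_size/2.
    """
    if len(mesh.nodes) < 2:
        raise ValueError("degenerate BCs: mesh too small to constrain")
    band = mesh.seed_size / 2.0 if band is None else band
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    fixed: list[tuple[int, int]] = []
    prescribed: list[tuple[int, int, float]] = []

    if preset == "right_stretch":
        left = np.flatnonzero(x <= x.min() + band)
        right = np.flatnonzero(x >= x.max() - band)
        fixed += [(int(n), UX) for n in left]
        anchor = left[np.lexsort((x[left], y[left]))[0]]
        fixed.append((int(anchor), UY))
        prescribed += [(int(n), UX, stretch) for n in right]
    elif preset == "top_stretch":
        bottom = np.flatnonzero(y <= y.min() + band)
        top = np.flatnonzero(y >= y.max() - band)
        sides = np.flatnonzero((x <= x.min() + band) | (x >= x.max() - band))
        fixed += [(int(n), UY) for n in bottom]
        fixed += [(int(n), UX) for n in sides]
        prescribed += [(int(n), UY, stretch) for n in top
                       if (int(n), UY) not in set(fixed)]
    else:
        raise ValueError(f"unknown BC preset {preset!r}")

    if not prescribed:
        raise ValueError("degenerate BCs: empty driven node set")
    return BCSpec(preset, fixed, prescribed, stretch)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    """Displacements, reactions and internal forces of a linear solve."""

    displacements: np.ndarray    # (N, 3)
    reactions: np.ndarray        # (3N,) zero at unconstrained DOFs
    end_forces: np.ndarray       # (E, 6) local (Fx1, Fy1, M1, Fx2, Fy2, M2)
    constrained_dofs: np.ndarray  # global DOF indices that carry reactions
    strain_energy: float = 0.0   # ½ uᵀKu, summed element-wise
    has_loads: bool = False      # True when external nodal loads were applied


def _local_stiffness(E: float, G: float, sec: Section, L: float) -> np.ndarray:
    A, I, A_s = sec.A, sec.I, sec.A_s
    phi = 12.0 * E * I / (G * A_s * L**2)
    a = E * A / L
    b = E * I / ((1.0 + phi) * L**3)
    k = np.zeros((6, 6))
    k[0, 0] = k[3, 3] = a
    k[0, 3] = k[3, 0] = -a
    k[1, 1] = k[4, 4] = 12 * b
    k[1, 4] = k[4, 1] = -12 * b
    k[1, 2] = k[2, 1] = k[1, 5] = k[5, 1] = 6 * b * L
    k[2, 4] = k[4, 2] = k[4, 5] = k[5, 4] = -6 * b * L
    k[2, 2] = k[5, 5] = (4 + phi) * b * L**2
    k[2, 5] = k[5, 2] = (2 - phi) * b * L**2
    return k


def _transform(c: float, s: float) -> np.ndarray:
    T = np.zeros((6, 6))
    R = np.array([[c, s, 0], [-s, c, 0], [0, 0, 1.0]])
    T[:3, :3] = R
    T[3:, 3:] = R
    return T


def solve(mesh: FEMesh, mat: Material, bcs: BCSpec,
          loads: list[tuple[int, int, float]] | None = None) -> SolveResult:
    """Assemble and solve the 2-D frame; returns displacements, reactions
    and per-element local end forces.

    Prescribed displacements are imposed by partitioning; optional nodal
    ``loads`` are (node, dof, force) triples.  A singular free block
    (under-constraint or a floating component) raises ``ValueError``.
    """
    n_dof = mesh.n_dof
    xy = mesh.nodes
    lengths = mesh.element_lengths()
    rows, cols, vals = [], [], []
    locals_: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for e, (i, j) in enumerate(mesh.elements):
        L = lengths[e]
        dx, dy = xy[j] - xy[i]
        c, s = dx / L, dy / L
        sec = mesh.sections[mesh.element_wall[e]]
        k_l = _local_stiffness(mat.E, mat.G, sec, L)
        T = _transform(c, s)
        k_g = T.T @ k_l @ T
        dofs = np.array([3 * i, 3 * i + 1, 3 * i + 2, 3 * j, 3 * j + 1, 3 * j + 2])
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(k_g.ravel())
        locals_.append((k_l, T, dofs))
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof)).tocsr()

    u = np.zeros(n_dof)
    cons = []
    for n, d in bcs.fixed:
        cons.append(3 * n + d)
    for n, d, v in bcs.prescribed:
        cons.append(3 * n + d)
        u[3 * n + d] = v
    cons = np.asarray(sorted(set(cons)), dtype=np.int64)
    free = np.setdiff1d(np.arange(n_dof), cons)

    f = np.zeros(n_dof)
    for n, d, v in loads or []:
        f[3 * n + d] += v

    K_ff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, cons] @ u[cons]
    try:
        with np.errstate(all="ignore"):
            lu = splu(K_ff)
            u_f = lu.solve(rhs)
            # one step of iterative refinement sharpens the reaction sums
            u_f += lu.solve(rhs - K_ff @ u_f)
    except RuntimeError as err:
        raise ValueError("singular system: structure under-constrained or "
                         "contains a floating component") from err
    if not np.all(np.isfinite(u_f)):
        raise ValueError("singular system: structure under-constrained or "
                         "contains a floating component")
    u[free] = u_f

    reactions = np.zeros(n_dof)
    reactions[cons] = (K @ u - f)[cons]

    end_forces = np.empty((len(mesh.elements), 6))
    energy = 0.0
    for e, (k_l, T, dofs) in enumerate(locals_):
        u_loc = T @ u[dofs]
        end_forces[e] = k_l @ u_loc
        energy += 0.5 * float(end_forces[e] @ u_loc)

    return SolveResult(u.reshape(-1, 3), reactions, end_forces, cons, energy,
                       has_loads=bool(loads))


def structural_stiffness(res: SolveResult, bcs: BCSpec) -> float:
    """K = (sum of driven-DOF reaction forces)/stretch, force per length.

    When every driven DOF carries the same prescribed value (the preset
    case, no applied loads) the reaction sum equals 2U/stretch by the work
    identity, which is evaluated element-wise and is free of the
    cancellation the raw reaction sum suffers; otherwise the reactions are
    summed directly.
    """
    values = {v for _, _, v in bcs.prescribed}
    if not res.has_loads and values == {bcs.stretch}:
        return float(2.0 * res.strain_energy / bcs.stretch**2)
    total = sum(res.reactions[3 * n + d] for n, d, _ in bcs.prescribed)
    return float(total / bcs.stretch)


def element_von_mises(res: SolveResult, mesh: FEMesh) -> np.ndarray:
    """Per-element von Mises stress.

    At each element end: σ_ax = N/A ± M·(t/2)/I at the two outer fibers,
    τ = V/A_s, σ_vm = sqrt(σ_ax² + 3τ²); the element value is the maximum
    over ends and fibers.
    """
    out = np.empty(len(mesh.elements))
    for e in range(len(mesh.elements)):
        sec = mesh.sections[mesh.element_wall[e]]
        f = res.end_forces[e]
        best = 0.0
        for N, V, M in ((-f[0], -f[1], f[2]), (f[3], f[4], f[5])):
            tau = V / sec.A_s
            for fiber in (1.0, -1.0):
                s_ax = N / sec.A + fiber * M * (sec.t / 2.0) / sec.I
                best = max(best, np.sqrt(s_ax**2 + 3.0 * tau**2))
        out[e] = best
    return out


def average_thickness(nominals: list[float]) -> float:
    """Arithmetic mean of nominal wall thicknesses (μm), to one decimal."""
    if not nominals:
        raise ValueError("empty thickness list")
    return round(float(np.mean(nominals)), 1)


def overlay_stress(img: RasterImage, mesh: FEMesh, stresses: np.ndarray,
                   scale: float) -> np.ndarray:
    """Draw elements over the micrograph, blue (min σ_vm) to red (max).

    ``scale`` is μm per pixel of the image; mesh coordinates are μm.  A
    degenerate stress range (min = max) renders all elements blue.
    """
    base = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    smin, smax = float(np.min(stresses)), float(np.max(stresses))
    norm = (np.zeros_like(stresses) if smax == smin
            else (stresses - smin) / (smax - smin))
    colors = blue_red(norm)
    h, w = base.shape
    px = mesh.nodes / scale  # μm → px; x = col, y = row
    for e, (i, j) in enumerate(mesh.elements):
        r0, c0 = int(round(px[i, 1])), int(round(px[i, 0]))
        r1, c1 = int(round(px[j, 1])), int(round(px[j, 0]))
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[keep], cc[keep]] = colors[e]
    return rgb
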