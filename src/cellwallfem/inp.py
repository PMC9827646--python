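"""Abaqus keyword-format (.inp) export of the beam model, plus a minimal
reader used for round-trip verification.

The writer emits *NODE, *ELEMENT (type B21) with one element set per
distinct wall section, *BEAM SECTION (RECT) blocks, an elastic material,
and a single static step carrying the boundary and prescribed-displacement
cards.  Output is byte-stable for identical inputs.  Abaqus DOF numbering
is used on *BOUNDARY cards: 1 = u_x, 2 = u_y, 6 = in-plane rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fem import BCSpec, FEMesh, Material, Section

_ABQ_DOF = {0: 1, 1: 2, 2: 6}


def export_inp(mesh: FEMesh, mat: Material, bcs: BCSpec,
               path: str | Path) -> None:
    """Write the complete model as an Abaqus keyword file."""
    lines: list[str] = ["*HEADING", "cellwallfem beam-network model"]
    lines.append("*NODE")
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.6f}, {y:.6f}")

    # group elements by section (thickness, depth)
    groups: dict[tuple[float, float], list[int]] = {}
    for e, wid in enumerate(mesh.element_wall):
        sec = mesh.sections[wid]
        groups.setdefault((sec.t, sec.depth), []).append(e)

    eid = 1
    elset_names = []
    for gi, ((t, depth), elems) in enumerate(sorted(groups.items())):
        name = f"WALLS_T{gi}"
        elset_names.append((name, t, depth))
        lines.append(f"*ELEMENT, TYPE=B21, ELSET={name}")
        for e in elems:
            i, j = mesh.elements[e]
            lines.append(f"{eid}, {i + 1}, {j + 1}")
            eid += 1

    for name, t, depth in elset_names:
        lines.append(f"*BEAM SECTION, ELSET={name}, MATERIAL=CELLWALL, SECTION=RECT")
        lines.append(f"{t:.6f}, {depth:.6f}")
        lines.append("0.0, 0.0, -1.0")  # beam normal (out of plane)

    lines.append("*MATERIAL, NAME=CELLWALL")
    lines.append("*ELASTIC")
    lines.append(f"{mat.E:.6g}, {mat.nu:.6g}")

    lines.append("*STEP")
    lines.append("*STATIC")
    lines.append("*BOUNDARY")
    for n, d in sorted(bcs.fixed):
        a = _ABQ_DOF[d]
        lines.append(f"{n + 1}, {a}, {a}")
    for n, d, v in sorted(bcs.prescribed):
        a = _ABQ_DOF[d]
        lines.append(f"{n + 1}, {a}, {a}, {v:.6f}")
    lines.append("*END STEP")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class InpModel:
    """Minimal parse of an exported model, for round-trip checks."""

    nodes: np.ndarray                       # (N, 2)
    elements: np.ndarray                    # (E, 2) 0-based
    element_section: list[tuple[float, float]]  # (t, depth) per element
    material: tuple[float, float]           # (E, nu)


def read_inp(path: str | Path) -> InpModel:
    nodes: dict[int, tuple[float, float]] = {}
    elements: list[tuple[int, int, str]] = []
    sections: dict[str, tuple[float, float]] = {}
    material = (0.0, 0.0)
    mode = None
    pending_section: str | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("*"):
            key = line.split(",")[0].upper()
            opts = dict(
                kv.split("=", 1) for kv in
                (p.strip() for p in line.split(",")[1:]) if "=" in kv)
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                mode = "element"
                current_elset = opts.get("ELSET", "")
            elif key == "*BEAM SECTION":
                mode = "section"
                pending_section = opts.get("ELSET", "")
            elif key == "*ELASTIC":
                mode = "elastic"
            else:
                mode = None
            continue
        parts = [p.strip() for p in line.split(",")]
        if mode == "node":
            nodes[int(parts[0])] = (float(parts[1]), float(parts[2]))
        elif mode == "element":
            elements.append((int(parts[1]) - 1, int(parts[2]) - 1, current_elset))
        elif mode == "section" and pending_section is not None:
            sections[pending_section] = (float(parts[0]), float(parts[1]))
            pending_section = None
        elif mode == "elastic":
            material = (float(parts[0]), float(parts[1]))
            mode = None
    order = sorted(nodes)
    idx = {nid: k for k, nid in enumerate(order)}
    node_arr = np.array([nodes[nid] for nid in order])
    elem_arr = np.array([(idx[i + 1], idx[j + 1]) for i, j, _ in elements],
                        dtype=np.int64)
    elem_sec = [sections[es] for _, _, es in elements]
    return InpModel(node_arr, elem_arr, elem_sec, material)
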