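"""Normalized sensitivity of tissue stiffness to wall parameters.

The parametric study perturbs one model parameter — the wall elastic
modulus or the wall thickness — by a uniform forward step (+5% by default)
across every wall, re-solves the frame, and reports the linear normalized
sensitivity

    S = ((K_pert − K_base)/K_base) / delta_frac,

i.e. the fractional stiffness change per fractional parameter change.
S = 1 means proportional response (always the case for the modulus of a
linear model); a bending-dominated cellular network approaches the cubic
thickness limit ((1+δ)³ − 1)/δ, ≈ 3.1525 at δ = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .fem import (BCSpec, FEMesh, Material, Section, solve,
                  structural_stiffness)

PARAMETERS = ("modulus", "thickness")


@dataclass
class SensitivityResult:
    parameter: str
    delta_frac: float
    K_base: float
    K_pert: float

    @property
    def S(self) -> float:
        return ((self.K_pert - self.K_base) / self.K_base) / self.delta_frac

    @property
    def percent_stiffness_change(self) -> float:
        return 100.0 * (self.K_pert - self.K_base) / self.K_base


def normalized_sensitivity(mesh: FEMesh, mat: Material, bcs: BCSpec,
                           parameter: str,
                           delta_frac: float = 0.05) -> SensitivityResult:
    """Forward-difference normalized sensitivity of structural stiffness.

    The chosen parameter is multiplied by (1 + delta_frac) uniformly across
    all walls, the model is re-solved, and S is formed; the baseline model
    is left unmodified.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    if delta_frac <= 0:
        raise ValueError("delta_frac must be positive")
    K_base = structural_stiffness(solve(mesh, mat, bcs), bcs)
    if parameter == "modulus":
        mat_p = replace(mat, E=mat.E * (1.0 + delta_frac))
        res_p = solve(mesh, mat_p, bcs)
    else:
        secs = [Section(s.t * (1.0 + delta_frac), s.depth) for s in mesh.sections]
        res_p = solve(mesh.with_sections(secs), mat, bcs)
    K_pert = structural_stiffness(res_p, bcs)
    return SensitivityResult(parameter, delta_frac, K_base, K_pert)
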