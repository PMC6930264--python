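"""Dimensionless free energy of a (shape, texture) state.

Energies are reported in units of the intrinsic nematic elastic constant
``k_i`` with lengths in units of ``R = sqrt(A/4pi)``.  The area density is

.. math::

    f = \\tfrac{1}{2}\\,\\frac{\\kappa}{k_i}\\, g_H
      + \\lambda_0^2\\Big[ (R/\\xi)^2 g_c + \\tfrac12 g_{int}
      + \\mu\\, g_{ext} \\Big],
      \\qquad \\mu = \\frac{k_e}{\\lambda_0 k_i},

with ``g_H = (C1+C2)^2`` the squared total curvature (the classic Helfrich
bending density with zero spontaneous curvature — the ``Tr C^2`` variant
differs from it only by the Gaussian curvature, whose integral is a
topological constant on closed genus-0 surfaces and cannot reorder shapes).

The nematic part is discretized on the staggered texture lattice with
nearest-neighbour (link) differences for the gradient term, so that the
Metropolis sampler's local energy changes and the total reported energy are
computed from one and the same lattice functional.  Azimuthal links carry
the spin-2 parallel-transport rotation ``2*delta``, ``delta = cos(theta)*dphi``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
import json

import numpy as np

from .geometry import ShapeParams, SurfaceGrid, build_profile, normalize_area
from .texture import NematicTexture, condensation_density


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless couplings and numerical settings of the hybrid model.

    Attributes
    ----------
    kappa_over_ki
        Bending modulus over intrinsic nematic constant, kappa/k_i.
    ke_over_ki
        Extrinsic (deviatoric) over intrinsic constant, k_e/k_i.
    lambda0
        Equilibrium order parameter lambda_0 in (0, 1/2].
    R_over_xi
        Vesicle radius over nematic correlation length (depth into the
        ordered phase); 7 for all reference runs.
    v
        Target reduced volume.
    n_modes, n_s, n_phi
        Fourier-mode count and grid resolution (101 x 101 reference grid).
    seed
        Base random seed recorded in every output.
    """

    kappa_over_ki: float = 1.0
    ke_over_ki: float = 0.0
    lambda0: float = 0.5
    R_over_xi: float = 7.0
    v: float = 0.6
    n_modes: int = 30
    n_s: int = 101
    n_phi: int = 101
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lambda0 <= 0.5):
            raise ValueError("lambda0 must lie in (0, 1/2]")
        if self.R_over_xi <= 0:
            raise ValueError("R_over_xi must be positive")
        if self.kappa_over_ki < 0 or self.ke_over_ki < 0:
            raise ValueError("elastic ratios must be non-negative")
        if not (0.0 < self.v <= 1.0):
            raise ValueError("reduced volume v must lie in (0, 1]")

    @property
    def mu(self) -> float:
        """Extrinsic-to-intrinsic weight mu = (k_e/k_i)/lambda0."""
        return self.ke_over_ki / self.lambda0

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class EnergyReport:
    """Free-energy components (units of k_i) and constraint residuals."""

    F_bending: float
    F_condensation: float = 0.0
    F_intrinsic: float = 0.0
    F_extrinsic: float = 0.0
    residual_area: float = 0.0
    residual_volume: float = 0.0
    residual_closure: float = 0.0

    @property
    def F_total(self) -> float:
        return (self.F_bending + self.F_condensation + self.F_intrinsic
                + self.F_extrinsic)

    def to_json(self) -> str:
        d = asdict(self)
        d["F_total"] = self.F_total
        return json.dumps(d)


def bending_density(grid: SurfaceGrid) -> np.ndarray:
    """Helfrich bending density g_H = (C1 + C2)^2 = 4 H^2."""
    return (grid.C1 + grid.C2) ** 2


def helfrich_energy(grid: SurfaceGrid, p: ModelParams) -> float:
    """F_bending = (kappa/k_i)/2 * ∮ g_H dA."""
    return 0.5 * p.kappa_over_ki * grid.surface_integral(bending_density(grid))


def _phi_link_rotation(grid: SurfaceGrid, n_phi: int):
    delta = np.cos(grid.theta) * (2.0 * np.pi / n_phi)
    return np.cos(2.0 * delta), np.sin(2.0 * delta)


def nematic_lattice_coeffs(grid: SurfaceGrid, p: ModelParams, n_phi: int):
    """Per-row coefficients of the nematic lattice energy (see module doc).

    Returns a dict of 1-D arrays over the staggered meridian rows:
    on-site condensation ``b_c``, fossil-curvature ``b_curv``, extrinsic
    ``b_ext`` weights, link weights ``w_s``/``w_p`` and the azimuthal-link
    rotation ``(cos 2delta, sin 2delta)``.
    """
    ds = grid.L_s / grid.n_s
    dphi = 2.0 * np.pi / n_phi
    cell = grid.J * ds * dphi
    lam2 = p.lambda0**2
    b_c = lam2 * p.R_over_xi**2 * cell
    b_curv = lam2 * 0.5 * (grid.C1**2 + grid.C2**2) * cell
    b_ext = lam2 * p.mu * (grid.C1**2 - grid.C2**2) * cell
    J_mid = 0.5 * (grid.J[:-1] + grid.J[1:])
    w_s = lam2 * 0.5 * J_mid * ds * dphi / ds**2
    w_p = lam2 * 0.5 * grid.J * ds * dphi / (grid.rho * dphi) ** 2
    c2d, s2d = _phi_link_rotation(grid, n_phi)
    return {"b_c": b_c, "b_curv": b_curv, "b_ext": b_ext,
            "w_s": w_s, "w_p": w_p, "c2d": c2d, "s2d": s2d}


def nematic_energy(tex: NematicTexture, grid: SurfaceGrid, p: ModelParams):
    """Condensation, intrinsic and extrinsic energies of a texture (lattice).

    Vectorized evaluation of the same lattice functional the Monte-Carlo
    sampler uses; returns ``(F_c, F_int, F_ext)`` in units of k_i.
    """
    if not grid.staggered:
        raise ValueError("nematic energies require a staggered texture grid")
    if tex.n_s != grid.n_s:
        raise ValueError("texture/grid meridian size mismatch")
    c = nematic_lattice_coeffs(grid, p, tex.n_phi)
    q1, q2 = tex.q1, tex.q2
    t = q1**2 + q2**2
    F_c = float(np.sum(c["b_c"][:, None] * (-2.0 * t + t**2)))
    F_ext = float(np.sum(c["b_ext"][:, None] * q1))
    F_curv = float(np.sum(c["b_curv"][:, None] * t))
    d1 = q1[1:, :] - q1[:-1, :]
    d2 = q2[1:, :] - q2[:-1, :]
    F_s = float(np.sum(c["w_s"][:, None] * (d1**2 + d2**2)))
    q1r = np.roll(q1, -1, axis=1)
    q2r = np.roll(q2, -1, axis=1)
    e1 = c["c2d"][:, None] * q1r - c["s2d"][:, None] * q2r - q1
    e2 = c["s2d"][:, None] * q1r + c["c2d"][:, None] * q2r - q2
    F_p = float(np.sum(c["w_p"][:, None] * (e1**2 + e2**2)))
    return F_c, F_curv + F_s + F_p, F_ext


def total_energy(shape: ShapeParams, tex: NematicTexture | None, p: ModelParams,
                 *, normalized: bool = True) -> EnergyReport:
    """Assemble the total free energy of a (shape, texture) state.

    The shape is rescaled to surface area 4*pi unless ``normalized`` is set
    to False.  ``tex=None`` evaluates the pure-bending (Helfrich) model.
    Deterministic given its inputs; raises for self-intersecting shapes or
    mismatched grids.
    """
    if normalized:
        shape = normalize_area(shape, n_s=p.n_s)
    node_grid = build_profile(shape, n_s=p.n_s)
    if not node_grid.valid:
        raise ValueError("self-intersecting shape (rho < 0)")
    F_b = helfrich_energy(node_grid, p)
    F_c = F_i = F_e = 0.0
    if tex is not None:
        stag = build_profile(shape, n_s=tex.n_s, staggered=True)
        F_c, F_i, F_e = nematic_energy(tex, stag, p)
    return EnergyReport(
        F_bending=F_b, F_condensation=F_c, F_intrinsic=F_i, F_extrinsic=F_e,
        residual_area=node_grid.area - 4.0 * np.pi,
        residual_volume=node_grid.reduced_volume - p.v,
        residual_closure=node_grid.closure_defect,
    )


def density_report(tex: NematicTexture, grid: SurfaceGrid, p: ModelParams):
    """Per-node weighted density fields (for w-profile style exports)."""
    from .texture import extrinsic_density, intrinsic_density

    lam2 = p.lambda0**2
    return {
        "g_c": lam2 * p.R_over_xi**2 * condensation_density(tex),
        "g_int": lam2 * 0.5 * intrinsic_density(tex, grid),
        "g_ext": lam2 * p.mu * extrinsic_density(tex, grid),
    }
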