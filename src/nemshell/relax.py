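"""Equilibrium (shape, texture) states by alternating relaxation.

The hybrid minimization alternates two stages until the total free energy
stops changing:

1. *Texture stage* — Metropolis Monte Carlo on the scaled tensor components
   ``(q1, q2)`` at fixed shape, with an annealing ladder of effective
   temperatures ending in a strict quench (annealing lets defects find
   their equilibrium latitudes instead of freezing into metastable walls).
2. *Shape stage* — constrained minimization of the Fourier amplitudes at
   fixed texture, holding area (exactly, by analytic rescaling to A = 4*pi),
   reduced volume and profile closure ``rho(L_s) = 0``.

Branches (prolate / oblate / stomatocyte) are selected purely by the seed
shape: prolate and oblate seeds are area-normalized spheroids (up-down
symmetric, hence even Fourier modes only), the stomatocyte seed is an
invaginated cup built from an asymmetric mode pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.optimize import brentq, minimize

from ._kernels import metropolis_sweep
from .energy import (EnergyReport, ModelParams, helfrich_energy,
                     nematic_energy, nematic_lattice_coeffs, total_energy)
from .geometry import (InvalidShapeError, ShapeParams, build_profile,
                       normalize_area)
from .texture import NematicTexture


@dataclass(frozen=True)
class MCSchedule:
    """Annealing schedule for the Metropolis texture sampler.

    Temperatures are in units of the mean condensation energy per lattice
    cell, ``lambda0^2 (R/xi)^2 (4*pi / n_cells)``, so the ladder is
    resolution independent.  The ladder must end at 0 (strict quench).
    """

    temperatures: tuple = tuple(5.0 * 0.72**k for k in range(19)) + (0.0,)
    sweeps_per_stage: int = 150
    proposal_width: float = 0.5
    adapt: bool = True
    target_acceptance: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.sweeps_per_stage < 1:
            raise ValueError("sweeps_per_stage must be >= 1")
        if self.proposal_width <= 0:
            raise ValueError("proposal_width must be positive")

    def quench_only(self) -> "MCSchedule":
        """Short low-temperature ladder to re-relax after a shape update."""
        tail = [t for t in self.temperatures if t <= 0.3]
        temps = tuple(tail[:: max(len(tail) // 4, 1)][:4]) + (0.0,)
        return replace(self, temperatures=temps,
                       sweeps_per_stage=max(self.sweeps_per_stage // 2, 1))

    def reseeded(self, seed: int) -> "MCSchedule":
        return replace(self, seed=seed)


@dataclass
class EquilibriumState:
    """Converged (shape, texture) pair with its energy decomposition."""

    shape: ShapeParams
    texture: NematicTexture | None
    params: ModelParams
    energy: EnergyReport | None = None
    branch: str = ""
    trace: list = field(default_factory=list)
    converged: bool = False
    warning: str = ""

    @property
    def F_total(self) -> float:
        return self.energy.F_total if self.energy is not None else np.nan


def mc_relax_texture(shape: ShapeParams, tex: NematicTexture, p: ModelParams,
                     sched: MCSchedule, *, grid=None,
                     return_trace: bool = False):
    """Metropolis relaxation of the texture on a fixed shape.

    Single-site Gaussian proposals on ``(q1, q2)`` accepted against the
    nematic lattice energy; the proposal width is auto-tuned toward the
    target acceptance rate during the annealed stages and frozen during the
    final quench.  Bit reproducible for a fixed ``sched.seed``.
    """
    if grid is None:
        shape = normalize_area(shape, n_s=p.n_s)
        grid = build_profile(shape, n_s=tex.n_s, staggered=True)
    c = nematic_lattice_coeffs(grid, p, tex.n_phi)
    args = (c["b_c"], c["b_curv"], c["b_ext"], c["w_s"], c["w_p"],
            c["c2d"], c["s2d"])
    rng = np.random.default_rng(sched.seed)
    tex = tex.copy()
    n_sites = tex.n_s * tex.n_phi
    t_scale = p.lambda0**2 * p.R_over_xi**2 * (4.0 * np.pi / n_sites)
    width = sched.proposal_width
    trace = []
    for T_hat in sched.temperatures:
        T = T_hat * t_scale
        for _ in range(sched.sweeps_per_stage):
            dq = rng.normal(0.0, width, (2, tex.n_s, tex.n_phi))
            u = rng.random((tex.n_s, tex.n_phi))
            acc = metropolis_sweep(tex.q1, tex.q2, dq[0], dq[1], u, T, *args)
            if sched.adapt and T > 0.0:
                rate = acc / n_sites
                width *= 1.04 if rate > sched.target_acceptance else 0.96
                width = min(max(width, 0.01), 2.0)
            elif T <= 0.0:
                # strict quench: shrink proposals to polish the minimum
                width = max(width * 0.95, 0.002)
        F = sum(nematic_energy(tex, grid, p))
        if not np.isfinite(F):
            raise RuntimeError("nematic energy diverged during MC relaxation")
        trace.append({"T_hat": T_hat, "F_nematic": F, "width": width})
    return (tex, trace) if return_trace else tex


@dataclass
class ShapeOptResult:
    shape: ShapeParams
    success: bool
    message: str
    F_total: float


def _full_amplitudes(x, n_modes, even_only):
    a = np.zeros(n_modes)
    if even_only:
        a[1::2] = x
    else:
        a[:] = x
    return a


def minimize_shape(shape: ShapeParams, tex: NematicTexture | None,
                   p: ModelParams, *, even_only: bool = False,
                   maxiter: int = 400, ftol: float = 1e-9,
                   n_s_opt: int | None = None) -> ShapeOptResult:
    """Constrained minimization of the Fourier amplitudes at fixed texture.

    Minimizes the total free energy over the amplitudes (the profile length
    is always rescaled analytically so A = 4*pi exactly) subject to the
    reduced-volume and closure equality constraints, by SLSQP.  With
    ``even_only`` the search is restricted to up-down symmetric shapes
    (prolate/oblate branches); the stomatocyte branch uses all modes.
    Self-intersecting trial shapes are rejected through a smooth penalty.
    """
    n_s = n_s_opt or p.n_s
    n_modes = shape.n_modes
    a0 = shape.amplitudes
    x0 = a0[1::2].copy() if even_only else a0.copy()

    cache: dict = {}

    def _build(x):
        key = x.tobytes()
        if key not in cache:
            try:
                a = _full_amplitudes(x, n_modes, even_only)
                sh = ShapeParams(L_s=shape.L_s, amplitudes=a)
                sh = normalize_area(sh, n_s=n_s, oversample=8)
                g = build_profile(sh, n_s=n_s, oversample=8)
            except (InvalidShapeError, FloatingPointError):
                sh = g = None
            if len(cache) > 4096:
                cache.clear()
            cache[key] = (sh, g)
        return cache[key]

    def objective(x):
        sh, g = _build(x)
        if g is None:
            return 1e6
        if g.min_rho < -1e-6:
            return 1e4 + 1e6 * g.min_rho**2
        F = helfrich_energy(g, p)
        if tex is not None:
            stag = build_profile(sh, n_s=tex.n_s, oversample=8, staggered=True)
            F += sum(nematic_energy(tex, stag, p))
        return F

    def constraints(x):
        _, g = _build(x)
        if g is None:
            return np.array([1e3, 1e3])
        return np.array([g.reduced_volume - p.v, g.closure_defect])

    res = minimize(objective, x0, method="SLSQP",
                   constraints=[{"type": "eq", "fun": constraints}],
                   options={"maxiter": maxiter, "ftol": ftol})
    a = _full_amplitudes(res.x, n_modes, even_only)
    new_shape = normalize_area(ShapeParams(L_s=shape.L_s, amplitudes=a),
                               n_s=n_s, oversample=8)
    cons = constraints(res.x)
    # a feasible iterate with a finite energy is usable even if SLSQP
    # stopped on its iteration limit near a flat optimum
    ok = bool(np.all(np.abs(cons) < 1e-6) and np.isfinite(res.fun))
    return ShapeOptResult(shape=new_shape, success=ok,
                          message=str(res.message), F_total=float(res.fun))


# ---------------------------------------------------------------------------
# branch seeding


def _spheroid_profile(c_over_a: float, n_fit: int = 1024):
    """Arc-length tangent-angle profile of a spheroid with semi-axes (1, c)."""
    u = np.linspace(0.0, np.pi, n_fit)
    dsdu = np.hypot(np.cos(u), c_over_a * np.sin(u))
    s = cumulative_simpson(dsdu, x=u, initial=0.0)
    theta = np.arctan2(c_over_a * np.sin(u), np.cos(u))
    return s, theta


def spheroid_shape(c_over_a: float, n_modes: int = 30) -> ShapeParams:
    """Fourier shape fitted to a spheroid meridian (aspect ratio c/a)."""
    s, theta = _spheroid_profile(c_over_a)
    L = s[-1]
    s_u = np.linspace(0.0, L, s.size)
    th_u = np.interp(s_u, s, theta)
    resid = th_u - np.pi * s_u / L
    i = np.arange(1, n_modes + 1)
    basis = np.sin(np.pi * np.outer(i, s_u) / L)
    amps = np.array([2.0 / L * simpson(resid * basis[m], x=s_u)
                     for m in range(n_modes)])
    return normalize_area(ShapeParams(L_s=L, amplitudes=amps))


def _spheroid_reduced_volume(c_over_a: float) -> float:
    sh = spheroid_shape(c_over_a, n_modes=24)
    return build_profile(sh, n_s=201).reduced_volume


def spheroid_for_v(v: float, branch: str, n_modes: int = 30) -> ShapeParams:
    """Spheroid seed with the requested reduced volume on a given branch."""
    if not (0.5 <= v <= 1.0):
        raise ValueError("branch seeding supports 0.5 <= v <= 1")
    if v >= 1.0 - 1e-12:
        return ShapeParams(L_s=np.pi, amplitudes=np.zeros(n_modes))
    if branch == "prolate":
        c = brentq(lambda x: _spheroid_reduced_volume(x) - v, 1.0 + 1e-6, 12.0,
                   xtol=1e-6)
    elif branch == "oblate":
        c = brentq(lambda x: _spheroid_reduced_volume(x) - v, 0.03, 1.0 - 1e-6,
                   xtol=1e-6)
    else:
        raise ValueError(f"unknown spheroid branch {branch!r}")
    return spheroid_shape(c, n_modes=n_modes)


def cup_shape(alpha: float, b: float, w1: float,
              n_modes: int = 30, n_fit: int = 2000) -> ShapeParams | None:
    """Invaginated cup built from three tangent arcs, projected on modes.

    Outer sphere (unit radius) up to polar angle ``pi - alpha``, a rim fold
    of radius ``b`` turning the tangent past pi, and an inverted inner
    spherical cap of half-angle ``w1`` descending to the inner pole.  The
    cap radius is fixed by profile closure; returns None when the requested
    geometry cannot close.
    """
    sa, sw = np.sin(alpha), np.sin(w1)
    c = (1.0 - b) * sa / sw - b
    if c <= 0.02:
        return None
    s1 = np.pi - alpha
    s2 = b * (alpha + w1)
    s3 = c * w1
    L = s1 + s2 + s3
    s = np.linspace(0.0, L, n_fit)
    th = np.where(s <= s1, s,
                  np.where(s <= s1 + s2, (np.pi - alpha) + (s - s1) / b,
                           (np.pi + w1) - (s - s1 - s2) / c))
    resid = th - np.pi * s / L
    i = np.arange(1, n_modes + 1)
    basis = np.sin(np.pi * np.outer(i, s) / L)
    amps = np.array([2.0 / L * simpson(resid * basis[m], x=s)
                     for m in range(n_modes)])
    return normalize_area(ShapeParams(L_s=L, amplitudes=amps))


def stomatocyte_seed(v: float, n_modes: int = 30, b: float = 0.15,
                     w1: float = 1.5) -> ShapeParams:
    """Invaginated-cup seed for the stomatocyte branch at reduced volume v.

    The opening angle of the cup is solved so the seed already has the
    requested reduced volume; the constrained minimization then relaxes it
    within the branch.
    """

    def v_of(alpha):
        sh = cup_shape(alpha, b, w1, n_modes)
        return build_profile(sh, n_s=201).reduced_volume - v

    alpha = brentq(v_of, 0.35, 1.65, xtol=1e-4)
    return cup_shape(alpha, b, w1, n_modes)


def seed_branch(branch: str, v: float, p: ModelParams,
                rng: np.random.Generator | None = None) -> EquilibriumState:
    """Initial state on the requested branch with a random texture.

    prolate seeds are elongated spheroids (z-extent exceeding the equatorial
    diameter), oblate seeds flattened spheroids, stomatocyte seeds
    invaginated cups; the texture is disordered, drawn from ``rng``.
    """
    if branch in ("prolate", "oblate"):
        shape = spheroid_for_v(v, branch, n_modes=p.n_modes)
    elif branch == "stomatocyte":
        shape = stomatocyte_seed(v, n_modes=p.n_modes)
    else:
        raise ValueError(f"unknown branch {branch!r}")
    rng = rng or np.random.default_rng(p.seed)
    tex = NematicTexture.random(p.n_s, p.n_phi, rng)
    return EquilibriumState(shape=shape, texture=tex,
                            params=p.with_(v=v), branch=branch)


def classify_branch(shape: ShapeParams, n_s: int = 101) -> str:
    """Label a shape prolate or oblate by its aspect (z-extent vs diameter)."""
    g = build_profile(shape, n_s=n_s)
    height = g.z.max() - g.z.min()
    diameter = 2.0 * g.rho.max()
    return "prolate" if height > diameter else "oblate"


# ---------------------------------------------------------------------------
# alternation


def alternate_to_equilibrium(init: EquilibriumState, p: ModelParams,
                             sched: MCSchedule, max_cycles: int = 8,
                             ftol: float = 1e-4) -> EquilibriumState:
    """Alternate texture MC and shape minimization until the energy settles.

    The first cycle anneals the texture through the full temperature ladder;
    later cycles re-relax with the low-temperature tail only.  Stops when the
    total energy changes by less than ``ftol`` (absolute, units of k_i) over
    a full cycle, or at ``max_cycles`` with a warning; returns the best state
    seen, with the per-cycle energy trace attached.
    """
    p = p.with_(v=init.params.v)
    shape = normalize_area(init.shape, n_s=p.n_s)
    tex = init.texture
    even_only = init.branch in ("prolate", "oblate")
    trace = []
    best = None
    F_prev = np.inf
    warning = ""
    for cycle in range(max_cycles):
        cyc_sched = (sched if cycle == 0 else sched.quench_only()).reseeded(
            sched.seed + 1000 * cycle)
        if tex is not None:
            tex = mc_relax_texture(shape, tex, p, cyc_sched)
        opt = minimize_shape(shape, tex, p, even_only=even_only,
                             maxiter=150 if cycle == 0 else 60)
        if opt.success:
            shape = opt.shape
        rep = total_energy(shape, tex, p)
        trace.append({"cycle": cycle, "F_total": rep.F_total,
                      "F_bending": rep.F_bending,
                      "shape_ok": opt.success})
        if best is None or rep.F_total < best.F_total:
            best = EquilibriumState(shape=shape, texture=tex, params=p,
                                    energy=rep, branch=init.branch)
        if abs(F_prev - rep.F_total) < ftol:
            best.converged = True
            break
        F_prev = rep.F_total
    else:
        warning = "alternation did not converge; returning best state"
    best.trace = trace
    best.warning = warning
    return best
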