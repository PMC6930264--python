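"""Branch competition across reduced volume: the oblate-prolate boundary.

Equilibrium energies of branch-seeded states are compared as a function of
the reduced volume ``v``; the stability boundary ``v2`` is the crossing of
the prolate and oblate (discocyte) branch energies, located by bisection on
the energy difference.  The same machinery locates the classic pure-bending
stomatocyte-discocyte boundary ``v1``.

Two modes are supported: ``"bending"`` (nematic couplings off — the
deterministic Helfrich limit) and ``"hybrid"`` (full model with Monte-Carlo
texture relaxation; branch energies are the best over seeded restarts to
tame MC noise).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .energy import ModelParams, total_energy
from .relax import (EquilibriumState, MCSchedule, alternate_to_equilibrium,
                    minimize_shape, seed_branch)


@dataclass
class BranchPoint:
    v: float
    F: dict
    states: dict = field(default_factory=dict, repr=False)


@dataclass
class PhaseBoundary:
    """(k_i/kappa, k_e/k_i, v2) boundary points with branch energies."""

    points: list
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.points)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, index=False)
        return buf.getvalue()


def _branch_energy(branch: str, v: float, p: ModelParams, mode: str,
                   sched: MCSchedule | None, restarts: int,
                   init: EquilibriumState | None = None):
    """Best converged state of one branch at one reduced volume."""
    p = p.with_(v=v)
    if mode == "bending":
        state = init or seed_branch(branch, v, p)
        opt = minimize_shape(state.shape, None, p,
                             even_only=branch in ("prolate", "oblate"))
        rep = total_energy(opt.shape, None, p)
        return EquilibriumState(shape=opt.shape, texture=None, params=p,
                                energy=rep, branch=branch, converged=opt.success)
    sched = sched or MCSchedule(seed=p.seed)
    best = None
    for r in range(max(restarts, 1)):
        rng = np.random.default_rng(p.seed + 7919 * r)
        state = seed_branch(branch, v, p, rng)
        if init is not None:
            state.shape = init.shape
        st = alternate_to_equilibrium(state, p,
                                      sched.reseeded(sched.seed + 104729 * r))
        if best is None or st.F_total < best.F_total:
            best = st
    return best


def branch_energies(v: float, p: ModelParams, restarts: int = 3, *,
                    mode: str = "hybrid", sched: MCSchedule | None = None,
                    branches=("prolate", "oblate"),
                    inits: dict | None = None) -> BranchPoint:
    """Best converged total energy per branch at reduced volume ``v``."""
    inits = inits or {}
    states = {b: _branch_energy(b, v, p, mode, sched, restarts,
                                inits.get(b)) for b in branches}
    return BranchPoint(v=v, F={b: s.F_total for b, s in states.items()},
                       states=states)


def find_v2(p: ModelParams, v_lo: float = 0.55, v_hi: float = 0.75,
            tol_v: float = 0.01, *, mode: str = "hybrid",
            restarts: int = 3, sched: MCSchedule | None = None,
            branches=("prolate", "oblate"), trace: list | None = None) -> float:
    """Bisect the branch energy difference to locate the crossing volume.

    The second branch of ``branches`` must be stable (lower energy) at
    ``v_lo`` and the first at ``v_hi``; otherwise an error reporting the
    endpoint energies is raised.  Warm-starts each branch from the nearest
    previously converged shape (continuation).
    """
    first, second = branches

    inits: dict = {}

    def diff(v):
        bp = branch_energies(v, p, restarts, mode=mode, sched=sched,
                             branches=branches, inits=dict(inits))
        for b, s in bp.states.items():
            inits[b] = s
        if trace is not None:
            trace.append(bp)
        return bp.F[first] - bp.F[second]

    d_lo = diff(v_lo)
    d_hi = diff(v_hi)
    if not (d_lo > 0 > d_hi):
        raise ValueError(
            f"no bracket: F_{first}-F_{second} is {d_lo:.4g} at v={v_lo} "
            f"and {d_hi:.4g} at v={v_hi}")
    while v_hi - v_lo > tol_v:
        v_mid = 0.5 * (v_lo + v_hi)
        if diff(v_mid) > 0:
            v_lo = v_mid
        else:
            v_hi = v_mid
    return 0.5 * (v_lo + v_hi)


def find_v1(p: ModelParams, v_lo: float = 0.50, v_hi: float = 0.65,
            tol_v: float = 0.01, **kw) -> float:
    """Pure-bending stomatocyte-discocyte crossing (Helfrich lower bound)."""
    kw.setdefault("mode", "bending")
    return find_v2(p, v_lo, v_hi, tol_v,
                   branches=("oblate", "stomatocyte"), **kw)


def scan_boundary(ki_over_kappa_values, ke_over_ki_values, p: ModelParams,
                  *, v_lo: float = 0.55, v_hi: float = 0.95,
                  tol_v: float = 0.01, mode: str = "hybrid",
                  restarts: int = 3,
                  sched: MCSchedule | None = None) -> PhaseBoundary:
    """v2 boundary over a grid of elastic ratios (the stability diagram)."""
    points = []
    for ke in ke_over_ki_values:
        for ki in ki_over_kappa_values:
            pp = p.with_(kappa_over_ki=1.0 / ki, ke_over_ki=ke)
            tr: list = []
            v2 = find_v2(pp, v_lo, v_hi, tol_v, mode=mode,
                         restarts=restarts, sched=sched, trace=tr)
            last = tr[-1]
            points.append({"ki_over_kappa": ki, "ke_over_ki": ke, "v2": v2,
                           "F_prolate": last.F.get("prolate", np.nan),
                           "F_oblate": last.F.get("oblate", np.nan)})
    return PhaseBoundary(points=points,
                         meta={"tol_v": tol_v, "mode": mode,
                               "restarts": restarts, "seed": p.seed})
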