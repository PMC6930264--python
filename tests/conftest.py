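"""Shared fixtures: scaled-down study conditions reused across test modules.

Expensive equilibria (pure-bending branch states, relaxed textures) are
computed once per session at the desk-scale resolution (20 Fourier modes,
61 x 61 grid) and shared between the unit and acceptance tests.
"""

import numpy as np
import pytest

from nemshell.defects import locate_defects
from nemshell.energy import ModelParams
from nemshell.geometry import ShapeParams, build_profile
from nemshell.relax import (MCSchedule, mc_relax_texture, minimize_shape,
                            seed_branch)
from nemshell.texture import NematicTexture

N_MODES, N_S, N_PHI = 20, 61, 61


def small_params(**kw) -> ModelParams:
    base = dict(n_modes=N_MODES, n_s=N_S, n_phi=N_PHI, v=0.6)
    base.update(kw)
    return ModelParams(**base)


def relax_best_of(shape, p, seeds=(0, 1, 2)):
    """Relax the texture on a fixed shape; keep the best consistent census.

    Returns (texture, defect_set) of the lowest-energy restart whose census
    closes to total charge +2.
    """
    from nemshell.energy import nematic_energy

    grid = build_profile(shape, n_s=N_S, staggered=True)
    best = None
    for seed in seeds:
        tex0 = NematicTexture.random(N_S, N_PHI, np.random.default_rng(seed))
        tex = mc_relax_texture(shape, tex0, p, MCSchedule(seed=seed),
                               grid=grid)
        F = sum(nematic_energy(tex, grid, p))
        ds = locate_defects(tex, grid)
        good = ds.converged
        if best is None or (good and (not best[3] or F < best[2])):
            best = (tex, ds, F, good)
    return best[0], best[1]


@pytest.fixture(scope="session")
def sphere_shape():
    return ShapeParams(L_s=np.pi, amplitudes=np.zeros(N_MODES))


@pytest.fixture(scope="session")
def sphere_mc(sphere_shape):
    """Relaxed nematic texture on the unit sphere (ground state search)."""
    p = small_params(v=1.0)
    tex, ds = relax_best_of(sphere_shape, p)
    return {"shape": sphere_shape, "texture": tex, "defects": ds, "params": p}


@pytest.fixture(scope="session")
def prolate08():
    """Pure-bending prolate equilibrium at v = 0.80."""
    p = small_params(v=0.8)
    opt = minimize_shape(seed_branch("prolate", 0.8, p).shape, None, p,
                         even_only=True)
    assert opt.success
    return {"shape": opt.shape, "params": p, "F": opt.F_total}


@pytest.fixture(scope="session")
def oblate06():
    """Pure-bending discocyte equilibrium at v = 0.60."""
    p = small_params(v=0.6)
    opt = minimize_shape(seed_branch("oblate", 0.6, p).shape, None, p,
                         even_only=True)
    assert opt.success
    return {"shape": opt.shape, "params": p, "F": opt.F_total}


@pytest.fixture(scope="session")
def prolate08_texture(prolate08):
    """Relaxed texture (k_e = 0) on the v = 0.80 prolate shape."""
    tex, ds = relax_best_of(prolate08["shape"], prolate08["params"])
    return {**prolate08, "texture": tex, "defects": ds}


@pytest.fixture(scope="session")
def oblate06_texture(oblate06):
    """Relaxed texture (k_e = 0) on the v = 0.60 discocyte shape."""
    tex, ds = relax_best_of(oblate06["shape"], oblate06["params"])
    return {**oblate06, "texture": tex, "defects": ds}
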