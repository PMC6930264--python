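"""Analytic fixtures: surfaces and textures with closed-form references.

Every test input in the package is generated here — spheres, spheroids,
cylinder and flat patches (built field-by-field, so curvature terms can be
zeroed exactly), and synthetic defect textures with imposed winding.  Each
fixture carries a ``reference`` dict of closed-form values (area, volume,
curvatures, winding) exact to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ShapeParams, SurfaceGrid, build_profile
from .relax import spheroid_shape
from .texture import NematicTexture


@dataclass
class Fixture:
    name: str
    reference: dict
    shape: ShapeParams | None = None
    grid: SurfaceGrid | None = None
    texture: NematicTexture | None = None
    params: dict = field(default_factory=dict)


def _synthetic_grid(s, theta, rho, z, C1, C2, kg2, J, L_s, staggered=True):
    w = np.full(s.size, (s[-1] - s[0]) / max(s.size - 1, 1))
    if staggered:
        w = np.full(s.size, L_s / s.size)
    ds = s[1] - s[0]
    area = float(2 * np.pi * np.sum(J) * ds)
    return SurfaceGrid(s=s, theta=theta, rho=rho, z=z, C1=C1, C2=C2,
                       K=C1 * C2, H=0.5 * (C1 + C2), kg2=kg2, J=J, w_s=w,
                       area=area, volume=0.0, reduced_volume=0.0,
                       closure_defect=0.0, min_rho=float(rho.min()), L_s=L_s,
                       staggered=staggered, shape=None)


def sphere_fixture(R: float = 1.0, n_s: int = 101, **_) -> Fixture:
    shape = ShapeParams(L_s=np.pi * R, amplitudes=np.zeros(8))
    grid = build_profile(shape, n_s=n_s)
    return Fixture(
        name="sphere", shape=shape, grid=grid,
        reference={"area": 4 * np.pi * R**2, "volume": 4 * np.pi / 3 * R**3,
                   "C1": 1.0 / R, "C2": 1.0 / R, "reduced_volume": 1.0},
        params={"R": R})


def spheroid_fixture(a: float = 1.0, c: float = 2.0, n_s: int = 101,
                     n_modes: int = 24, **_) -> Fixture:
    """Spheroid with semi-axes (a, a, c); closed-form area and volume."""
    x = c / a
    if abs(x - 1.0) < 1e-12:
        return sphere_fixture(R=a, n_s=n_s)
    if x > 1.0:  # prolate
        e = np.sqrt(1.0 - 1.0 / x**2)
        area = 2 * np.pi * a**2 * (1 + (c / a) * np.arcsin(e) / e)
    else:  # oblate
        e = np.sqrt(1.0 - x**2)
        area = 2 * np.pi * a**2 * (1 + (1 - e**2) / e * np.arctanh(e))
    # spheroid_shape normalizes to A = 4*pi; rescale to semi-axis a
    shape = spheroid_shape(x, n_modes=n_modes).rescaled(
        np.sqrt(area / (4.0 * np.pi)))
    grid = build_profile(shape, n_s=n_s)
    return Fixture(
        name="spheroid", shape=shape, grid=grid,
        reference={"area": area, "volume": 4 * np.pi / 3 * a**2 * c},
        params={"a": a, "c": c})


def shape_area(shape: ShapeParams, n_s: int = 201) -> float:
    return build_profile(shape, n_s=n_s).area


def cylinder_fixture(r: float = 1.0, L: float = 2.0, n_s: int = 41,
                     **_) -> Fixture:
    """Open cylinder patch of radius r: C1 = 0, C2 = 1/r, kg2 = 0."""
    s = (np.arange(n_s) + 0.5) * (L / n_s)
    one = np.ones(n_s)
    grid = _synthetic_grid(
        s=s, theta=np.pi / 2 * one, rho=r * one, z=s, C1=0.0 * one,
        C2=one / r, kg2=0.0 * one, J=r * one, L_s=L)
    return Fixture(name="cylinder-patch", grid=grid,
                   reference={"C1": 0.0, "C2": 1.0 / r, "area": 2 * np.pi * r * L},
                   params={"r": r, "L": L})


def flat_fixture(L: float = 2.0, n_s: int = 41, **_) -> Fixture:
    """Flat Cartesian patch: all curvatures and the frame connection zero.

    The azimuthal coordinate acts as a second Cartesian direction of unit
    metric (rho = 1), so the nematic energy reduces to its flat-space form.
    """
    s = (np.arange(n_s) + 0.5) * (L / n_s)
    one = np.ones(n_s)
    zero = np.zeros(n_s)
    grid = _synthetic_grid(s=s, theta=zero, rho=one, z=zero, C1=zero,
                           C2=zero, kg2=zero, J=one, L_s=L)
    return Fixture(name="flat-patch", grid=grid,
                   reference={"C1": 0.0, "C2": 0.0}, params={"L": L})


def defect_texture_fixture(m: float = 0.5, n_s: int = 41, n_phi: int = 41,
                           core_cells: float = 3.0, center=None,
                           **_) -> Fixture:
    """Planar texture with one imposed defect of winding m at the center.

    Director angle ``theta_d = m * atan2(j - j0, k - k0)`` with a melted
    (tanh) core profile; intended for winding/detection tests on patch
    grids, where lattice indices act as Cartesian coordinates.
    """
    if center is None:
        center = (n_s // 2, n_phi // 2)
    j0, k0 = center
    jj, kk = np.meshgrid(np.arange(n_s), np.arange(n_phi), indexing="ij")
    ang = m * np.arctan2(jj - j0 + 1e-9, kk - k0 + 1e-9)
    r = np.hypot(jj - j0, kk - k0)
    lam = np.tanh(r / core_cells)
    tex = NematicTexture(lam * np.cos(2 * ang), lam * np.sin(2 * ang))
    return Fixture(name="defect-texture", texture=tex,
                   reference={"winding": m}, params={"m": m, "center": center})


_FIXTURES = {
    "sphere": sphere_fixture,
    "spheroid": spheroid_fixture,
    "cylinder-patch": cylinder_fixture,
    "flat-patch": flat_fixture,
    "defect-texture": defect_texture_fixture,
}


def make_fixture(name: str, **params) -> Fixture:
    """Build a named analytic fixture; unknown names raise ``ValueError``."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}") from None
    return builder(**params)
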