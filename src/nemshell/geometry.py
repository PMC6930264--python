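"""Differential geometry of closed axisymmetric surfaces of revolution.

A vesicle shape is encoded by the tangent angle :math:`\\theta(s)` of its
meridian profile curve, expanded in a sine series on top of a linear ramp,

.. math::

    \\theta(s) = \\theta_0 \\frac{s}{L_s}
               + \\sum_{i=1}^{N} a_i \\sin\\!\\Big(\\frac{\\pi i s}{L_s}\\Big),

with :math:`\\theta(0)=0` and :math:`\\theta(L_s)=\\theta_0=\\pi` for closed,
smooth (genus-0) shapes.  The profile coordinates follow by quadrature,
:math:`\\rho(s)=\\int_0^s\\cos\\theta`, :math:`z(s)=\\int_0^s\\sin\\theta`,
so ``s`` is exact arc length (first fundamental form ``E = rho^2``,
``F = 0``, ``G = 1``, Jacobian ``J = rho``).

Principal curvatures are ``C1 = dtheta/ds`` along meridians and
``C2 = sin(theta)/rho`` along parallels, with the smooth-pole limit
``C2 -> C1``.  Lengths are measured in units of ``R = sqrt(A/4pi)``; the
dimensionless model always works at ``A = 4pi``.

Closure ``rho(L_s) = 0`` is *not* automatic for arbitrary amplitudes: this
module only reports the closure defect, and the shape optimizer enforces it
as an equality constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson, simpson


class InvalidShapeError(ValueError):
    """Raised when a profile is geometrically unusable (e.g. rho < 0)."""


@dataclass(frozen=True)
class ShapeParams:
    """Fourier representation of the meridian tangent angle.

    Parameters
    ----------
    L_s
        Profile length in units of R; must be positive.
    amplitudes
        Sine-series amplitudes ``a_1 .. a_N`` (dimensionless).
    theta0
        Tangent angle at the far pole; ``pi`` for closed smooth shapes.
    """

    L_s: float
    amplitudes: np.ndarray
    theta0: float = np.pi

    def __post_init__(self):
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if amps.ndim != 1 or amps.size < 1:
            raise ValueError("amplitudes must be a 1-D array with N >= 1")
        if not self.L_s > 0:
            raise ValueError(f"L_s must be positive, got {self.L_s}")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_modes(self) -> int:
        return self.amplitudes.size

    def theta(self, s):
        """Tangent angle theta(s); s may be scalar or array in [0, L_s]."""
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-12 * self.L_s) or np.any(s > self.L_s * (1 + 1e-12)):
            raise ValueError("arc length s outside [0, L_s]")
        x = np.pi * s / self.L_s
        i = np.arange(1, self.n_modes + 1)
        out = self.theta0 * s / self.L_s + np.sin(np.multiply.outer(x, i)) @ self.amplitudes
        return out if out.shape else float(out)

    def dtheta_ds(self, s):
        """Meridian principal curvature C1(s) = dtheta/ds (analytic)."""
        s = np.asarray(s, dtype=float)
        x = np.pi * s / self.L_s
        i = np.arange(1, self.n_modes + 1)
        out = self.theta0 / self.L_s + np.cos(np.multiply.outer(x, i)) @ (
            np.pi * i / self.L_s * self.amplitudes
        )
        return out if out.shape else float(out)

    def rescaled(self, factor: float) -> "ShapeParams":
        """Geometrically similar shape with all lengths scaled by `factor`."""
        return replace(self, L_s=self.L_s * factor)

    def to_json(self) -> str:
        return json.dumps(
            {"L_s": self.L_s, "theta0": self.theta0, "a": self.amplitudes.tolist(),
             "N": self.n_modes}
        )

    @classmethod
    def from_json(cls, text: str) -> "ShapeParams":
        d = json.loads(text)
        return cls(L_s=d["L_s"], amplitudes=np.asarray(d["a"], dtype=float),
                   theta0=d.get("theta0", np.pi))


def theta_of_s(shape: ShapeParams, s):
    """Evaluate the meridian tangent angle at arc length ``s``.

    Raises ``ValueError`` if ``s`` lies outside ``[0, L_s]``.
    """
    return shape.theta(s)


@dataclass
class SurfaceGrid:
    """Discretized profile with all curvature fields and quadrature weights.

    All fields are sampled on the nodes ``s``; ``w_s`` are 1-D quadrature
    weights such that ``sum(w_s * f)`` approximates the meridian integral of
    ``f``.  ``staggered`` grids place nodes at cell midpoints (no nodes at
    the poles); they carry midpoint-rule weights and are used for texture
    fields, which are not single-valued at the coordinate poles.
    """

    s: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    z: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    K: np.ndarray
    H: np.ndarray
    kg2: np.ndarray
    J: np.ndarray
    w_s: np.ndarray
    area: float
    volume: float
    reduced_volume: float
    closure_defect: float
    min_rho: float
    L_s: float
    staggered: bool = False
    shape: ShapeParams | None = field(default=None, repr=False)

    @property
    def n_s(self) -> int:
        return self.s.size

    @property
    def valid(self) -> bool:
        """No self-intersection through the axis (rho >= 0 in the interior)."""
        return self.min_rho > -1e-9

    def closed(self, tol: float = 1e-5) -> bool:
        return abs(self.closure_defect) < tol and self.valid

    def line_integral(self, f: np.ndarray) -> float:
        """Integral of a nodal field along the meridian, int f ds."""
        return float(self.w_s @ np.asarray(f))

    def surface_integral(self, f) -> float:
        """Integral of a field over the closed surface, ∮ f dA.

        Accepts a 1-D axisymmetric field ``f(s)`` or a 2-D field ``f(s, phi)``
        sampled on ``n_phi`` equispaced azimuthal nodes.
        """
        f = np.asarray(f, dtype=float)
        if f.ndim == 1:
            return float(2.0 * np.pi * (self.w_s @ (self.J * f)))
        n_phi = f.shape[1]
        dphi = 2.0 * np.pi / n_phi
        return float(dphi * (self.w_s @ (self.J * f.sum(axis=1))))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"s": self.s, "rho": self.rho, "z": self.z, "theta": self.theta,
             "C1": self.C1, "C2": self.C2, "K": self.K, "H": self.H,
             "kg2": self.kg2, "J": self.J}
        )


def _simpson_weights(n: int, h: float) -> np.ndarray:
    """Composite-Simpson weights on a uniform grid (trapezoid patch if n even)."""
    w = np.zeros(n)
    if n < 3:
        w[:] = h / 2.0
        return w
    m = n if n % 2 == 1 else n - 1
    w[0:m] = h / 3.0
    w[1:m - 1:2] = 4.0 * h / 3.0
    w[2:m - 1:2] = 2.0 * h / 3.0
    w[m - 1] = h / 3.0
    if n % 2 == 0:  # close the last cell with a trapezoid
        w[-2] += h / 2.0
        w[-1] += h / 2.0
    return w


def build_profile(shape: ShapeParams, n_s: int = 101, *, oversample: int = 16,
                  staggered: bool = False) -> SurfaceGrid:
    """Construct the surface of revolution for a shape.

    The profile is integrated by composite Simpson quadrature on a uniform
    fine grid (``oversample`` sub-intervals per output cell) and sampled on
    ``n_s`` nodes — at the cell midpoints when ``staggered``.  The closure
    defect ``|rho(L_s)|`` is reported, never enforced.
    """
    if n_s < 3:
        raise ValueError("n_s must be >= 3")
    L = shape.L_s
    if staggered:
        n_fine = 2 * oversample * n_s
        idx = oversample * (2 * np.arange(n_s) + 1)
    else:
        n_fine = oversample * (n_s - 1)
        idx = oversample * np.arange(n_s)
    s_fine = np.linspace(0.0, L, n_fine + 1)
    h = s_fine[1] - s_fine[0]
    th_fine = shape.theta(s_fine)
    rho_fine = cumulative_simpson(np.cos(th_fine), dx=h, initial=0.0)
    z_fine = cumulative_simpson(np.sin(th_fine), dx=h, initial=0.0)

    area = float(2.0 * np.pi * simpson(rho_fine, dx=h))
    volume = float(np.pi * simpson(rho_fine**2 * np.sin(th_fine), dx=h))
    R0 = np.sqrt(max(area, 1e-300) / (4.0 * np.pi))
    v = volume / (4.0 * np.pi / 3.0 * R0**3) if area > 0 else 0.0

    s = s_fine[idx]
    theta = th_fine[idx]
    rho = rho_fine[idx]
    z = z_fine[idx]
    C1 = shape.dtheta_ds(s)
    C2 = np.empty_like(C1)
    pole = np.zeros(s.size, dtype=bool)
    if not staggered:
        pole[0] = True  # rho(0) = 0 by construction
        pole[-1] = np.abs(rho[-1]) < 1e-8  # far pole only if actually closed
    interior_rho = np.where(pole, 1.0, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        C2 = np.where(pole, C1, np.sin(theta) / interior_rho)
    # tiny-rho interior nodes (numerically touching the axis): use the pole limit
    near_axis = (~pole) & (np.abs(rho) < 1e-10)
    C2[near_axis] = C1[near_axis]

    K = C1 * C2
    H = 0.5 * (C1 + C2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kg2 = np.where(pole | near_axis,
                       np.sign(np.cos(theta)) * np.inf,
                       np.cos(theta) / np.where(np.abs(rho) < 1e-300, 1e-300, rho))
    J = rho.copy()

    if staggered:
        w = np.full(n_s, L / n_s)
    else:
        w = _simpson_weights(n_s, s[1] - s[0])

    interior = rho_fine[1:-1]
    min_rho = float(interior.min()) if interior.size else 0.0
    return SurfaceGrid(
        s=s, theta=theta, rho=rho, z=z, C1=C1, C2=C2, K=K, H=H, kg2=kg2, J=J,
        w_s=w, area=area, volume=volume, reduced_volume=float(v),
        closure_defect=float(rho_fine[-1]), min_rho=min_rho, L_s=L,
        staggered=staggered, shape=shape,
    )


def principal_curvatures(grid: SurfaceGrid, shape: ShapeParams | None = None):
    """Principal curvatures (C1, C2) = (dtheta/ds, sin(theta)/rho).

    C1 is evaluated analytically from the sine series; C2 uses the smooth-pole
    limit C2 -> C1 at the poles.  Raises ``InvalidShapeError`` if rho vanishes
    away from the poles (profile touching the rotation axis).
    """
    shape = shape or grid.shape
    if shape is None:
        raise ValueError("grid carries no shape and none was given")
    interior = slice(1, -1) if not grid.staggered else slice(None)
    if np.any(grid.rho[interior] <= 0) and grid.min_rho <= 0:
        raise InvalidShapeError("rho vanishes away from the poles")
    return grid.C1, grid.C2


def curvature_invariants(grid: SurfaceGrid):
    """Gaussian K, mean H, geodesic curvature of parallels kg2, Jacobian J.

    In the arc-length parameterization these reduce to K = C1*C2,
    2H = C1 + C2, kg2 = cos(theta)/rho and J = rho.
    """
    return grid.K, grid.H, grid.kg2, grid.J


def area_volume(grid: SurfaceGrid):
    """Total area A, enclosed volume V and reduced volume v = V/(4pi/3 R^3).

    Raises ``InvalidShapeError`` for an open (non-closing) profile.
    """
    if not grid.closed(tol=1e-3 * grid.L_s):
        raise InvalidShapeError(
            f"profile does not close: |rho(L_s)| = {abs(grid.closure_defect):.3g}"
        )
    return grid.area, grid.volume, grid.reduced_volume


def normalize_area(shape: ShapeParams, n_s: int = 101, **kw) -> ShapeParams:
    """Rescale a shape so its surface area is exactly 4*pi (lengths in R)."""
    g = build_profile(shape, n_s=n_s, **kw)
    if g.area <= 0:
        raise InvalidShapeError("non-positive area")
    return shape.rescaled(np.sqrt(4.0 * np.pi / g.area))


def revolution_mesh(grid: SurfaceGrid, n_phi: int = 64):
    """Triangulated surface-of-revolution mesh (vertices, faces) for export."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    verts = np.stack(
        [np.outer(grid.rho, np.cos(phi)).ravel(),
         np.outer(grid.rho, np.sin(phi)).ravel(),
         np.repeat(grid.z, n_phi)], axis=1)
    faces = []
    for j in range(grid.n_s - 1):
        for k in range(n_phi):
            a = j * n_phi + k
            b = j * n_phi + (k + 1) % n_phi
            c = (j + 1) * n_phi + k
            d = (j + 1) * n_phi + (k + 1) % n_phi
            faces.append((a, b, d))
            faces.append((a, d, c))
    return verts, np.asarray(faces, dtype=int)
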