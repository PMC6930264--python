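"""In-plane nematic order on an axisymmetric surface.

The scaled 2-D order tensor is parameterized in the principal frame
``(e1, e2)`` (meridian, parallel) as

.. math::

    Q = q_1 (e_1\\otimes e_1 - e_2\\otimes e_2)
      + q_2 (e_1\\otimes e_2 + e_2\\otimes e_1),

so ``q1 = lam*cos(2*theta_d)``, ``q2 = lam*sin(2*theta_d)`` with amplitude
``lam = sqrt(q1^2 + q2^2)`` (bulk value 1 after scaling by the equilibrium
order parameter) and director angle ``theta_d`` measured from the meridian.

Energy densities (dimensionless, see the free-energy module for weights):

* condensation  ``g_c = -Tr Q^2 + (Tr Q^2)^2/4 = -2 lam^2 + lam^4``,
* extrinsic     ``g_ext = Q . C^2 = q1 (C1^2 - C2^2)``,
* intrinsic     ``g_int = |grad_s Q|^2``, the squared surface gradient of the
  *embedded* tensor.  In the principal frame it splits into covariant
  in-surface derivatives of ``(q1, q2)`` — with the spin-2 connection
  ``2*kg2`` coming from the rotation of the frame along parallels — plus the
  curvature ("normal production") term ``lam^2 (C1^2 + C2^2)`` generated by
  tilting of the tangent frame in 3-D:

  .. math::

      g_{int} = (D_s q_1)^2 + (D_s q_2)^2 + (D_\\varphi q_1)^2
              + (D_\\varphi q_2)^2 + (q_1^2+q_2^2)(C_1^2+C_2^2),

  with ``D_s = d/ds`` and
  ``D_phi q1 = (1/rho) dq1/dphi - 2 kg2 q2``,
  ``D_phi q2 = (1/rho) dq2/dphi + 2 kg2 q1``.

  Tensor norms use the convention ``|A|^2 = (1/2) A_ij A_ij``, under which a
  locally parallel-transported unit-amplitude field carries exactly the
  fossil density ``C1^2 + C2^2``.

Texture grids are staggered half a cell away from the poles, where the
``(e1, e2)`` frame (and hence ``q1, q2``) is not single-valued; the ``J -> 0``
area weight suppresses the pole cells in all integrals.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceGrid


@dataclass
class NematicTexture:
    """Scaled tensor components q1, q2 on a (s, phi) grid.

    Arrays are indexed ``[j, k]`` with ``j`` the (staggered) meridian node and
    ``k`` the azimuthal node; the phi direction is periodic with ``n_phi``
    equispaced nodes on [0, 2*pi).
    """

    q1: np.ndarray
    q2: np.ndarray

    def __post_init__(self):
        self.q1 = np.asarray(self.q1, dtype=float)
        self.q2 = np.asarray(self.q2, dtype=float)
        if self.q1.shape != self.q2.shape or self.q1.ndim != 2:
            raise ValueError("q1 and q2 must be 2-D arrays of identical shape")

    @property
    def n_s(self) -> int:
        return self.q1.shape[0]

    @property
    def n_phi(self) -> int:
        return self.q1.shape[1]

    @property
    def phi(self) -> np.ndarray:
        return np.arange(self.n_phi) * (2.0 * np.pi / self.n_phi)

    def amplitude(self) -> np.ndarray:
        return np.hypot(self.q1, self.q2)

    def director_angle(self) -> np.ndarray:
        """Director angle in [0, pi) from the meridian; NaN where lam = 0."""
        ang = 0.5 * np.arctan2(self.q2, self.q1)
        ang = np.mod(ang, np.pi)
        ang[self.amplitude() < 1e-300] = np.nan
        return ang

    @classmethod
    def uniform(cls, n_s: int, n_phi: int, q1: float = 1.0, q2: float = 0.0):
        return cls(np.full((n_s, n_phi), float(q1)), np.full((n_s, n_phi), float(q2)))

    @classmethod
    def random(cls, n_s: int, n_phi: int, rng: np.random.Generator,
               scale: float = 0.5):
        """Disordered initial texture with isotropically distributed (q1, q2)."""
        return cls(rng.normal(0.0, scale, (n_s, n_phi)),
                   rng.normal(0.0, scale, (n_s, n_phi)))

    def copy(self) -> "NematicTexture":
        return NematicTexture(self.q1.copy(), self.q2.copy())

    def rolled(self, shift: int) -> "NematicTexture":
        """Texture rigidly rotated by `shift` azimuthal cells."""
        return NematicTexture(np.roll(self.q1, shift, axis=1),
                              np.roll(self.q2, shift, axis=1))

    def to_json(self) -> str:
        return json.dumps({"q1": self.q1.tolist(), "q2": self.q2.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NematicTexture":
        d = json.loads(text)
        return cls(np.asarray(d["q1"]), np.asarray(d["q2"]))

    def to_csv(self, grid: SurfaceGrid) -> str:
        import pandas as pd

        s = np.repeat(grid.s, self.n_phi)
        phi = np.tile(self.phi, self.n_s)
        df = pd.DataFrame(
            {"s": s, "phi": phi, "q1": self.q1.ravel(), "q2": self.q2.ravel(),
             "lambda": self.amplitude().ravel(),
             "theta_dir": self.director_angle().ravel()})
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()


def amplitude_director(tex: NematicTexture):
    """Order amplitude lam and director angle (lam = 0 cells report NaN)."""
    return tex.amplitude(), tex.director_angle()


def condensation_density(tex: NematicTexture) -> np.ndarray:
    """Landau condensation density g_c = -2(q1^2+q2^2) + (q1^2+q2^2)^2."""
    t = tex.q1**2 + tex.q2**2
    return -2.0 * t + t**2


def extrinsic_density(tex: NematicTexture, grid: SurfaceGrid) -> np.ndarray:
    """Extrinsic (deviatoric) density g_ext = q1 (C1^2 - C2^2).

    Equals ``lam (C1^2 - C2^2) cos(2 theta_d)`` in the eigenframe; zero
    wherever the surface is locally umbilical (C1 = C2).
    """
    _check_grid(tex, grid)
    return tex.q1 * (grid.C1**2 - grid.C2**2)[:, None]


def covariant_gradient(q1: np.ndarray, q2: np.ndarray, grid: SurfaceGrid,
                       *, periodic_phi: bool = True, dphi: float | None = None):
    """Covariant in-surface derivatives (Ds q1, Ds q2, Dphi q1, Dphi q2).

    Centred finite differences (one-sided at the meridian ends, and at the
    phi patch ends when ``periodic_phi`` is False) with metric factors 1 and
    1/rho, and the spin-2 frame connection 2*kg2 along parallels.
    """
    ds = grid.s[1] - grid.s[0]
    if dphi is None:
        dphi = 2.0 * np.pi / q1.shape[1]
    dq1_s = np.gradient(q1, ds, axis=0, edge_order=2)
    dq2_s = np.gradient(q2, ds, axis=0, edge_order=2)
    if periodic_phi:
        dq1_p = (np.roll(q1, -1, axis=1) - np.roll(q1, 1, axis=1)) / (2 * dphi)
        dq2_p = (np.roll(q2, -1, axis=1) - np.roll(q2, 1, axis=1)) / (2 * dphi)
    else:
        dq1_p = np.gradient(q1, dphi, axis=1, edge_order=2)
        dq2_p = np.gradient(q2, dphi, axis=1, edge_order=2)
    inv_rho = (1.0 / grid.rho)[:, None]
    kg2 = grid.kg2[:, None]
    Dp_q1 = inv_rho * dq1_p - 2.0 * kg2 * q2
    Dp_q2 = inv_rho * dq2_p + 2.0 * kg2 * q1
    return dq1_s, dq2_s, Dp_q1, Dp_q2


def intrinsic_density(tex: NematicTexture, grid: SurfaceGrid) -> np.ndarray:
    """Full embedded-gradient density g_int = |grad_s Q|^2.

    Sum of the covariant in-surface gradient of (q1, q2) and the normal
    production term ``(q1^2+q2^2)(C1^2+C2^2)``; for a locally
    parallel-transported unit-amplitude field this reduces to the fossil
    value ``C1^2 + C2^2``.
    """
    _check_grid(tex, grid)
    Ds1, Ds2, Dp1, Dp2 = covariant_gradient(tex.q1, tex.q2, grid)
    fossil = ((tex.q1**2 + tex.q2**2) * (grid.C1**2 + grid.C2**2)[:, None])
    return Ds1**2 + Ds2**2 + Dp1**2 + Dp2**2 + fossil


def parallel_transported_texture(grid: SurfaceGrid, n_phi: int | None = None,
                                 theta_dir0: float = 0.0,
                                 phi: np.ndarray | None = None) -> NematicTexture:
    """Unit-amplitude texture parallel transported along parallels from phi=0.

    The director angle obeys ``d(theta_d)/dphi = -cos(theta)`` (the frame
    rotates at rate kg2 per unit parallel arc), integrated on the continuous
    branch from phi = 0.  The field is generally *not* single-valued around
    the full parallel — it serves as a local (fossil-energy) reference in the
    column near phi = 0, where it is also transported along meridians.
    """
    if phi is None:
        phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    ang = theta_dir0 - np.multiply.outer(np.cos(grid.theta), phi)
    return NematicTexture(np.cos(2.0 * ang), np.sin(2.0 * ang))


def _check_grid(tex: NematicTexture, grid: SurfaceGrid):
    if tex.n_s != grid.n_s:
        raise ValueError(
            f"texture has {tex.n_s} meridian rows but grid has {grid.n_s}")
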