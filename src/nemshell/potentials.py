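"""Geometric curvature potentials predicting defect-attracting regions.

For a locally parallel-transported (fossil) director field the intrinsic and
extrinsic elastic densities depend on geometry alone:

* ``w_int = C1^2 + C2^2`` — the fossil intrinsic penalty; it locally
  depresses the ordering temperature, ``T*_eff = T* - (k_i/4 alpha_0) w_int``;
* ``w_ext = (C1^2 - C2^2) cos(2 theta_d)``, minimized over the director
  orientation: ``w_ext_min = -|C1^2 - C2^2|``;
* the total potential ``w_t = w_int/2 + mu * w_ext_min`` (with the
  ``lambda0 = 1/2`` convention inside ``mu``).

Regions where ``w_t(s)`` is locally maximal tend to attract topological
defects — exactly at the maximum for oblates, slightly poleward of it for
prolates where like-charged defects repel each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import ModelParams
from .geometry import SurfaceGrid


@dataclass
class PotentialProfile:
    """Curvature-potential profiles along the meridian."""

    s: np.ndarray
    w_int: np.ndarray
    w_ext_min: np.ndarray
    w_t: np.ndarray
    maxima_idx: np.ndarray
    transition_shift: np.ndarray
    L_s: float
    mu: float

    @property
    def maxima_s(self) -> np.ndarray:
        return self.s[self.maxima_idx]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"s": self.s, "w_int": self.w_int,
                             "w_ext_min": self.w_ext_min, "w_t": self.w_t})

    def predicted_sites_json(self) -> str:
        import json

        return json.dumps({"mu": self.mu, "L_s": self.L_s,
                           "maxima_s": self.maxima_s.tolist()})


def intrinsic_potential(grid: SurfaceGrid) -> np.ndarray:
    """Fossil intrinsic potential w_int = C1^2 + C2^2 (>= 0)."""
    return grid.C1**2 + grid.C2**2


def extrinsic_potential(grid: SurfaceGrid, theta_dir) -> np.ndarray:
    """Orientation-dependent extrinsic potential (C1^2 - C2^2) cos(2 theta_d)."""
    return (grid.C1**2 - grid.C2**2) * np.cos(2.0 * np.asarray(theta_dir))


def extrinsic_potential_min(grid: SurfaceGrid) -> np.ndarray:
    """Minimal extrinsic potential w_ext_min = -|C1^2 - C2^2| (<= 0)."""
    return -np.abs(grid.C1**2 - grid.C2**2)


def transition_shift(grid: SurfaceGrid) -> np.ndarray:
    """Local depression of the ordering temperature, w_int/4.

    Dimensionless field proportional to w_int; in physical units the shift is
    ``(k_i / 4 alpha_0) * w_int`` (the k_e = 0 renormalization of T*).
    """
    return 0.25 * intrinsic_potential(grid)


def _local_maxima(w: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Discrete interior local maxima with plateau ties broken toward larger J."""
    idx = []
    n = w.size
    j = 1
    while j < n - 1:
        k = j  # plateau [j, k] of equal values
        while k + 1 < n and w[k + 1] == w[j]:
            k += 1
        if k < n - 1 and w[j] > w[j - 1] and w[j] > w[k + 1]:
            plateau = np.arange(j, k + 1)
            idx.append(int(plateau[np.argmax(J[plateau])]))
        j = k + 1
    return np.asarray(idx, dtype=int)


def total_potential(grid: SurfaceGrid, p: ModelParams) -> PotentialProfile:
    """Total curvature potential w_t = w_int/2 + mu * w_ext_min and its peaks."""
    w_int = intrinsic_potential(grid)
    w_ext = extrinsic_potential_min(grid)
    w_t = 0.5 * w_int + p.mu * w_ext
    return PotentialProfile(
        s=grid.s, w_int=w_int, w_ext_min=w_ext, w_t=w_t,
        maxima_idx=_local_maxima(w_t, grid.J),
        transition_shift=0.25 * w_int, L_s=grid.L_s, mu=p.mu)


def patch_charge(grid: SurfaceGrid, s_lo: float, s_hi: float) -> float:
    """Smeared Gaussian-curvature charge -(1/2pi) ∬ K dA over an s-interval.

    Diagnostic for effective-topological-charge bookkeeping on user-chosen
    patches; the closed surface carries total smeared charge -2.
    """
    mask = (grid.s >= s_lo) & (grid.s <= s_hi)
    f = np.where(mask, grid.K, 0.0)
    return float(-grid.surface_integral(f) / (2.0 * np.pi))


def distance_to_peak(profile: PotentialProfile, s: float) -> float:
    """Meridian distance from s to the nearest w_t local maximum."""
    if profile.maxima_idx.size == 0:
        return np.inf
    return float(np.min(np.abs(profile.maxima_s - s)))
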