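"""Numba kernels for the Metropolis texture sampler.

The lattice energy is the one assembled in :mod:`nemshell.energy`
(``nematic_lattice_coeffs``): on-site condensation/fossil/extrinsic terms
plus nearest-neighbour link terms for the covariant gradient, with the
spin-2 rotation on azimuthal links.  A sweep visits every site once in
raster order; proposals and uniforms are pre-drawn so runs are bit
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def _site_energy(j, k, a, b, q1, q2, n_s, n_phi,
                 b_c, b_curv, b_ext, w_s, w_p, c2d, s2d):
    t = a * a + b * b
    e = b_c[j] * (-2.0 * t + t * t) + b_curv[j] * t + b_ext[j] * a
    if j > 0:
        da = a - q1[j - 1, k]
        db = b - q2[j - 1, k]
        e += w_s[j - 1] * (da * da + db * db)
    if j < n_s - 1:
        da = q1[j + 1, k] - a
        db = q2[j + 1, k] - b
        e += w_s[j] * (da * da + db * db)
    kp = k + 1 if k + 1 < n_phi else 0
    km = k - 1 if k > 0 else n_phi - 1
    # link k -> k+1: this site is the unrotated member
    e1 = c2d[j] * q1[j, kp] - s2d[j] * q2[j, kp] - a
    e2 = s2d[j] * q1[j, kp] + c2d[j] * q2[j, kp] - b
    e += w_p[j] * (e1 * e1 + e2 * e2)
    # link k-1 -> k: this site enters rotated
    e1 = c2d[j] * a - s2d[j] * b - q1[j, km]
    e2 = s2d[j] * a + c2d[j] * b - q2[j, km]
    e += w_p[j] * (e1 * e1 + e2 * e2)
    return e


@njit(cache=False, fastmath=False)
def metropolis_sweep(q1, q2, dq1, dq2, urand, T,
                     b_c, b_curv, b_ext, w_s, w_p, c2d, s2d):
    """One in-place Metropolis sweep; returns the number of accepted moves.

    ``T <= 0`` is a strict quench: only non-increasing moves are accepted.
    """
    n_s, n_phi = q1.shape
    accepted = 0
    for j in range(n_s):
        for k in range(n_phi):
            a0 = q1[j, k]
            b0 = q2[j, k]
            a1 = a0 + dq1[j, k]
            b1 = b0 + dq2[j, k]
            e0 = _site_energy(j, k, a0, b0, q1, q2, n_s, n_phi,
                              b_c, b_curv, b_ext, w_s, w_p, c2d, s2d)
            e1 = _site_energy(j, k, a1, b1, q1, q2, n_s, n_phi,
                              b_c, b_curv, b_ext, w_s, w_p, c2d, s2d)
            dE = e1 - e0
            if dE <= 0.0 or (T > 0.0 and urand[j, k] < np.exp(-dE / T)):
                q1[j, k] = a1
                q2[j, k] = b1
                accepted += 1
    return accepted
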