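"""Nematic order parameter fields and their energy densities."""

import numpy as np
import pytest

from nemshell.fixtures import make_fixture
from nemshell.geometry import ShapeParams, build_profile
from nemshell.texture import (NematicTexture, amplitude_director,
                              condensation_density, covariant_gradient,
                              extrinsic_density, intrinsic_density,
                              parallel_transported_texture)


@pytest.mark.parametrize("q1, q2, lam, ang", [
    (1.0, 0.0, 1.0, 0.0),            # along the meridian
    (0.0, 1.0, 1.0, np.pi / 4),
    (-1.0, 0.0, 1.0, np.pi / 2),     # along the parallel
])
def test_amplitude_director_values(q1, q2, lam, ang):
    tex = NematicTexture.uniform(3, 4, q1, q2)
    lam_f, ang_f = amplitude_director(tex)
    assert lam_f[0, 0] == pytest.approx(lam)
    assert ang_f[0, 0] == pytest.approx(ang)


def test_director_angle_undefined_at_zero_amplitude():
    tex = NematicTexture.uniform(2, 2, 0.0, 0.0)
    _, ang = amplitude_director(tex)
    assert np.all(np.isnan(ang))


@pytest.mark.parametrize("q1, q2, expected", [
    (1.0, 0.0, -1.0),   # -2 + 1
    (0.0, 0.0, 0.0),
    (1.0, 1.0, 0.0),    # -4 + 4
])
def test_condensation_density_values(q1, q2, expected):
    tex = NematicTexture.uniform(2, 3, q1, q2)
    assert condensation_density(tex)[0, 0] == pytest.approx(expected)


def test_extrinsic_density_sphere_vanishes():
    fx = make_fixture("sphere")
    grid = build_profile(fx.shape, n_s=21, staggered=True)
    tex = NematicTexture.uniform(21, 8, 0.3, -0.7)
    np.testing.assert_allclose(extrinsic_density(tex, grid), 0.0, atol=1e-9)


@pytest.mark.parametrize("q1, q2, expected", [
    (1.0, 0.0, -1.0 / 0.5**2),   # meridian-aligned on a cylinder, r = 0.5
    (0.0, 1.0, 0.0),             # at 45 degrees the deviatoric pull cancels
])
def test_extrinsic_density_cylinder(q1, q2, expected):
    fx = make_fixture("cylinder-patch", r=0.5)
    tex = NematicTexture.uniform(fx.grid.n_s, 8, q1, q2)
    np.testing.assert_allclose(extrinsic_density(tex, fx.grid), expected,
                               atol=1e-12)


def test_extrinsic_bound():
    """|g_ext| <= lam |C1^2 - C2^2| with equality on the principal axes."""
    fx = make_fixture("cylinder-patch", r=0.5)
    rng = np.random.default_rng(3)
    tex = NematicTexture.random(fx.grid.n_s, 8, rng)
    g_e = extrinsic_density(tex, fx.grid)
    bound = tex.amplitude() * np.abs(fx.grid.C1**2 - fx.grid.C2**2)[:, None]
    assert np.all(np.abs(g_e) <= bound + 1e-12)
    aligned = NematicTexture.uniform(fx.grid.n_s, 8, -1.0, 0.0)
    np.testing.assert_allclose(
        np.abs(extrinsic_density(aligned, fx.grid)),
        aligned.amplitude() * np.abs(fx.grid.C1**2 - fx.grid.C2**2)[:, None])


def test_flat_uniform_texture_has_zero_intrinsic_density():
    fx = make_fixture("flat-patch")
    tex = NematicTexture.uniform(fx.grid.n_s, 12, 0.6, -0.2)
    np.testing.assert_allclose(intrinsic_density(tex, fx.grid), 0.0,
                               atol=1e-12)


@pytest.mark.parametrize("amps", [
    np.zeros(4),                          # sphere
    np.array([0.3, 0.0, 0.0, 0.0]),       # egg
    np.array([0.1, -0.2, 0.05, 0.1]),
])
def test_parallel_transport_fossil_energy(amps):
    """A locally parallel-transported unit-amplitude field carries exactly
    the fossil density C1^2 + C2^2 (evaluated on a small phi patch around
    the transported column)."""
    shape = ShapeParams(L_s=np.pi, amplitudes=amps)
    grid = build_profile(shape, n_s=101, staggered=True)
    dphi = 1e-3
    tex = parallel_transported_texture(grid, phi=np.arange(-2, 3) * dphi)
    D = covariant_gradient(tex.q1, tex.q2, grid, periodic_phi=False,
                           dphi=dphi)
    mid = 2
    g_int = sum(d[:, mid]**2 for d in D) + (
        tex.q1[:, mid]**2 + tex.q2[:, mid]**2) * (grid.C1**2 + grid.C2**2)
    np.testing.assert_allclose(g_int, grid.C1**2 + grid.C2**2, atol=1e-4)


def _embedding_oracle(grid, n_phi, q1, q2):
    """|grad_s Q|^2 by finite-differencing the embedded Cartesian tensor."""
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    th = grid.theta
    e1 = np.stack([np.cos(th)[:, None] * np.cos(phi)[None, :],
                   np.cos(th)[:, None] * np.sin(phi)[None, :],
                   np.broadcast_to(np.sin(th)[:, None], (th.size, n_phi))], -1)
    e2 = np.stack([np.broadcast_to(-np.sin(phi)[None, :], (th.size, n_phi)),
                   np.broadcast_to(np.cos(phi)[None, :], (th.size, n_phi)),
                   np.zeros((th.size, n_phi))], -1)
    E1 = (e1[..., :, None] * e1[..., None, :]
          - e2[..., :, None] * e2[..., None, :])
    E2 = (e1[..., :, None] * e2[..., None, :]
          + e2[..., :, None] * e1[..., None, :])
    Q = q1[..., None, None] * E1 + q2[..., None, None] * E2
    ds = grid.s[1] - grid.s[0]
    dphi = phi[1] - phi[0]
    dQs = np.gradient(Q, ds, axis=0, edge_order=2)
    dQp = ((np.roll(Q, -1, axis=1) - np.roll(Q, 1, axis=1)) / (2 * dphi)
           / grid.rho[:, None, None, None])
    return 0.5 * (np.sum(dQs**2, axis=(-2, -1)) + np.sum(dQp**2, axis=(-2, -1)))


def test_intrinsic_density_matches_embedding_oracle():
    """The frame-component formula (spin connection + normal production)
    agrees with brute-force differentiation of the embedded 3-D tensor."""
    shape = ShapeParams(L_s=np.pi, amplitudes=np.array([0.25, 0.0, 0.1, 0.0]))
    grid = build_profile(shape, n_s=81, staggered=True)
    n_phi = 80
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    q1 = 0.8 + 0.1 * np.sin(grid.s[:, None]) * np.cos(phi[None, :])
    q2 = 0.2 * np.cos(grid.s[:, None]) + 0.1 * np.sin(2 * phi[None, :])
    tex = NematicTexture(q1, q2)
    gi = intrinsic_density(tex, grid)
    gi_oracle = _embedding_oracle(grid, n_phi, q1, q2)
    I_mod = grid.surface_integral(gi)
    I_ora = grid.surface_integral(gi_oracle)
    assert I_mod == pytest.approx(I_ora, rel=0.02)
    inner = slice(5, -5)
    np.testing.assert_allclose(gi[inner], gi_oracle[inner], rtol=0.05,
                               atol=1e-3)


def test_intrinsic_density_nonnegative_and_above_fossil_average():
    shape = ShapeParams(L_s=np.pi, amplitudes=np.zeros(4))
    grid = build_profile(shape, n_s=61, staggered=True)
    tex = NematicTexture.uniform(61, 40, 1.0, 0.0)  # lam = 1 everywhere
    gi = intrinsic_density(tex, grid)
    assert np.all(gi >= -1e-12)
    fossil = grid.C1**2 + grid.C2**2
    assert (grid.surface_integral(gi) / (4 * np.pi)
            >= grid.surface_integral(fossil) / (4 * np.pi) - 1e-9)


def test_rotational_symmetry_of_densities():
    """A rigid phi-rotation leaves all density surface integrals unchanged."""
    shape = ShapeParams(L_s=np.pi, amplitudes=np.array([0.2, 0.1]))
    grid = build_profile(shape, n_s=41, staggered=True)
    rng = np.random.default_rng(11)
    tex = NematicTexture.random(41, 24, rng)
    rolled = tex.rolled(7)
    for density in (condensation_density,):
        assert grid.surface_integral(density(tex)) == pytest.approx(
            grid.surface_integral(density(rolled)), rel=1e-12)
    for density in (extrinsic_density, intrinsic_density):
        assert grid.surface_integral(density(tex, grid)) == pytest.approx(
            grid.surface_integral(density(rolled, grid)), rel=1e-10)


def test_texture_roundtrip_and_validation():
    rng = np.random.default_rng(0)
    tex = NematicTexture.random(5, 6, rng)
    back = NematicTexture.from_json(tex.to_json())
    np.testing.assert_allclose(back.q1, tex.q1)
    with pytest.raises(ValueError):
        NematicTexture(np.zeros((2, 3)), np.zeros((3, 2)))
    with pytest.raises(ValueError):
        intrinsic_density(NematicTexture.uniform(5, 6),
                          build_profile(shape_for_mismatch(), n_s=7,
                                        staggered=True))


def shape_for_mismatch():
    return ShapeParams(L_s=np.pi, amplitudes=np.zeros(2))
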