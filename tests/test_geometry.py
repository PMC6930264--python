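"""Axisymmetric surface construction and differential-geometry identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nemshell.geometry import (InvalidShapeError, ShapeParams, area_volume,
                               build_profile, curvature_invariants,
                               normalize_area, principal_curvatures,
                               theta_of_s)

SPHERE = ShapeParams(L_s=np.pi, amplitudes=np.zeros(4))
EGG = ShapeParams(L_s=np.pi, amplitudes=np.array([0.3, 0.0, 0.0, 0.0]))


@pytest.mark.parametrize("shape, s, expected", [
    (SPHERE, np.pi / 2, np.pi / 2),            # linear ramp only
    (SPHERE, np.pi, np.pi),                    # boundary condition
    (ShapeParams(2.7, np.zeros(3)), 2.7, np.pi),
    (EGG, np.pi / 2, np.pi / 2 + 0.3),         # sin(pi/2) = 1
    (EGG, 0.0, 0.0),
])
def test_theta_of_s_values(shape, s, expected):
    assert theta_of_s(shape, s) == pytest.approx(expected, abs=1e-14)


def test_theta_of_s_domain_error():
    with pytest.raises(ValueError):
        theta_of_s(SPHERE, -0.1)
    with pytest.raises(ValueError):
        theta_of_s(SPHERE, np.pi + 0.1)


def test_shape_params_validation():
    with pytest.raises(ValueError):
        ShapeParams(L_s=-1.0, amplitudes=np.zeros(3))
    with pytest.raises(ValueError):
        ShapeParams(L_s=1.0, amplitudes=np.zeros((2, 2)))


def test_shape_json_roundtrip():
    text = EGG.to_json()
    back = ShapeParams.from_json(text)
    assert back.L_s == EGG.L_s
    np.testing.assert_array_equal(back.amplitudes, EGG.amplitudes)


def test_unit_sphere_profile_exact():
    g = build_profile(SPHERE, n_s=101)
    np.testing.assert_allclose(g.rho, np.sin(g.s), atol=1e-10)
    np.testing.assert_allclose(g.z, 1 - np.cos(g.s), atol=1e-10)
    assert abs(g.closure_defect) < 1e-10
    A, V, v = area_volume(g)
    assert A == pytest.approx(4 * np.pi, rel=1e-9)
    assert V == pytest.approx(4 * np.pi / 3, rel=1e-9)
    assert v == pytest.approx(1.0, abs=1e-9)


def test_sphere_radius_two_scaling():
    big = ShapeParams(L_s=2 * np.pi, amplitudes=np.zeros(4))
    g = build_profile(big, n_s=101)
    assert g.rho[g.n_s // 2] == pytest.approx(2.0, abs=1e-9)  # rho(L/2) = R
    assert g.reduced_volume == pytest.approx(1.0, abs=1e-9)
    C1, C2 = principal_curvatures(g)
    np.testing.assert_allclose(C1, 0.5, atol=1e-12)
    np.testing.assert_allclose(C2, 0.5, atol=1e-9)


def test_sphere_curvature_fields():
    g = build_profile(SPHERE, n_s=101)
    K, H, kg2, J = curvature_invariants(g)
    np.testing.assert_allclose(K, 1.0, atol=1e-8)
    np.testing.assert_allclose(H, 1.0, atol=1e-8)
    np.testing.assert_allclose(J, np.sin(g.s), atol=1e-10)
    eq = g.n_s // 2  # s = pi/2: the equator is a geodesic
    assert kg2[eq] == pytest.approx(0.0, abs=1e-12)


def test_perturbed_profile_matches_adaptive_quadrature():
    g = build_profile(EGG, n_s=51)
    for j in [7, 19, 33, 50]:
        rho_ref, _ = quad(lambda t: np.cos(EGG.theta(t)), 0, g.s[j],
                          epsabs=1e-12, limit=200)
        z_ref, _ = quad(lambda t: np.sin(EGG.theta(t)), 0, g.s[j],
                        epsabs=1e-12, limit=200)
        assert g.rho[j] == pytest.approx(rho_ref, abs=1e-8)
        assert g.z[j] == pytest.approx(z_ref, abs=1e-8)


def test_perturbed_area_volume_against_oracle():
    g = build_profile(EGG, n_s=101)
    A_ref, _ = quad(lambda t: 2 * np.pi * quad(
        lambda u: np.cos(EGG.theta(u)), 0, t, epsabs=1e-12)[0], 0, np.pi,
        epsabs=1e-10, limit=200)
    assert g.area == pytest.approx(A_ref, rel=1e-6)


def _general_formula_oracle(g):
    """K, 2H, kg2 via the generic surface-of-revolution formulas (FD route).

    The generic mean-curvature expression evaluates to ``-(C1 + C2)`` with
    this package's profile orientation (normal pointing the other way); the
    oracle returns it sign-flipped.
    """
    ds = g.s[1] - g.s[0]
    r1 = np.gradient(g.rho, ds, edge_order=2)
    z1 = np.gradient(g.z, ds, edge_order=2)
    r2 = np.gradient(r1, ds, edge_order=2)
    z2 = np.gradient(z1, ds, edge_order=2)
    gmet = r1**2 + z1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        K = -z1 * (z1 * r2 - z2 * r1) / (g.rho * gmet**2)
        H2 = -(g.rho * (z1 * r2 - z2 * r1) - z1 * gmet) / (g.rho * gmet**1.5)
        kg2 = r1 / (g.rho * np.sqrt(gmet))
    return K, H2, kg2


def test_curvature_identities_against_general_formulas():
    """K = C1*C2 and 2H = C1+C2 vs the generic (rho, z)-derivative route."""
    g = build_profile(EGG, n_s=401)
    K_o, H2_o, kg2_o = _general_formula_oracle(g)
    m = g.rho > 0.2  # FD oracle loses accuracy near the poles (1/rho terms)
    np.testing.assert_allclose((g.C1 * g.C2)[m], K_o[m], atol=1e-4)
    np.testing.assert_allclose((g.C1 + g.C2)[m], H2_o[m], atol=1e-4)
    np.testing.assert_allclose(g.kg2[m], kg2_o[m], atol=1e-4)


def test_c2_cross_check_via_gauss_route():
    """C2 agrees with K/C1 computed from the analytic series derivative."""
    g = build_profile(EGG, n_s=101)
    inner = slice(1, -1)
    np.testing.assert_allclose(g.C2[inner], (g.K / g.C1)[inner], atol=1e-6)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-0.25, 0.25), min_size=2, max_size=6))
def test_gauss_bonnet_and_identities_random_shapes(amps):
    shape = ShapeParams(L_s=np.pi, amplitudes=np.array(amps) + 1e-3)
    g = build_profile(shape, n_s=201)
    # Gauss-Bonnet for genus 0, regardless of closure in rho
    assert g.surface_integral(g.K) == pytest.approx(4 * np.pi, abs=1e-4)
    np.testing.assert_allclose(g.K, g.C1 * g.C2, atol=1e-12)
    np.testing.assert_allclose(2 * g.H, g.C1 + g.C2, atol=1e-12)


def test_scale_covariance():
    f = 1.7
    g1 = build_profile(EGG, n_s=201)
    g2 = build_profile(EGG.rescaled(f), n_s=201)
    assert g2.reduced_volume == pytest.approx(g1.reduced_volume, abs=1e-10)
    assert g2.area == pytest.approx(f**2 * g1.area, rel=1e-10)
    assert g2.volume == pytest.approx(f**3 * g1.volume, rel=1e-10)


def test_refinement_reduces_quadrature_error():
    coarse = abs(build_profile(EGG, n_s=51, oversample=1).area
                 - build_profile(EGG, n_s=401, oversample=16).area)
    fine = abs(build_profile(EGG, n_s=101, oversample=1).area
               - build_profile(EGG, n_s=401, oversample=16).area)
    assert fine < coarse / 4  # at least the composite-rule order


def test_open_profile_rejected_by_area_volume():
    open_shape = ShapeParams(L_s=np.pi, amplitudes=np.array([1.0]))
    g = build_profile(open_shape, n_s=101)
    assert abs(g.closure_defect) > 1e-3
    with pytest.raises(InvalidShapeError):
        area_volume(g)


def test_self_intersecting_profile_flagged():
    bad = ShapeParams(L_s=np.pi, amplitudes=np.array([0.0, 3.0]))
    g = build_profile(bad, n_s=201)
    assert not g.valid


def test_normalize_area():
    sh = normalize_area(EGG)
    assert build_profile(sh, n_s=201).area == pytest.approx(4 * np.pi,
                                                            rel=1e-9)


def test_build_profile_requires_three_nodes():
    with pytest.raises(ValueError):
        build_profile(SPHERE, n_s=2)
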