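# nemshell

Closed axisymmetric **nematic vesicles**: a hybrid Helfrich–Landau model of
fluid membranes with in-plane orientational order, built to study how
extrinsic (deviatoric) curvature elasticity stabilizes the biconcave
discocyte shape of red blood cells.

## Who this is for

The classic Helfrich bending model predicts stable discocytes only in a
narrow window of reduced volume, v ∈ [v₁ ≈ 0.59, v₂ ≈ 0.65], much narrower
than the experimentally observed range. If the membrane carries in-plane
nematic order (from lipid chains, anisotropic proteins or BAR domains), the
order couples to the curvature tensor and the competition between shapes
changes. `nemshell` implements this coupled model for membrane biophysicists
who want to compute equilibrium shapes, textures, topological defects and
stability diagrams of such vesicles.

## The model

A shape is a surface of revolution encoded by the tangent angle of its
meridian, θ(s) = πs/L_s + Σᵢ aᵢ sin(πis/L_s), with area fixed to 4π
(lengths in units of R = √(A/4π)). The in-plane order is a scaled 2-D
tensor Q = q₁(e₁⊗e₁ − e₂⊗e₂) + q₂(e₁⊗e₂ + e₂⊗e₁) on the (s, φ) grid.
The dimensionless free-energy density (units of the intrinsic elastic
constant k_i) is

    f = ½ (κ/k_i) (C₁+C₂)²
      + λ₀² [ (R/ξ)² g_c + ½ g_int + μ g_ext ],      μ = (k_e/k_i)/λ₀

with condensation g_c = −2λ² + λ⁴, the full embedded gradient
g_int = |∇_s Q|² (covariant part plus the fossil term λ²(C₁²+C₂²)), and the
deviatoric coupling g_ext = q₁(C₁²−C₂²). Equilibria are found by
alternating Metropolis Monte-Carlo relaxation of (q₁, q₂) with constrained
(volume + closure) minimization of the Fourier amplitudes.

Geometry-only *curvature potentials* predict where topological defects go
without solving for the texture: w_int = C₁²+C₂², w_ext^min = −|C₁²−C₂²|,
w_t = ½w_int + μ w_ext^min.

## Worked example

Four +1/2 defects on a sphere — the nematic ground state on a spherical
vesicle:

```python
import numpy as np
from nemshell import (ModelParams, MCSchedule, ShapeParams, NematicTexture,
                      build_profile, mc_relax_texture, locate_defects)

p = ModelParams(v=1.0, n_s=61, n_phi=61)         # R/xi = 7, lambda0 = 1/2
sphere = ShapeParams(L_s=np.pi, amplitudes=np.zeros(20))
tex0 = NematicTexture.random(61, 61, np.random.default_rng(0))
tex = mc_relax_texture(sphere, tex0, p, MCSchedule(seed=0))
grid = build_profile(sphere, n_s=61, staggered=True)
census = locate_defects(tex, grid)
print(len(census.defects), sorted(round(d.m, 2) for d in census.defects),
      round(census.total_charge, 2))
```

prints

```
4 [0.5, 0.5, 0.5, 0.5] 2.0
```

— four half-charge defects whose winding numbers sum to +2, as required by
the Poincaré–Hopf theorem on a genus-0 surface. The bending-only phase
boundary is one call: `find_v2(p, 0.60, 0.70, mode="bending")` returns
≈ 0.653, the classic oblate–prolate crossing.

A command-line interface mirrors the library
(`nemshell relax|potentials|defects|phase-scan|fixtures`).

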