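# Methods

## Model

A vesicle is a closed axisymmetric fluid sheet of genus 0. Its meridian is
described by the tangent angle θ(s) on arc length s ∈ [0, L_s], expanded as
a linear ramp plus a sine series (N modes); ρ(s) and z(s) follow by
quadrature, so s is exact arc length and the first fundamental form is
diagonal with G = 1, J = ρ. Principal curvatures are C₁ = θ′(s) along
meridians (analytic from the series) and C₂ = sin θ/ρ along parallels, with
the smooth-pole limit C₂ → C₁. Closure ρ(L_s) = 0 is an optimization
constraint, never assumed.

In-plane order is a 2-D nematic tensor, scaled by the bulk equilibrium
order parameter λ₀ so its amplitude is 1 in a flat ordered membrane. The
dimensionless free energy per unit area (units of k_i, lengths in R) is

f = ½ (κ/k_i)(C₁+C₂)² + λ₀²[(R/ξ)² g_c + ½ g_int + μ g_ext],

with g_c = −2λ² + λ⁴, g_ext = q₁(C₁²−C₂²), μ = (k_e/k_i)/λ₀, and g_int the
squared surface gradient of the *embedded* tensor. In the principal frame

g_int = (∂_s q₁)² + (∂_s q₂)² + (D_φ q₁)² + (D_φ q₂)² + λ²(C₁²+C₂²),

where D_φ carries the spin-2 connection 2κ_g2 = 2cosθ/ρ (rotation of the
frame along parallels) and the last term is the normal-production ("fossil")
energy: a locally parallel-transported unit-amplitude field carries exactly
C₁²+C₂². Tensor norms use |A|² = ½A_ijA_ij; with the full Frobenius norm
every nematic elastic term doubles and no shape ranking changes, but the
½ convention is what makes the fossil density literally C₁²+C₂², the
anchor identity verified against a brute-force Cartesian-embedding oracle
in the tests.

The bending density uses the spontaneous-curvature-free form (C₁+C₂)².
The Tr C² variant differs by 2K, whose surface integral is the Gauss–Bonnet
constant 8π at fixed topology, so the choice cannot reorder shapes; this is
also tested. The Gaussian (saddle-splay) modulus is omitted for the same
reason, and there is no spontaneous curvature or area-difference
elasticity.

## Parameters

| parameter | meaning | default |
|---|---|---|
| κ/k_i | bending vs intrinsic nematic stiffness | 1.0 |
| k_e/k_i | extrinsic (deviatoric) vs intrinsic stiffness | 0 |
| λ₀ | equilibrium order parameter ∈ (0, ½] | ½ |
| R/ξ | vesicle size over nematic correlation length | 7 |
| v | target reduced volume | — |
| N, n_s, n_φ | Fourier modes, meridian nodes, azimuthal nodes | 30, 101, 101 |

R/ξ = 7 and λ₀ = ½ are the reference conditions of the study this model
implements; the 101×101 grid is the reference texture lattice. λ₀ enters
both as the λ₀² prefactor and inside μ, taken literally.

## Discretization and numerics

*Geometry.* Profiles are integrated by composite Simpson quadrature on a
16× oversampled uniform fine grid (error ~10⁻¹¹ at default sizes) and
sampled on n_s nodes. Texture grids are staggered half a cell from the
poles, where the principal frame (and hence q₁, q₂) is not single-valued;
pole cells are suppressed by the J → 0 area weight, and no lattice link
crosses a pole.

*Lattice energy.* For Monte Carlo the gradient term is discretized on
links: plain differences along meridians (geodesics, no frame rotation) and
rotation-corrected differences R(2δ)q_{k+1} − q_k with δ = cosθ·Δφ along
parallels. The vectorized total energy and the sampler's local ΔE evaluate
one and the same functional. Per-node centred-difference densities are kept
for analysis output only.

*Monte Carlo.* Single-site Gaussian proposals on (q₁, q₂); width auto-tuned
to ≈40% acceptance while annealed. The temperature ladder is geometric,
5.0·0.72^k (k = 0…18) then 0, in units of the mean condensation energy per
cell so it is resolution independent; 150 sweeps per stage. The final stage
is a strict quench (only non-increasing moves) during which the proposal
width is shrunk geometrically to polish the minimum. The slow ladder is
what lets defect–antidefect pairs annihilate; a faster one freezes textures
with spurious pairs. All randomness flows from one recorded seed;
identical seeds give bit-identical runs.

*Shape minimization.* Because the dimensionless model fixes A = 4π, the
profile length is rescaled analytically to the target area at every
evaluation and the optimizer (SLSQP) works on the amplitudes alone, with
two equality constraints: reduced volume and closure. Up-down-symmetric
branches (prolate, oblate) are restricted to even modes — odd modes break
the mirror symmetry and are reserved for the stomatocyte branch.
Self-intersecting trials (ρ < 0) are rejected through a smooth penalty. A
feasible iterate with a finite energy is accepted even when SLSQP stops at
its iteration cap near a flat optimum.

*Branch seeding.* Prolate/oblate seeds are spheroids fitted in θ(s) with
the aspect ratio solved for the target v. The stomatocyte seed is a
three-arc cup (outer sphere, rim fold of radius 0.15, inverted inner cap of
half-angle 1.5) whose opening angle is solved for the target v; its branch
energy plateaus near twice the sphere bending energy, as expected for
deeply invaginated shapes.

*Defect census.* Cores are connected regions with λ < 0.4 (between the
melted core and the bulk value 1). Interior cores get the winding of a
surrounding lattice loop with increments lifted to (−π/2, π/2]; physical
charges are measured in the outward orientation (the chart frame normal
points inward, so chart loops are traversed reversed). The meridian frame
carries index +1 at each pole, so polar caps contribute 1 ± w_ring. Cores
whose amplitude fails to melt below threshold are recovered by a
latitude-ring winding scan, which closes the total charge to +2 exactly on
any texture whose clean rings exist.

*Phase boundaries.* Branch energies are best-of-restarts (hybrid mode) or
deterministic minimizations (bending mode); the crossing is bisected to
tol_v = 0.01 with warm-start continuation of each branch's shape along the
scan.

## Problem sizes used in tests and the acceptance script

The shipped tests and `scripts/acceptance.py` run at a desk scale chosen
for convergence per cost: N = 20 modes, 61×61 grid, ≤3 restarts. At this
scale the bending-limit boundaries reproduce the classic values
(v₂ ≈ 0.653, v₁ ≈ 0.591, both ±0.02), and mode-refinement checks (N = 40,
121 nodes) shift branch energies by ≲0.015 in units of 8πκ near the
crossing.

## What the hybrid pipeline does and does not show at desk scale

With κ = k_i/1.4, k_e = k_i/2 (μ = 1) the pipeline reproduces the
qualitative texture phenomenology: the discocyte's equatorial rim band
orders strongly and aligns with the soft principal direction (mean
alignment 0.98), and its four +1/2 defects are expelled from the equator to
the secondary maxima of w_t(s) — while at k_e = 0 they sit on the equator
at the w_t maximum. The quantitative broadening of the oblate stability
window is however resolution sensitive: at 61×61/N = 20 the co-optimized
prolate branch elongates, collects comparable extrinsic energy along its
body and parks its topological charge at the slender tips, keeping
F_prolate below F_oblate at v = 0.76. In the dimensionless model both
branches' high-curvature features carry the same net elastic rate — per
unit of ∮(1/r²)dA a thin feature of radius r costs ½·(κ/k_i) = 0.357 in
bending plus λ₀²/4 = 0.125 in fossil energy against an extrinsic gain of
λ₀²μ = 0.25 (at κ = k_i/1.4, μ = 1) — so the branch competition is delicate and
converges slowly with the texture lattice; resolving the reported
wide-window crossing requires the reference 101×101 lattice with long,
well-restarted relaxations (hours of compute), which the shipped tests do
not attempt.

## Known limitations

- Axisymmetric shapes only; the texture is fully 2-D but the geometry is
  not, so non-axisymmetric shape instabilities are invisible.
- No membrane-skeleton shear elasticity (no echinocytes), no thermal shape
  fluctuations, no bilayer/area-difference refinements, no hexatic order.
- The stomatocyte branch is used in pure-bending mode only; deeply
  invaginated shapes past self-contact are outside the representation.
- Azimuthal defect positions are not predicted by the curvature potentials
  (they are functions of s only), and defect positions from MC carry
  restart-to-restart scatter of order the defect-interaction scale.
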