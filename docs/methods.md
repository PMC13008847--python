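# Methods

## Problem setting

Plasma leaves a tumor microvessel through sub-micron fenestrae and spreads
into an extracellular matrix (ECM) so densely packed with fiber bundles that
forward pressure-driven perfusion is strongly suppressed. `radtme` models
this transport regime with a reduced-order *reverse advection–diffusion*
(RAD) surrogate and provides the surrounding analysis stack: fiber/fenestra
geometry generation, occupied/wetted-area kinetics, paired perfusion
effect-size statistics, blood-rheology and electrohydrodynamic (EHD)
closures, and image-derived metrics.

"Reverse" is a statement about the targeted transport regime — net
progression biased against the forward Darcy expectation because of
geometric obstruction and elevated interstitial pressure — not about the
mathematics: the governing equation is the ordinary linear scalar transport
equation

    ∂c/∂t + ω·∇c − D ∇²c = 0

with effective diffusivity `D` and a spatially uniform, phenomenological
advection `ω` normal to the fenestra.

## Geometry generation

The ECM is a rectangle (default 10 × 5 μm², origin at the lower-left,
units μm) perforated by non-overlapping circular fibers. Packings are
realised by random sequential addition (RSA): candidate centers are drawn
uniformly over the interior region admitting the candidate radius plus a
wall gap and rejected on overlap. Fibers are kept fully interior so the
packing fraction φ = Σπr²/A_dom is exact and every fiber is a closed
boundary loop for meshing. For a target φ with `n` equal fibers the radius
is `r = sqrt(φ A_dom / (n π))`; for φ = 0.30 with 40 fibers in 10 × 5 μm²
this gives r ≈ 0.345 μm. A realized packing outside φ ± 0.002 is reported
as a failed placement. The default inter-fiber gap of 0.02 μm prevents mesh
degeneracy between near-touching fibers and is configurable.

Fenestra ensembles place one aperture center per model, evenly spaced over
the vessel length minus two clearance zones: with N = 15 over a 500 μm
vessel and 25 μm clearances, centers run 25 … 475 μm in steps of
ΔL = 450/14 ≈ 32.1429 μm. The near-wall closure length `a_fen = 0.1 μm`
is a reported characteristic scale with no accompanying closure formula
and is recorded as metadata only.

## RAD discretisation

* **Mesh.** Points are laid along the outer rectangle (with the fenestral
  aperture sampled at ≤ width/4), along each fiber circle, on an offset
  guard ring around each circle (improves boundary-element quality), and on
  an interior hexagonal lattice of pitch `h`; a Delaunay triangulation of
  the union is pruned of triangles whose centroid lies inside a fiber.
  Boundary edges (edges owned by one triangle) are tagged inlet / outer /
  fiber; loops are counted by union–find and equal `n_fibers + 1`.
* **Elements.** Piecewise-linear (P1) triangles. Diffusion uses the exact
  stiffness matrix; for a Delaunay triangulation this is an M-matrix, which
  underwrites the discrete maximum principle. Mass is lumped (row-sum),
  avoiding the early-time oscillations of the consistent mass matrix.
* **Advection.** Standard Galerkin, with streamline-upwind Petrov–Galerkin
  (SUPG) stabilisation available per element; the `auto` policy engages it
  only where the cell Péclet number ω h_e / 2D exceeds 2. At the default
  parameters (D = 1270 μm²/s, ω_y ≈ 34 μm/s, h = 0.08 μm) the cell Péclet
  is ~10⁻³ and SUPG never engages.
* **Time stepping.** Backward Euler with a constant step, factorised once
  (sparse LU) and back-substituted per step; unconditionally stable. The
  default is 2000 steps over the simulated window (Δt = 10⁻⁴ s for the
  reference run), matching the step convention of the CFD it surrogates. The inlet holds c = c_in (Dirichlet) for t > 0 from a zero
  initial condition; all other boundaries, including fiber surfaces, are
  natural zero-flux.
* **Normalisation.** The equation is linear, so the solver works on
  C̃ = c/c_in and rescales on output; the nominal c_in = 8×10¹³ (model
  units) is accepted for fidelity but cannot affect normalised results.
* **Occupied area.** A(t) is the area where C̃ > θ, computed exactly per
  element from the linear interpolant (case analysis on the sorted vertex
  values), not by counting elements. θ defaults to 0.05; the two-regime
  conclusion is insensitive to θ across [0.01, 0.2] (tested).

### Parameter choices for the reference run

When the surrogate is calibrated against vessel-scale CFD, ω_y is the
ensemble average of fenestral entry-velocity magnitudes; no such value is
tabulated here, so the package default, ω_y = 34.3 μm/s, adopts the
domain-averaged plasma velocity scale of the vessel mesh-refinement study
(3.43 × 10⁻⁵ m/s, stored in the closures registry) as the nearest
available stand-in. With D = 1270 μm²/s
the 10 × 5 μm² domain saturates in ~0.02 s, so the reference run simulates
0.2 s in 2000 implicit steps with ~50 log-spaced snapshots; the
steep-then-shallow two-regime log–log shape of A(t) is the reproducible
observable, while the absolute transition time depends on the particular
fiber arrangement and advection magnitude and is not asserted.

### Verification

The solver is checked against the 1D semi-infinite closed form
c/c_in = erfc(y / 2√(Dt)) (full-width inlet, no fibers, no advection),
agreeing within 2% (measured ≈0.2% at h = 0.1); linearity in c_in holds to
solver tolerance; the discrete maximum principle holds to 10⁻⁸·c_in on the
reference fibered run; mirror symmetry is exact against a reflected-mesh
solve; and A(t_end) changes by ~1% when h is halved.

## Kinetics

Power-law growth A = 10^b t^m is fitted by OLS on (log₁₀ t, log₁₀ A) using
the textbook normal-equation formulas; the two-segment fit scans every
admissible split (minimum 3 points per segment, since R² is uninformative
below that), fits both sides independently (unconstrained, possibly
discontinuous), and keeps the split minimising the total RSS. The
breakpoint is reported at the geometric mean of the two straddling sample
times — the natural midpoint on a log axis; no standard fixes the
estimator convention, so this one is documented and kept. A single-regime
record leaves the RSS indifferent to the split; the earliest admissible
split is returned flagged `degenerate` rather than raising, because regime
order can invert in experiments and slopes are reported without enforcing
m₁ > m₂.

Temporal calibration between two model variants is the single stretch
k = t*_slow / t*_fast applied to the time axis. The experiment–model
reconciliation compares post-transition windows: ratio
(t_exp_end − t*_exp)/t*_CFD ≈ 509 for the reference inputs (120 s, 4.1 s,
0.2277 s), interpreted through thin-layer mass conservation Q = εH dA/dt as
a thickness ratio, giving an effective 2D thickness h_eff = H_exp/ratio
(≈ 15 μm from H_exp = 7.5 mm). The same ratio rescales model time and area
(f_t = f_a = ratio by construction); the residual curve is
log₁₀(A_exp / (A_model · f_a)) with the rescaled model series interpolated
in log–log space.

## Perfusion statistics

All effect sizes operate on dimensionless intensities S ∈ [0, 1]. Cohen's d
uses the pooled n−1 standard deviation. The probability of superiority
(AUC) counts ties as ½ — the standard probability-of-superiority
convention —
and is computed by the rank (Mann–Whitney) formulation; Cliff's
δ = 2·AUC − 1. The Hodges–Lehmann shift is, by default, the median of the
elementwise paired differences; the classical
cross-pair median is available via `method="cross"`. Exceedance curves use
the strict inequality E(τ) = #{S > τ}/N. The area between two curves is
integrated exactly as a step function over the pooled breakpoint grid; for
bounded samples this equals the difference of sample means (the
survival-expectation identity), which the tests verify to 10⁻¹².

The ensemble summary takes one paired mean per model: grand means, their
difference Δ, a percentile bootstrap CI on the mean paired difference
(model-level resampling, B = 10⁴ default, seeded), the exact two-sided
Wilcoxon signed-rank p (zeros dropped; all-positive differences over 15
models give p = 2/2¹⁵ ≈ 6.1×10⁻⁵), and the relative gain 100·Δ/grand-mean
of the baseline. An all-zero difference vector is flagged degenerate with
p = 1 rather than raising.

## Closure evaluators

The Carreau–Yasuda blood viscosity is evaluated as
η = η_plasma · a(α_r) · (1 + (τγ̇)²)^((b−1)/2) with τ = 0.110 s and cubic
polynomial coefficients in hematocrit α_r; a and b are dimensionless, so
the expression is read as the suspension viscosity in multiples of the
baseline plasma viscosity (0.001 Pa·s) — no separate constant RBC viscosity
exists in this reading, though a literal three-term weighted-sum policy is
available with a caller-supplied η_RBC. Below 6 s⁻¹ the Yasuda branch uses
k = ln(ln γ̇)/ln γ̇ and b = 1 + k·poly(α_r), i.e. (b−1)/k equals the
hematocrit polynomial (a b^(−1/k) reading would differ but is rejected as
dimensionally incoherent with the Carreau exponent). Since k is undefined
for γ̇ ≤ 1, the evaluator falls back to the high-shear coefficient set
there — which has the correct Newtonian plateau limit — and warns; clamping
γ̇ instead would make b diverge like ln ln γ̇ and overflow the viscosity.

The RBC shape factor is ξ = 1.5·(1 + (τγ̇)²)^0.058697 up to 300 s⁻¹ and 1
above — continuous below the cutoff with a single jump at 300 s⁻¹. The Kelvin force is f = ρ_e E − ½∇ε‖E‖², reducing to ρ_e E for
uniform permittivity; the phase-aggregated wall force adds the
zeta-potential term ζ ε₀ ε_r E componentwise. No electrostatic Poisson
solve is performed — fields and charge densities are caller-supplied.
Phase-fraction validation (each α ∈ [0,1], Σα = 1 within 10⁻¹²) returns a
structured report and never raises. A parameter registry carries every
material/electrical constant and the vessel mesh-refinement study table.

## Imaging

Pixel classification uses HSV hue bands — red [0°,20°)∪[340°,360°),
green+yellow [40°,160°), blue [190°,260°) — with white pores split off
first (value > 0.9, saturation < 0.1) and a catch-all "other" class, so
counts always partition the frame. Contour palettes vary between tools,
so the bands are config-overridable and all tests use
palette-pure synthetic frames. Occupancy ratios normalise blue to 1 with
white excluded. Wetted-area binarisation marks a pixel as dye-covered when
red exceeds max(green, blue) by a byte-level threshold (default 50),
matching red dye on a white background; areas scale by pixel_scale². The
colorbar LUT inversion for intensities is nearest-neighbor and flagged
approximate: it is exact only for frames whose colors appear in the LUT.

## Synthetic data

Generators emulate each consumed input with known ground truth. Intensity
samples are beta-distributed (bounded support matches S ∈ [0,1]),
reparameterised by (mean, sd), then affinely contracted about the target
mean so the sample mean is exact to machine precision without clipping —
this is what makes the ABC identity reproduce 0.125 exactly from means
0.650/0.525. Piecewise power-law series are continuous at t* (b₂ = b₁ +
(m₁−m₂)log₁₀ t*) even though the fitter is unconstrained, with optional
lognormal noise. Model ensembles add a common condition effect plus
model-level Gaussian jitter. Frame generators emit palette-pure blocks
with exact counts and growing red disks (r = √(g t), so area slope 1 on
log–log axes). All generators are bit-reproducible under a fixed seed and
return their parameters as a manifest.

What the generators deliberately do **not** emulate: spatially correlated
CFD concentration fields, camera noise and mixed-palette antialiasing in
frames, or inter-model correlation structure in ensembles. Passing tests
therefore demonstrate correctness of the estimators and solvers under the
stated generating laws, not robustness to real-image artefacts.

## Problem sizes

The default verification suite runs the reference 40-fiber transport
configuration once at h = 0.08 μm (~14k elements, 2000 implicit steps,
a few seconds), the erfc benchmark at h = 0.1 μm, and statistics at
n = 10³–10⁴ samples with B ≤ 4×10³ bootstrap replicates — sizes chosen so
the full suite completes in well under a minute while keeping every
tolerance meaningful.

## Known limitations

* The surrogate is 2D, with uniform ω and equal-radius fibers; no momentum
  or pressure fields, no multiphase front tracking.
* Mesh quality in narrow inter-fiber gaps (< h) relies on Delaunay slivers
  that a constrained mesher would avoid; the direct sparse solver is
  indifferent, but gradient accuracy in those gaps is reduced.
* The maximum principle is inherited from the Delaunay M-matrix property
  for pure diffusion; strong advection (cell Péclet ≫ 2) is only
  stabilised, not bound-preserving, and is reported via a warning when
  bounds are violated beyond 10⁻⁸.
* Hue-band classification and LUT inversion are approximations for real
  imagery; they are exact only on palette-pure frames.
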