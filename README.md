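# radtme

Reduced-order modelling and analysis of plasma transport in the tumor
microenvironment: a **reverse advection–diffusion (RAD)** finite-element
surrogate on fiber-obstructed extracellular-matrix (ECM) domains, together
with the full analysis stack used around such simulations — fiber/fenestra
geometry generation, occupied/wetted-area kinetics with two-segment
breakpoint regression and experiment-to-model scaling reconciliation,
paired perfusion effect-size statistics, blood-rheology and
electrohydrodynamic (EHD) closure evaluators, and image-derived metrics.

**Who it is for.** Computational biophysicists studying interstitial
transport in dense tumor stroma who need a fast, scriptable surrogate for
plasma ingress through a fenestra and reproducible implementations of the
accompanying kinetics/statistics pipeline.

## The model

Plasma-borne solute concentration `c(x, y, t)` on a rectangular ECM domain
perforated by impermeable circular fibers obeys

```
∂c/∂t + ω·∇c − D ∇²c = 0
```

with effective diffusivity `D`, a spatially uniform advection
`ω = (0, ω_y)` normal to the fenestra, a constant Dirichlet inlet
`c = c_in` on the sub-micron fenestral aperture, zero-flux conditions on
all other boundaries (including every fiber surface), and `c(x, y, 0) = 0`.
"Reverse" names the transport regime the surrogate targets — progression
biased against the forward Darcy-perfusion expectation in obstructed,
high-pressure stroma — not a sign change in the physics. The solver uses P1
finite elements on a Delaunay triangulation with fiber interiors carved
out, lumped mass, backward-Euler stepping and optional SUPG stabilisation.

The occupied interstitial area `A(t) = |{c/c_in > θ}|` is the headline
observable. On log–log axes it follows `A = 10^b t^m` piecewise: a steep
advection-driven regime then a shallow diffusion-limited regime, separated
by a breakpoint `t*` found by an unconstrained two-segment least-squares
fit. Paired perfusion gains between EHD-forced and baseline conditions are
summarised by Cohen's *d*, the probability of superiority (AUC), Cliff's
δ = 2·AUC − 1, the Hodges–Lehmann shift, exceedance curves
`E(τ) = P(S > τ)` and the area between them (ABC), which for intensities
bounded in [0, 1] equals the difference of sample means.

## Worked example

```python
import numpy as np
from radtme import *
from radtme.kinetics import two_segment_breakpoint

# 40 equal fibers filling 30% of a 10 x 5 um^2 ECM domain
dom = RectDomain(10.0, 5.0)
r = fiber_radius_for_packing(0.30, dom, 40)
field = generate_fiber_field(dom, 40, r, min_gap=0.02, seed=1, target_phi=0.30)
print(f"fiber radius: {r:.4f} um, realized phi: {packing_fraction(field):.4f}")

# transport solve through a 0.3 um fenestra
mesh = build_mesh(field, FenestraSpec(0.3, "bottom", 5.0), h=0.08)
steps = np.unique(np.round(np.geomspace(1, 2000, 50)).astype(int))
params = RADParams(diffusivity=1270.0, omega=(0.0, 34.3),
                   inlet_concentration=8.0e13, t_end=0.2, n_steps=2000,
                   output_times=steps * 1e-4)
fields = solve_rad(mesh, params)
series = occupied_area_series(fields, 0.05)
bp = two_segment_breakpoint(series)
print(f"t* = {bp.t_star:.4f} s, m_adv = {bp.advection_fit.slope:.2f}, "
      f"m_diff = {bp.diffusion_fit.slope:.3f}")
```

prints

```
fiber radius: 0.3455 um, realized phi: 0.3000
t* = 0.0061 s, m_adv = 0.91, m_diff = 0.008
```

i.e. the packing generator hits the 30% target exactly with r ≈ 0.345 μm,
and the occupied area grows steeply (slope ≈ 0.9) until the advection-driven
plume spans the pore space, then nearly saturates (slope ≈ 0.01) in the
diffusion-limited regime — the characteristic two-regime kinetics of
fenestral plasma ingress. A statistics one-liner on synthetic ROI
intensities with means 0.650 (EHD) and 0.525 (non-EHD):

```python
from radtme.synthetic import gen_intensity_pair
from radtme.perfstats import compare
a, b, _ = gen_intensity_pair(0.650, 0.525, 0.06, 10_000, seed=1)
rep = compare(a, b, taus=(0.7,))
print(f"ABC = {rep.abc:.3f}, Cohen d = {rep.cohen_d:.2f}")
# ABC = 0.125, Cohen d = 2.08
```

The ABC equals the mean gap 0.125 exactly — the survival-integral identity
for bounded intensities.

A command-line interface mirrors the library:

```
radtme geometry --domain 10x5 --n 40 --phi 0.30 --seed 1 --out field.csv
radtme run --preset paper --seed 1 --out runs/
radtme kinetics reconcile --t-exp-end 120 --t-star-exp 4.1 \
       --t-star-cfd 0.2277 --h-exp 7500
```

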