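# Methods

## Model structure

`aridpatch` couples two formalisms on a square plot of nx × ny soil
parcels (side Δx, default 4 m):

* **Continuous dynamics** — each parcel carries surface water O and
  soil water W (mm); each plant carries a biomass B (g). Within one
  event step (Δt = 0.2 d) the water fields and all plant biomasses form
  a single ODE system advanced by classical RK4 with shared substeps;
  parcel biomass totals are refreshed at every RK4 stage, so plants and
  water never see stale state ("coupled" mode). A cheaper "split" mode
  (plants integrate against frozen water, then water against frozen
  biomass) exists for comparison and agrees with the coupled mode to
  within 1% on deterministic scenarios (tested).
* **Discrete events** — after each continuous block, seed dispersal,
  seedling establishment, stochastic death and ageing occur as
  per-plant random draws (seeds attempted in randomized order).

State is stored structure-of-arrays (`Population`), and the coupled
integrator is a numba kernel; the NumPy implementations in
`hydrology`/`metabolism` define the reference semantics and the test
suite checks the kernel against them and against fine-step explicit
integration.

## Water equations and their two readings

The water dynamics follow the grid ecohydrology tradition
(infiltration enhanced by vegetation, Michaelis–Menten uptake, linear
evaporation/drainage, Laplacian exchange between parcels). Two details
of the published formulation are ambiguous, and both are exposed as
switches rather than silently resolved:

1. **Biomass units in the water equations**
   (`biomass_density_coupling`, default on). Plants draw a water
   *volume* proportional to biomass; a parcel's depth therefore changes
   by the summed volume divided by the parcel area, i.e. the water
   equations see the biomass *density* P = ΣB/Δx² (g·m⁻²), exactly as
   in the parent vegetation-pattern models where k₂ and K_a are
   per-m² constants. The alternative (raw per-parcel gram totals in
   place of P) is provably inconsistent with the reference biomass
   densities this model is known to produce: with per-parcel totals,
   plot-total uptake at any soil-water level that lets plants persist
   (W ≥ 4.5 mm) would exceed total rainfall whenever standing biomass
   exceeds ≈2.4 g·m⁻² at 1.3 mm/day — far below the reported standing
   crops. At Δx = 1 m the two readings coincide; the hand-calculable
   examples in the tests use that geometry.
2. **Infiltration denominator**
   (`infiltration_literal_denominator`, default on). The flux is
   α·O·(P + k₂W₀)/(W + k₂) as printed in the source formulation:
   infiltration strengthens with vegetation *and* with local soil-water
   deficit. The saturating variant α·O·(P + k₂W₀)/(P + k₂), used by the
   models this one adapts, is available; it is bounded by α·O and makes
   the conventional bare-soil initialization O = R/(αW₀), W = R/r_w an
   exact equilibrium (verified to machine precision over 200 simulated
   days). The default (literal) variant treats those values purely as
   the initial condition. The literal variant is the default because it
   is what sustains the emblematic behaviour: under the saturating
   form, a spatially uniform "seedling soup" (soil water pinned at the
   seedling-neutral level W* = k₁d/(bg_max − d) = 4.5 mm, all plants
   tiny) is linearly stable against all wavelengths at rainfall
   ≥ 0.9 mm/day (dispersion analysis of the three-field mean-field
   system; the same analysis applied to the parent parameterization
   reproduces its known ~50 m Turing band, validating the method), and
   simulations duly converge to that soup instead of patterning. The
   literal term makes vegetated parcels strong water sinks, keeps
   inter-patch soil dry, and produces the spots → labyrinth → cover
   sequence along the rainfall gradient.

Boundary conditions are zero-flux by default (closed hydrological
unit; mass conservation is tested), periodic optionally. States are
clamped non-negative after each substep and clamps are counted
(`SimOutput.n_clamped`).

## Plants

Growth: dB/dt = B·b·g_max·(1 − B/K_p)·W/(W + k₁) − d·B, reading W from
the plant's own parcel only (no multi-parcel rooting). The size factor
caps growth but not water draw, preserving the asymmetry of the source
formulation. With saturating water the equilibrium is
K_p(1 − d/(bg_max)) = 320 g; at realistic parcel water (~7 mm) the
effective ceiling is ≈120 g.

Reproduction: expected seeds per step = B·s·f(m)·Δt with the maturity
factor f(m) = l/m for m > 0 and f(0) = 1 (the printed l/m form is
singular at the default m = 0; the chosen convention keeps lifetime
fecundity roughly constant as maturity is delayed, and the l/m = 365
alternative at m = 0 would imply seed rains orders of magnitude beyond
anything the reported population sizes could absorb). Expectations
above one are split into a deterministic floor plus a Bernoulli
remainder. Dispersal is isotropic with lognormal distances
parameterized by the *mean* μ (location = ln μ − σ²/2); seeds crossing
the plot edge are lost. Establishment (1 g, age 0) is blocked when the
target parcel's biomass density exceeds K_a; by default seedlings may
establish where they cannot currently grow ("doomed seedlings") — the
`preemptive_seedling_removal` shortcut that rejects them is off because
it biases pattern formation.

Death: once B/B_max < d_b, daily probability 1 − B/(d_b·B_max)
("graded", default; an "abrupt" variant 1 − (B/B_max)·d_b reflecting an
alternative literal reading is provided), converted to the event step
via complement exponentiation so probabilities stay in [0,1]. Age
mortality is a constant hazard with exact mean lifetime l
(p_step = 1 − e^(−Δt/l)); a hard cutoff at l is available, and the
hazard can be disabled from a given time (`age_mortality_off_after`),
as the shift experiment requires.

## Parameters

Defaults (SimConfig) are the standard calibration: b = 10 g·mm⁻¹·m²,
g_max = 0.05, k₁ = 3 mm, K_p = 800 g, d = 0.3 d⁻¹, l = 365 d,
d_b = 0.8, m = 0 d, s = 0.002 seeds·g⁻¹·d⁻¹, μ = 10 m, σ = 1.5,
K_a = 30 g·m⁻², α = 0.1, k₂ = 5, W₀ = 0.15, r_w = 0.1 d⁻¹,
D_O = 10 m²·d⁻¹, D_W = 0.01 m²·d⁻¹, Δx = 4 m, Δt = 0.2 d. Rainfall R
is constant, step-shifted, or sinusoidal (rejected if it would go
negative).

Integration substep: SimConfig defaults to dt_int = 0.02 d;
the experiment presets use 0.04 d, which reproduces the 0.02 d
trajectories to within the convergence tolerances of the test suite
(and bit-identical demographic outcomes in spot checks) at half the
cost. The RK4/fine-Euler oracle agreement and step-halving convergence
are tested explicitly.

## Initial conditions

Water starts at O = R/(αW₀), W = R/r_w on every parcel. Founders get
biomass ~ Uniform[1, 2] g (overridably fixed at 1 g) and integer ages
uniform on [1, l]. "Aggregated" placement packs plants round-robin into
n_patches contiguous patches whose combined footprint is ⌈1% of
parcels⌉; "random" scatters them uniformly. One root seed spawns
independent child streams for initialization and lifecycle events, so
the event stream does not shift when initialization consumes more or
less randomness.

## Experiments and problem sizes

* `exp1a` (patterns): 400 × 400 m, 1000 founders, s = 0.002. The full
  design runs 10 years; the figures and the packaged checks use 5-year
  states. Acceptance-grade checks run at half linear scale
  (200 × 200 m, 250 founders), one run per rainfall level.
* `exp1a-demography`: 200 × 200 m, 250 founders in 25 patches,
  s = 0.001, 5 years; 5 replicate seeds per rainfall level.
* `exp1b` (trait sweep): demographic design with μ (or m) varied;
  5 replicates per value here (the full design used 70).
* `exp2a` (shift): 200 × 200 m, 250 founders, R = 1.3 until day 1500
  then 0.8, age mortality off after the shift, assessed 365 d later;
  5 replicates (the full design used 100). Pre/post IP and ICS use 4 m
  quadrats — the original analysis tool's quadrat size is unstated, so
  absolute index values are comparable only in order of magnitude.
* `exp2b` (seasonality): 200 × 200 m, 12 years, sinusoid
  R = 1.3 + A·sin(2πt/365); statistics over the last 4 years; checks
  run at half scale with 3 replicates (full design 100).
* `ring`: qualitative scenario (50 × 50 m, Δx = 1 m, μ = 5 m, rainfall
  oscillating 1.0–1.6 mm/day) provided as a preset only.

Replicate seeds derive from one root seed via `SeedSequence`; results
are independent of execution order.

## What the checks do and do not show

The synthetic experiments emulate the study conditions (founder
layouts, rainfall regimes, horizons) but not real field data: there is
no rainfall intermittency, soil heterogeneity, grazing, or
interspecific structure, so green checks demonstrate internal
consistency and qualitative agreement with the reference behaviour,
not field realism. Known quantitative gaps, measured and left open
rather than tuned away: replicate-mean plant biomass in the
demographic preset is high (~120 g vs the reference 45.4 g at
0.9 mm/day) and roughly flat across rainfall — our patch parcels
equilibrate wetter (~8 mm) than the reference state implies (~5–6.6 mm),
so adults grow larger and sparser; pre-shift cluster size is likewise
lower than reported (ICS ~6 vs 16), which flips the sign of the ICS
change across the shift; the trait-sweep ICS declines monotonically
with dispersal distance instead of peaking near 20 m; and seasonal
forcing raises rather than conserves mean biomass at moderate
amplitude. Seedling percentage, post-shift ICS magnitude, post-shift
seedling-class mortality, all monotone orderings of cover and density
with rainfall, and the IP response to dispersal distance reproduce
well.

## Numerical and degenerate-input notes

Empty populations are legal everywhere (summaries report zeros/NaN,
dispersion indices raise `UndefinedIndexError` on an all-zero
pattern); extinction is absorbing. Quadrat size must divide the plot.
σ = 0 gives a deterministic dispersal distance. Non-finite integrator
states raise `NumericalInstabilityError` advising a smaller dt_int.
Sample (n−1) variance is used in both dispersion indices.
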