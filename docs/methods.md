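# Methods

## Model overview

`chondrosim` couples three layers:

1. **Equilibrium consolidation mechanics** (module `mechanics`). The
   aggrecan osmotic pressure is the cubic virial expansion
   Π(a) = RT(α₁a + α₂a² + α₃a³) with R = 8.3×10³ mL·kPa·mol⁻¹·K⁻¹,
   T = 300 K, α₁ = 1.4×10⁻⁷ mol/mg, α₂ = 4.4×10⁻⁹ mol·mL/mg²,
   α₃ = 5.7×10⁻¹¹ mol·mL²/mg³. A day's sustained stress σ consolidates
   the tissue to the strain ε solving Π(a/(1−ε)) = σ; the model is
   one-dimensional and homogeneous, assumes the full equilibrium is
   reached within the day, and assigns the entire compressive
   resistance to aggrecan (no collagen tension term). Tissue health is
   0.35 − ε(a, 400 kPa): the margin to a typical tolerable maximal
   strain under a standard test load, negative in the OA danger regime.

2. **Daily damage/repair dynamics** (module `dynamics`). Discrete-time
   (1-day step) synchronous updates of chondrocyte, aggrecan and
   collagen densities, driven by the scalar activity level
   A = ε·f (strain fraction × loading frequency, units Hz). Damage is a
   shifted logistic sigmoid D(A) with D(0) = 0 and sup D = 1 exactly
   (both identities are algebraic, and the implementation keeps the two
   cancelling terms in the same floating-point form so D(0) is 0.0
   bit-exactly). Synthesis per cell relaxes exponentially in A/A₀ from
   a resting to a saturated rate. All parameter defaults are the
   published set; A₀ = 0.30 × 0.3 Hz = 0.09 Hz reads the "30 %"
   threshold strain as the fraction 0.30, which keeps μ·A
   dimensionless with μ in seconds and A in Hz.

3. **Stochastic loading and Monte Carlo risk** (modules `activity`,
   `risk`). A lifestyle profile draws each day's stress and frequency
   independently from normals with sd = mean/3, truncated below at 0 by
   resampling (resampling avoids the point mass at zero that clamping
   would create; a negative draw has probability ≈1.3×10⁻³ per draw).
   Ensembles use per-realization streams spawned from a base seed via
   `numpy.random.SeedSequence`, so results are independent of execution
   order and bit-reproducible. Hitting times are the first day at or
   after the lifestyle-switch day with health strictly below zero,
   converted to weeks (days/7, no sub-day interpolation); censored
   realizations (no crossing within the horizon) are excluded from the
   mean/sd and counted separately.

## Numerical choices

- **Strain solver.** Because Π is strictly increasing with Π(0) = 0,
  the balance Π(a/(1−ε)) = σ is solved by inverting Π once per stress:
  x = Π⁻¹(σ) by bracketed Brent root-finding (xtol 10⁻¹⁰ on density,
  machine rtol), then ε = 1 − a/x. This is algebraically identical to
  root-finding on ε but lets the fixed 400 kPa health-test inversion be
  cached, which dominates the per-day cost. A bracketed solver is used
  rather than the cubic closed form so the code survives future
  generalisations of Π. Stresses at or below the resting pressure Π(a)
  return ε = 0 (no swelling branch; the clamp is logged at debug
  level). A positive stress on zero aggrecan raises a distinct
  `UnresistedLoadError` rather than looping.
- **Clamping.** Densities are clamped at 0 after each daily update and
  the event logged; with the default rates clamping only occurs in the
  terminal collapse phase.
- **Steady state.** `steady_state` iterates the daily map under the
  deterministic mean load until the maximum relative per-day change
  across the three densities falls below a tolerance. Under zero load
  the map has a genuine fixed point (closed forms: n* = n⁽⁰⁾,
  c* = ρ⁽ᶜ⁰⁾n⁽⁰⁾/λ⁽ᶜ⁰⁾ = 183.33 mg/mL) and converges to machine
  precision. Under physiologic loads no strict interior fixed point
  exists (see Limitations), so the default tolerance of 5×10⁻⁴/day is
  deliberately loose: it detects the quasi-stationary plateau (for the
  medium profile: n = 9.83×10⁷ cells/mL, a = 84.4 mg/mL,
  c = 184.5 mg/mL, health +0.085, reached after ≈120 days from the
  default start state of n⁽⁰⁾ cells, 100 mg/mL aggrecan — a typical
  healthy density — and c⁽⁰⁾ collagen). Tighter tolerances raise an
  explicit non-convergence error carrying the last state.
- **Confidence bands.** "95 % band" defaults to the empirical 2.5/97.5
  percentiles across realizations (the spread of individual subjects);
  `method="mean_se"` gives the normal-theory CI of the ensemble mean
  instead.
- **Failure probability.** The cross-pair estimate of P(L > R) is
  computed by sorting and binary search, exactly equal to the
  exhaustive pairwise count; a paired mode compares draws elementwise
  for pre-coupled samples.

## Default study protocol

The packaged scenario presets reproduce the published lifestyle-switch
experiments: initialize at the medium-profile quasi-steady state, 700
days of stochastic medium activity (σ̄ = 350 kPa, f̄ = 0.1 Hz), then an
abrupt switch to high (450 kPa, 0.12 Hz) or low (200 kPa, 0.02 Hz)
activity for 4,200 days (600 weeks), with 500 realizations. The source
publication states neither the initial condition, the burn-in length,
nor the realization count; these defaults are this package's fixed
reconstruction, chosen once. Hitting times are measured from the switch
day (configurable).

## Model behaviour under the default parameters, and limitations

A reduced fixed-point analysis (solving the chondrocyte and collagen
balances self-consistently across all aggrecan densities) shows the
aggrecan balance residual under the medium profile is strictly negative
— the published default parameter set admits **no homeostatic interior
fixed point**. The medium lifestyle is only quasi-stable: the tissue
sits near (n ≈ 0.95–0.98 n⁽⁰⁾, a ≈ 82–85 mg/mL, health ≈ +0.05…+0.09)
for one to two years and then drifts slowly downward, because
chondrocyte death at medium activity levels (D⁽ⁿ⁾ ≈ 0.02–0.03 with the
shallow μ⁽ⁿ⁾ = 50 s sigmoid) outpaces the logistic proliferation
margin, shrinking synthesis and feeding back through strain into more
damage. Consequences measured by this implementation:

- Health stays positive for 500 days of medium activity in ≥95 % of
  realizations (the regime is stable on the 1–2 year scale), but the
  mean health approaches zero within roughly 2 years of stochastic
  medium loading.
- After the 700-day burn-in the ensemble is already at the zero-health
  threshold, so high-switch hitting times measured from the switch day
  are near zero (mean ≈ 0.01–0.3 weeks depending on the seed), far
  below the published 345 ± 47 weeks. A sensitivity scan over a common
  steepness rescaling of both damage sigmoids (μ → mμ) moves the mean
  onset from ~35 weeks (m = 1, no burn-in drift correction) through
  ~107 ± 10 (m = 1.5) and ~552 ± 104 (m = 2) to "never fails" (m ≥ 3):
  the published onset estimate lies in a hypersensitive transition zone
  that the printed parameter values do not reach. This package
  implements the equations and constants exactly as published and
  reports the discrepancy rather than adjusting parameters toward the
  published figure.
- The qualitative switch phenomenology is reproduced: the high switch
  shows a brief synthesis-driven rise in mean health followed by a
  persistent decline to collapse; the low switch drops health below
  zero within weeks (under-synthesis) and then plateaus near the
  threshold instead of declining indefinitely.

What the synthetic loading generator does and does not emulate: it
captures day-to-day variability of a stationary lifestyle
(independent truncated-normal stress and frequency, constant
distribution parameters within a schedule segment) and abrupt lifestyle
changes; it does not model within-day load sequences, autocorrelated
activity, stress–frequency correlation, traumatic single events beyond
the normal tail, or population variability in the tissue parameters
(explorable by re-running with different parameter files). Passing
tests therefore validate the model's internal consistency and its
response to stationary stochastic loading, not calibration against
clinical OA incidence.

Further limitations: spatially homogeneous one-dimensional tissue; no
transient poroelasticity (each day reaches full consolidation); no
collagen contribution to compressive stiffness; protease, cytokine and
signalling pathways are abstracted into the damage/repair rate
functions; strain is clamped to compression only.
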