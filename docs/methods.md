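# Methods

This note records the models implemented in `valvefatigue`, their
assumptions, the defaults that matter, and the choices made where the
published method left the design open.

## Fatigue life model

The leaflet's life is evaluated at a single material point — the
maximum-stress integration point — under a *stationary* load spectrum: the
stress history of one representative cardiac cycle is assumed to repeat
unchanged for the device's whole service life.  Counting is performed on
the full supplied signal and counts divided by the number of cardiac cycles
spanned, so multi-cycle inputs average out per-cycle numerical jitter.

Stresses are signed throughout (compression negative), which lets the
amplitude/mean definitions and the Gerber correction apply unchanged to
compressive phases.

**Turning points and peak averaging.**  The signal is reduced to strictly
alternating local extrema (plateaus collapse to their first sample;
endpoints are kept).  Peaks of the same kind whose values differ pairwise
by at most `rel_tolerance × max|stress|` are replaced by their arithmetic
mean — a spectrum simplification that removes numerically-distinct copies
of the same physical peak.  Default `rel_tolerance = 0.05`; `0` is the
identity.  If averaging degenerates an adjacent max/min pair, the sequence
is re-reduced to strict alternation.

**Rainflow variant.**  Four-point rule: whenever four consecutive turning
points enclose an inner range not exceeding either neighbouring range, the
inner pair is extracted as a closed cycle (count 1.0); the unclosed
residual contributes 0.5 per adjacent pair.  Two half-cycles are equivalent
to one full cycle, and twice the summed counts always equals the number of
half-cycle ranges in the input (a conserved quantity asserted by property
tests).  Sub-cycles whose extremes agree within an absolute `1e-6` MPa are
merged.  An alternative reading of the half-cycle bookkeeping — counting
*every singleton* sub-cycle as 0.5 rather than only unclosed residuals —
exists; this package counts residuals as 0.5, which is the standard
rainflow convention and matches the full/half-cycle language of the method.

**Mean-stress correction and S-N curve.**  Each sub-cycle maps to a fully
pulsatile equivalent stress `SNf = s_a / (1 − (s_m/Su)²)`.  The squared
term is sign-symmetric, so compressive means are penalised exactly like
tensile ones; a `clamp_negative_mean` option zeroes negative means for
sensitivity studies (off by default).  Consequently the Basquin pair
(σ_f, β) supplied in the material card **must be calibrated on pulsatile
(R = 0) tests** — the Gerber step maps every cycle onto that reference
curve.  No endurance limit is assumed; an optional threshold amplitude
(`endurance_limit`, default off) can suppress damage below a user-chosen
amplitude.

**Clamping.**  `|s_m| ≥ Su` or `SNf ≥ σ_f` would put the Basquin inverse
below half a cycle, which is not physically countable; such sub-cycles are
clamped to Nf = 0.5 (failure within one half-cycle), flagged in the result
breakdown, and logged.  Zero-amplitude sub-cycles contribute no damage.

**Units and conversions.**  MPa, seconds and cycles throughout; one cardiac
cycle is one heart beat, days = L/(bpm·60·24), years use the 365-day
convention.  The default heart rate is 70 bpm, the pulse-duplicator
protocol rate.

## Tear propagation model

The initial tear is an ellipse with semi-axes a ≥ b (mm).  Per sub-cycle,
the far-field extremes are amplified by the stress concentration factor and
converted to elastic-plastic crack stresses by the Glinka strain-energy-
density criterion; the stress range then drives Paris-law growth.

- **Kt convention.**  The default is `Kt = 1 + 2·b/a`, which lies in
  (1, 3] for a ≥ b and reaches the circular-hole value 3 at a = b.  Note
  this *differs* from the classical elliptical-hole factor `1 + 2·a/b`
  (unbounded for sharp ellipses); the classical form is available as
  `kt_convention="classical"` for sensitivity studies.  The default is kept
  deliberately because the whole parameter set (C, m, e, K) must be
  calibrated jointly with whichever convention is used.
- **Glinka solve.**  The left side of
  `σ²/E + (2σ/(e+1))(σ/K)^(1/e) = (Kt·S)²/E` is strictly increasing in
  σ > 0, so the root in (0, Kt·S] is unique; it is found by Brent's method
  on that bracket (the lower end is negative, the upper end non-negative by
  construction) and verified to satisfy the equation to a relative residual
  of 1e-10, else an error is raised.  Negative applied stress is solved on
  the magnitude and the sign restored; the interpretation of K is the
  cyclic strength coefficient of a Ramberg–Osgood-type hardening law.
- **ΔK and the axis-swap rule.**  `ΔK = Δσ·√(π·ℓ)` with no geometry factor
  (Y = 1, exactly as the method states).  Growth along the major axis uses
  ℓ = b; growth along the minor axis uses ℓ = a.  Because the minor-axis
  driving length is the larger one, b can outgrow a; the axes are left
  unsorted as they evolve and Kt is applied verbatim to the current values.
- **Cadence.**  Geometry (hence Kt and ΔK) is refreshed after every block
  of `block_size` cardiac cycles; `block_size = 1` (the default) refreshes
  every cycle and is the limit the superposition formula approximates.  A
  Richardson-style convergence check on block halving is part of the test
  suite.  Half-cycles contribute with weight 0.5 by default
  (`half_cycle_weight=False` floors counts to whole cycles).
- **Termination.**  Paris growth with m > 2 blows up in finite cycle count,
  so long runs should set `max_axis_length` (e.g. the leaflet dimension);
  the trajectory then stops with status `"tear-through"`.

## Synthetic cardiac spectra

The generator emulates the qualitative structure of leaflet stress
histories from valve fluid–structure simulations: one dominant systolic
extremum per cycle (a smooth `sin^(2n)` bump over the systolic window,
default 35 % of the period — a standard physiological systole fraction), a
secondary diastolic bump, a sign profile (compression-dominant outer
surface vs. tension-dominant inner surface), strict cycle-to-cycle
repetition when noise is off, and optional seeded additive Gaussian noise.
Bumps are renormalised on the sample grid so the noise-free sampled extreme
equals the template peak exactly.

The three packaged templates carry the reported per-patient systolic peak
magnitudes (A: 0.659 MPa compressive, B: 0.632 MPa compressive, C:
1.676 MPa tensile) at 70 bpm.  The diastolic counter-stress magnitudes —
0.10, 0.30 and 0.80 MPa for A, B and C — are qualitative defaults chosen
once: A's small value encodes its mild diastolic tension reversal, B's
larger value its stronger diastolic excursion after balloon dilatation of
the clinical geometry, and C's its persistent dual-phase tension.  These
values (not the peaks) set the per-cycle amplitude and mean, and with them
the demo life ordering A > B ≫ C emerges from the pipeline.  The generator
is an *emulation*, not a reconstruction: it does not model hemodynamics,
pressure-to-stress transfer, beat-to-beat variability, or surface shear.
Passing tests therefore demonstrate correctness of the counting and damage
machinery on realistic waveform shapes, not predictive accuracy for any
real patient.

## Material cards

`MaterialFatigueProperties` holds Su, σ_f, β (< 0), E, the work-hardening
exponent e ∈ (0, 1], the cyclic strength coefficient K, and the Paris pair
(C, m); `paris_c` must be supplied in units consistent with mm and
MPa·√mm — it is validated for positivity but never unit-converted.  The
neo-Hookean helpers (C10 = μ0/2, D1 = 3(1 − 2ν)/(μ0(ν + 1)), and the
strain-energy evaluation) document the leaflet hyperelastic card for
completeness; the fatigue pipeline does not consume them, since the
upstream structural simulation that would is outside this package's scope.

The packaged demo card is a **placeholder**: the fitted fatigue/fracture
constants of glutaraldehyde-treated bovine pericardium come from a
proprietary cyclic-test campaign and are not redistributable, so the demo
values are order-of-magnitude plausible picks made once (Su 15 MPa,
σ_f 16 MPa, β −0.17, E 2 MPa, e 0.15, K 20 MPa, C 1e-6, m 3).  Absolute
lives computed with them are demonstrations only.

## Problem sizes and numerical choices

Tests and the acceptance script use 3 cardiac cycles at 200 samples/cycle
for pipeline runs (enough to exercise multi-cycle normalisation while every
check completes in seconds), 3000-cycle propagations for the Paris
closed-form comparison, and a 10 mm tear-through threshold for the demo
propagation.  Rainflow equivalence is property-tested against an
independent brute-force four-point oracle on random alternating sequences
of length ≤ 15; the Glinka solver is checked against plain bisection over
a parameter grid.

## Known limitations

- Single-point, uniaxial, stress-based analysis: no multiaxial counting,
  no strain-based methods, no spectral (frequency-domain) fatigue.
- Linear (Miner) damage accumulation; no load-sequence effects,
  probabilistic S-N scatter, or safety factors.
- Paris growth without threshold ΔK_th, crack closure, or mixed-mode
  effects; Y = 1 throughout.
- The synthetic generator's waveform shape and diastolic magnitudes are
  stated defaults, not data-derived.
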