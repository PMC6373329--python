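# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `netpet`.

## Forward model of the synthetic cohort

The simulator is built so that the estimators under test are *exactly
identifiable* on noiseless data; it validates estimators, not tissue biology.

**Plasma input.** A Feng-type curve in minutes and kBq/mL:
`C_p(t) = a1·(t−t0)·e^(−lam1(t−t0)) + a2·(e^(−lam2(t−t0)) − e^(−lam1(t−t0)))
+ a3·(e^(−lam3(t−t0)) − e^(−lam1(t−t0)))` for `t > t0`, else 0. Defaults:
`a1 = 800 kBq/mL/min`, `a2 = 20`, `a3 = 10 kBq/mL`, `lam1 = 4`, `lam2 = 0.5`,
`lam3 = 1e-4 min⁻¹`, `t0 = 0.5 min`. The tail rate `lam3` is deliberately
near zero. With a tail decaying at rate λ, the late tissue-to-reference
ratio of a target region tends to `1 + (k2′ − k2a)/(k2a − λ)`, which exceeds
`1 + BP_ND` for any λ > 0; at `lam3 = 1e-4` the excess is ≈ 0.001 for the
thalamus-like default (BP 0.24, k2′ 0.0322 min⁻¹), so static ratios approach
the true BP_ND from below over the scan — the under-then-converge behaviour
a late-window ratio method must exhibit for its validation to be meaningful.
A faster tail (e.g. 0.01 min⁻¹) would make the static ratio *overshoot* the
true value at late times and invert the window-bias ordering. All simulated
concentrations are decay-corrected, as clinical PET frames are; absolute
scale is arbitrary because every estimator in the package is scale-invariant
(asserted by tests).

**Reference region** (occipital cortex, zero specific binding): one-tissue
compartment, `C_R = K1′ · (C_p ⊗ e^(−k2′ t))`, default `K1′ = 0.3
mL/min/mL`.

**Target regions**: SRTM2 kinetics `C_T = R1·[C_R + (k2′ − k2a)·(C_R ⊗
e^(−k2a t))]` with `k2a = R1·k2′/(1 + BP_ND)`; for a one-tissue reference
this equals the one-tissue target solution with delivery `R1·K1′`, so the
generated BP_ND is exact by construction.

**Convolutions** use an exponential-kernel recursion that is exact for
piecewise-linear inputs, evaluated with `scipy.signal.lfilter` on a uniform
grid (default step 0.0025 min). At that step the curves agree with an
adaptive ODE solution to better than 1e-4 relative at every frame mid-time;
the binding error this induces in the fits is below 3e-4 BP units.

**Region registry** (per hemisphere where paired): thalamus 0.24, putamen
0.25, locus coeruleus 0.19 (with reduced delivery R1 = 0.9), frontal 0.02,
amygdala −0.01, caudate −0.03, cerebellum/parietal/hippocampus −0.04,
brainstem −0.07 — 17 atlas target VOIs (8 paired + brainstem) plus the locus
coeruleus and the occipital reference. These levels span the range reported
for noradrenaline-transporter PET in parkinsonian cohorts.

**Cohort defaults** (the study conditions every test and the acceptance
script use): 10 subjects; schedule `6x30,3x60,2x120,22x300` (33 frames,
120 min); population `k2′ ~ Normal(0.0322, 0.0105²) min⁻¹` truncated above
0.005; per-region BP jitter SD 0.04 (chosen at the lower end of the
between-subject SDs such studies report, 0.03–0.08); frame noise: Gaussian
with SD `alpha·sqrt(max(value, 0.01 kBq/mL)/Δt_min)`, default `alpha = 0.3`,
a count-statistics surrogate in which variance grows with activity and
shrinks with frame duration (≈ 2–4 % on late 300-s frames). One cohort seed
spawns independent per-subject substreams (`SeedSequence.spawn`), so
extending the cohort never perturbs existing subjects.

**What the generator does not emulate**: scanner/reconstruction physics,
motion, partial-volume effects, a second tissue compartment, or violations
of the reference-region assumption. Passing tests therefore demonstrate
estimator correctness under the models' own assumptions, not robustness to
real-data model misspecification.

## Estimation chain

1. **MRTM** (three coefficients, OLS): `C_T(T) = γ1∫C_R + γ2∫C_T + γ3C_R(T)`,
   `k2′ = γ1/γ3`, `BP = −(γ1/γ2 + 1)`. Applied to the merged (unweighted
   mean; volume weights accepted) left+right thalamus against the occipital
   reference on the 0–90-min TACs. The phrase "one-parameter" sometimes used
   for this step refers to the one parameter of interest, k2′; the estimator
   itself is the standard three-coefficient multilinear form.
2. **Population k2′**: arithmetic mean of the per-subject MRTM estimates; a
   failing subject aborts with its id (silent exclusion would bias every
   downstream BP).
3. **MRTM2** (two coefficients, k2′ fixed) and **SRTM2** (basis functions)
   give per-region BP_ND. In the noiseless limit both agree with truth and
   with each other to < 5e-4 BP units on the default registry.
4. **Static BP**: duration-weighted window mean of target and reference,
   ratio minus one. Hemispheres are pooled by averaging the two per-side BP
   values (pooling the TACs first is also implemented; the two orders agree
   exactly for symmetric kinetics).
5. **Agreement**: per region × window × model Spearman ρ (average ranks,
   large-sample t p-value) and ICC(A,1); pooled per window × model OLS of
   static on model BP over subject × region points.

## Numerical choices

- **Cumulative integrals at frame mid-times**: frame values are within-frame
  averages, so the integral to a frame start is the exact duration-weighted
  sum of preceding values; the half-frame to the mid-time adds
  `value·Δt/2`. Exact for constants, O(Δt²) otherwise.
- **t\*** (start of the multilinear fit window) defaults to 0: simulated
  data satisfy the operational equations from t = 0 (verified: estimates
  move < 0.4 % for t\* ∈ {0, 10, 20} min). Raise it for real data.
- **Least-squares weighting**: unweighted by default; optional frame-duration
  weights.
- **Collinearity guard**: condition number of the column-scaled design
  > 1e8 raises (e.g. a target exactly proportional to the reference).
- **SRTM2 search**: 100 log-spaced k2a values in [1e-4, 1] min⁻¹, single
  free amplitude R1 per candidate (model folded as
  `C_T = R1·[C_R + (k2′−k2a)B(k2a)]`), then golden-section refinement of
  k2a (log-domain width 1e-4) between the grid neighbours of the winner; an
  optimum pinned at the grid edge sets a boundary flag. Deterministic, no
  initialization sensitivity. The convolution basis is built from an
  average-preserving reconstruction of the reference TAC (linear through
  the mid-times with four correction sweeps so it re-bins to the measured
  frame averages); a continuous reference can be supplied instead.
- **Static windows** must coincide exactly with frame boundaries; any
  misalignment raises rather than interpolating.
- **ICC variant**: ICC(A,1) (two-way, single measurement, absolute
  agreement), because the static scan is meant to *replace* the kinetic
  model, so systematic offsets must count against it; the consistency
  variant ICC(C,1) is selectable.
- **Multiple comparisons**: Bonferroni across the five clinical covariates
  (per family); configurable.

## Design decisions where the design was open

- Hemisphere pooling averages per-side BP values (not TACs) by default,
  because the reported region-level statistics are BP summaries; both orders
  are available and agree on symmetric data.
- Merged thalamus uses equal weights (synthetic hemispheres have equal
  volume); volume weights are accepted for user data.
- Time is seconds in files and minutes in all math; conversion happens only
  at the I/O boundary. Intervals are half-open `[start, end)`, 0-based.
- The clinical-association analysis is the Spearman pathway only; a MANOVA
  over unspecified outcome sets is deliberately out of scope.

## Problem sizes

The test suite and the acceptance script simulate 10-subject cohorts; the
noisy slope-ordering check uses 20 replicate cohorts and the clinical-null
check 100 replicate covariate draws, which keeps a full run around half a
minute on one CPU while leaving the Monte-Carlo standard errors of the
reported fractions at the few-percent level.

## Known limitations

- The large-sample t approximation for Spearman's p is anti-conservative at
  n = 10 (measured per-test level ≈ 0.0126 at nominal 0.01 after Bonferroni),
  so the family-wise non-significance rate of the clinical-null check runs
  near 94 %, slightly under the nominal 95 %. The package reports the
  computed fraction as is.
- MRTM k2′ under frame noise is variable at realistic noise (per-subject
  relative errors of tens of percent at alpha = 0.3); only the cohort mean
  is transferred downstream, which is the reason the two-parameter models
  are used for regional BP in the first place.
- Static-window BP inherits the transient-equilibrium bias by design; the
  package quantifies it rather than correcting it.
- The image-space TAC extractor averages voxels within integer labels; it
  does not register, resample or partial-volume-correct.
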