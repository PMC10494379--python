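# Methods

## Signal models and units

All fitting operates on the normalized ratio S(b)/S(0); the measured S(0)
divides the curve rather than being estimated as a free parameter, which
matches how the three models are written and removes one degree of
freedom per voxel. Diffusion coefficients are carried internally in
mm²/s (brain tissue ≈ 1e-3 mm²/s); reporting layers rescale by 1e3 where
"×10⁻³" table units are wanted. Published tables in this area sometimes
print the inverted unit string "×10⁻³ s/mm²" for diffusivities; the
physically meaningful unit is mm²/s and that is what the package uses.

The biexponential fast compartment decays with exponent (D* + D). The
more common convention uses D* alone; both are available through the
`variant` switch of `predict_biexp` / `FittingConfig.biexp_variant`, with
(D* + D) the default. The two differ only by a shift of D* by D (< 5% at
typical values), absorbed into the D* estimate.

The stretched exponential is exp[−(b·DDC)^α]: the heterogeneity index α
is the exponent of the *product* b·DDC. The constraint α ∈ (0, 1] makes
α = 1 the monoexponential limit and lower α a broader intravoxel mixture
of decay rates.

## Fitting

**ADC** uses the closed-form two-point estimate from b = 0 and 1000 s/mm²
only, mirroring the conventional clinical DWI product map, even though 12
b-values are available; a log-linear least squares over all points is
available via `FittingConfig(adc_all_b=True)`.

**IVIM** fitting is segmented — the field-standard stabilizer for an
ill-conditioned model:

1. log-linear fit of points with b ≥ 200 s/mm² (the first weighting in
   the default scheme beyond the perfusion-sensitive regime) gives D and
   the slow-compartment intercept;
2. f = 1 − exp(intercept), clipped to [0, 1];
3. D* from a 1-D bounded search seeded by a 48-point log-spaced global
   grid over the pseudodiffusion axis — the only direction along which
   the least-squares surface has multiple local minima, so a global grid
   here removes the need for multi-start refinement;
4. bounded full nonlinear least squares over (D, D*, f) with an analytic
   Jacobian (default on; `refine=False` stops after step 3).

D* ≥ D is enforced structurally by parameterizing D* = D + δ with δ ≥ 0,
keeping the compartments identifiable (no label swapping). Bounds:
D ∈ (1e-6, 5e-3), D* ∈ (1e-4, 5e-1) mm²/s, f ∈ [0, 1] — wide enough to
contain reported tumour values with margin. Solver tolerances are set to
machine level (xtol = ftol = 1e-15), which makes noise-free forward-fit
round trips exact to ~1e-13 relative while costing little on noisy data
(~1 ms per voxel).

**Stretched-exponential** fitting is a bounded nonlinear least squares
with DDC initialized from the two-point ADC and α from 0.8; bounds
DDC ∈ (1e-6, 1e-1) mm²/s, α ∈ (0.01, 1.0].

Degenerate curves (non-positive S(0), non-decaying signal) are flagged
per voxel — `converged=False` at curve level, NaN parameters plus an
infinite fit-quality value at volume level — and never abort a volume:
real masks always contain pathological voxels.

## Synthetic cohort

The phantom cohort emulates a 40-patient study: 22 progression and 18
pseudoprogression lesions. Each subject is one homogeneous ellipsoid
(in-plane radius 1.8 voxels × 2.5 mm ⇒ central-slice cross-section
≈ 56 mm², within the 45–65 mm² range of a typical lesion tracing; five
axial slices) in a 16×16×8 volume of 2.5×2.5×4 mm voxels, embedded in a
fixed white-matter-like background (D = 0.78e-3 mm²/s, D* = 10e-3, f =
0.05, implying a two-point ADC ≈ 0.8e-3). Per-subject biexponential
truths (D, D*, f) are drawn independently from the group's published
mean/SD as truncated normals; no between-parameter covariance is modelled
because none is reported — a documented limitation.

The lesion signal is generated from the biexponential truth. The
subject's monoexponential and stretched "truths" (ADC, DDC, α) are
defined as the noise-free best fits of those models to the generated
curve: model mismatch is inherent to multi-model DWI, and this definition
makes recovery testing well-posed. Noise is Rician — the magnitude-MRI
standard — applied per voxel and b-value as sqrt((S+g₁)² + g₂²) with
g₁, g₂ ~ N(0, σ), σ = S(0)/SNR, SNR = 50 at b = 0 in the lesion by
default. Cohort generation is a pure function of (preset, seed); each
subject draws from a child seed spawned deterministically.

A second reader is emulated by morphological jitter of the ROI: a random
integer shift of up to one voxel per axis plus, half the time, a
one-voxel erosion or dilation, constrained to ≥ 50% overlap with the
original tracing. With 2.5 mm voxels this is a fairly coarse disagreement
and deliberately pulls some background into the second reader's ROI —
that contamination, not fitting noise, dominates the interobserver
spread, which is what the ICC/Bland–Altman layer is meant to exercise.
Consequences worth knowing: parameter recovery against generating truths
should be judged on the true-mask reader, and reader-averaged group means
sit a few percent closer to background values than the truths.

What the phantoms do **not** model: within-lesion texture (no
heterogeneity statistics are reported to emulate), partial-volume and
susceptibility effects, anatomy, motion. Passing tests therefore show the
pipeline is correct under its own generative assumptions, not that it is
robust to real-patient confounds.

## ROI protocol

Per lesion and reader, the measurement is the mean of each parameter map
over the in-ROI voxels on the three consecutive axial slices containing
the most lesion (ties broken toward the inferior-most triple), repeated
three times and averaged. "Three ROIs / measured 3 times" is
operationalized as three repeats of this protocol: repeats are identical
for a fixed mask and differ only when each repeat uses its own jittered
tracing, since no definition of how the three ROIs differ is available.
Axial is the third voxel axis after reorientation to canonical (RAS)
axes; masks are strictly binary; NaN voxels are excluded from means, and
an ROI with no finite voxels for some parameter fails QC loudly. The
per-slice ROI area (voxel count × in-plane voxel area / number of slices)
is warned about when outside 45–65 mm².

## Statistics

- **Normality**: one-sample KS against a normal with estimated mean/SD,
  i.e. the Lilliefors correction (via statsmodels) — appropriate when the
  null's parameters come from the sample.
- **Group comparison**: pooled-variance Student t (df = n₁+n₂−2), also
  computable directly from per-group (n, mean, SD) summaries. The pooled
  form was chosen because it reproduces the published worked-example t
  statistics from their printed summaries; Welch's does not.
- **ICC**: fixed to ICC(2,1) — two-way random effects, absolute
  agreement, single measures — computed from the ANOVA mean squares with
  the F-based (Satterthwaite) 95% CI. The form is a documented choice,
  not tuned. Agreement bands: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate,
  ≤0.80 good, else excellent.
- **Bland–Altman**: bias ± 1.96·SD of paired differences.
- **ROC**: empirical AUC under the Mann–Whitney tie convention (½ credit)
  via placement values; orientation auto-selected per marker so AUC ≥ 0.5
  and recorded. Cutoffs are searched over midpoints between consecutive
  observed values (plus ±∞); the Youden-maximal cutoff wins, ties broken
  toward higher specificity. 95% CIs use the DeLong variance, truncated
  to [0, 1].
- **DeLong comparison**: paired placement-value covariance test,
  two-sided normal p. Marker orientation is supplied by the caller (the
  report uses each ROC's recorded direction); auto-orienting inside the
  test would condition on the data and makes the null rejection rate
  collapse (measured ≈ 0.002 instead of 0.05), so the core test never
  does it. Identical oriented markers short-circuit to p = 1.
- **Multiple testing**: none applied; recorded in report metadata.

Group-level statistics use reader-averaged values per subject;
agreement statistics use the first two readers.

## Problem sizes and runtime choices

The default study (40 subjects, ~170 fitted voxels each after dilating
the lesion mask by 2 voxels to cover jittered tracings, 3 models per
voxel) runs in under a minute on one CPU; fitting is restricted to the
dilated lesion because background far from any tracing never enters a
measurement. Monte-Carlo calibration checks in the test suite use 100 to
1000 replicates, sized so that their pass bands are several standard
errors wide under the null.

## Known limitations

- D* is intrinsically ill-conditioned (it only shapes the few low-b
  points); at SNR 50 its per-voxel estimates are noisy and upward-biased
  for small-D* subjects, so only loose (median-within-30%) recovery is
  asserted.
- Rician bias slightly inflates high-b signal at low SNR, depressing
  ADC/D/DDC by ~1% at SNR 50; no bias correction is applied.
- The vendor workstation's fitting algorithm is unpublished; the
  segmented strategy here is the field standard but cannot be validated
  against the product implementation.
- Interclass correlation magnitudes depend strongly on the reader-jitter
  scale, which is a modelling choice (1 voxel), not an estimate from
  reader data.
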