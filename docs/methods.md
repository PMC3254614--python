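# Methods

`fionmri` quantifies iron-oxide-labeled macrophages in gradient-echo (GRE)
magnitude MRI along two routes: voxel-wise T2* relaxometry of multi-echo
phantom acquisitions, and a single-echo, muscle-normalized hypointensity
statistic (the *black pixel count*) for in-vivo tumor and lymph-node scenes.
Because no imaging data accompany the study design this package targets, a
synthetic-data module generates every input with known ground truth; all
validation is against that ground truth or against independent oracles.

## Signal model and relaxometry

A GRE voxel follows mono-exponential effective transverse decay,

    SI(TE) = SI0 · exp(−TE / T2*),

with SI0 the proton-density amplitude and T2* the effective relaxation time.
Iron-oxide particles shorten T2*; in the dilute linear regime the relaxation
rate R2* = 1/T2* is affine in the agent's molar concentration C:

    R2*(C) = R2*_intrinsic + r2* · C,

where r2* is the relaxivity in mM⁻¹s⁻¹. Concentrations given in µg Fe/mL are
converted to mM by dividing by the molar mass of iron (55.845 g/mol).

Two per-voxel estimators are available:

* **Log-linear OLS** (default): ordinary least squares of ln SI on TE;
  T2* = −1/slope, SI0 = exp(intercept), R² computed in log space. Closed-form
  and deterministic; exact on noiseless data for any ≥2 echoes. This is the
  conventional estimator for four-point pixel-by-pixel mapping.
* **Nonlinear magnitude fit** (`method="nls"`): least squares of
  SI0·exp(−TE/T2*) against the magnitudes, seeded from the log-linear
  solution. Magnitude noise is Rician, so echoes that have decayed into the
  noise floor are lifted toward ~σ√(π/2); the log fit weights those echoes
  heavily (log residuals) and overestimates T2*, while the magnitude-domain
  fit is nearly unbiased. With TE up to 57 ms and T2* near 9 ms the last echo
  carries ~0.2% of SI0, so at moderate SNR the nonlinear fit is the
  appropriate estimator and is the one used in the noisy validation runs.

Voxels are invalid (flagged, never an exception) when any echo is at or
below the signal floor (default: only non-positive values), when fewer than
two echoes are usable, or when the fit is non-decaying (slope ≥ 0 or T2*
above the 2000 ms cap). ROI summaries average T2* over valid voxels only.

**Relaxivity** is the OLS slope of tube-level R2* (s⁻¹, from ROI-mean T2*)
on molar concentration. Since R2* depends only on the decay constant, the
slope is invariant to any global intensity rescaling.

## Black pixel count

For each acquisition, lesion voxel signals are divided by the mean signal of
a muscle ROI from the same acquisition (muscle is unaffected by the agent,
so the ratio cancels inter-scan intensity fluctuations) and expressed in
percent: nSI = 100·SI/SI_muscle. Lesion voxels are pooled over all slices.

* The **baseline threshold** is the minimum nSI of the pre-injection lesion
  — the literal sample minimum by default, faithful to the statistic's
  definition. Because a single noisy voxel controls a sample minimum, a
  quantile option (`q > 0`, lower order statistic) is provided for
  robustness; it is off by default.
* The **black pixel count** is the percentage of post-injection lesion
  voxels strictly below that threshold.
* Histograms use fixed 1-percent bins [k, k+1) from 0, frequencies in
  percent of lesion voxels; values beyond the last edge extend the histogram
  rather than being clipped.
* A lymph node is called **metastatic** iff its black pixel count is
  strictly over the 20% rule threshold.

The whole chain is scale-invariant by construction: multiplying pre and post
volumes by any c > 0 changes no threshold, count, histogram or call.

## Synthetic data

The generator defines the study conditions; it is a model of the
acquisitions, not a fit to any particular image.

**Phantom** (four echoes at TE = 4.9, 13.6, 22.3, 57 ms): disk-shaped agar
tubes of labeled-cell pellets at 0, 12.5, 25, 50 and 100 µg Fe/mL on a 64×64
grid, intrinsic T2* 100 ms, SI0 1000, relaxivity 324 mM⁻¹s⁻¹, slowly
decaying background. Per voxel the noiseless signal is the mono-exponential
above; ground truth carries the true per-voxel T2*. Note the linear model
puts the 50 and 100 µg tubes at T2* ≈ 3.3 and 1.7 ms — below what a 4.9-ms
shortest echo can sample, consistent with the saturation such acquisitions
show at high loading. Noisy relaxivity-recovery runs therefore use tubes in
the measurable regime (0–10 µg Fe/mL, T2* ≳ 15 ms); noiseless exactness
holds at any concentration.

**Scene** (single echo, TE = 12 ms): a lesion disk and a disjoint muscle
disk on a 48×48 grid. A designed fraction f of lesion voxels — exactly
round(f·n), round half up, chosen uniformly at random — carries
labeled-macrophage signal loss, modeled as a multiplicative drop
(factor 0.25) on the baseline lesion signal; since the in-vivo statistic
uses a single TE, only relative signal matters, and the fully physical decay
path is exercised by the phantom. Defaults: baseline lesion SI 600, muscle
SI 500 (baseline nSI 120%), Rician σ = 20 (muscle SNR 25 — a documented
configuration choice, not a claim about any particular scanner). The
separation between the hypointense level (nSI 30) and the baseline spread
(~4 nSI units) makes the black pixel count a nearly unbiased estimate of
100·f, which the recovery tests quantify.

**Cohorts**: per subject, a pre-injection scene with fraction 0 and a
post-injection scene with a fraction drawn from a truncated normal
(bounds [0, 1]) at the group's mean ± sd. Default lymph-node arms: brachial
0.45064 ± 0.11932, axillary 0.34242 ± 0.11456, inguinal 0.08413 ± 0.05449
(n = 6 each); tumor arms 0.12093 ± 0.04139 vs 0.02074 ± 0.01461. Truncation
is required because the sds would otherwise generate impossible fractions;
it shifts the smallest group's realized mean up by ~0.7 points.

**Noise** is Rician everywhere: magnitude of a complex Gaussian,
independently per echo (no motion or inter-echo correlation model).

What the generator does *not* emulate: k-space sampling, partial volume,
susceptibility dipoles around iron deposits, B0 inhomogeneity, flip-angle/TR
weighting, registration error between timepoints, or anatomically realistic
lesion texture. Passing tests therefore demonstrate correctness of the
statistics pipeline under its stated model, not performance on real
acquisitions.

## Statistics

Two-group comparisons: two-sided Student's t or Mann-Whitney U;
`method="auto"` gates on Shapiro-Wilk normality of both groups at α = 0.05.
Three or more groups: one-way ANOVA with Tukey-Kramer post-hoc contrasts
(studentized-range adjustment with the unequal-n generalization, via
statsmodels; cross-checked in the tests against scipy's independent
implementation). Repeated acquisitions contribute one summary value per
lesion per timepoint, so the multi-group comparison is a one-way ANOVA on
those summaries rather than a repeated-measures model — a deliberate
simplification, not asserted as equivalent. `anova_tukey(pairwise=False)`
skips the post-hoc table in large simulation loops; the omnibus F test is
identical.

A power fact worth stating explicitly: with group spreads of ~11–12 points
and a brachial-axillary separation of ~10.8 points, the Tukey-adjusted
brachial-vs-axillary contrast has low power at n = 6 per group (all three
pairwise contrasts come out significant in roughly a quarter of simulated
cohorts, and the validation suite measures exactly that). The two contrasts
against the inguinal arm are essentially always significant, and the group
*ordering* is preserved in ~95% of cohorts.

## Numerical choices and problem sizes

* Seeds: every generator takes an explicit seed; cohort draws, voxel
  selection and noise all flow from one seed via spawned substreams, so runs
  are bit-reproducible.
* Validation problem sizes: 64×64 phantoms (~76 voxels per tube), 48×48
  scenes (~250 lesion voxels), cohorts of 6–12 lesions per arm, 200-seed
  cohort replications, 5000-replicate null calibrations, 100-replicate noisy
  relaxivity runs — sizes chosen so the whole suite runs in a couple of
  minutes on one CPU while keeping Monte-Carlo error well inside the
  asserted tolerances.
* Ties and boundaries are strict by definition: "below threshold" is `<`,
  "over 20%" is `>`; a node at exactly 20.0% is non-metastatic.
* Degenerate inputs: empty ROIs, non-positive muscle references, non-binary
  masks, overlapping lesion/muscle masks, duplicate echo times and NaN
  voxels all fail loudly with typed errors; degenerate voxels inside a fit
  are flagged invalid with a reason code instead.

## Known limitations

* The linear relaxivity model ignores the saturation and aggregation
  effects that flatten measured T2* at high intracellular iron loads.
* The literal-minimum baseline threshold is sensitive to the darkest
  pre-injection voxel; the quantile option mitigates but departs from the
  statistic's definition.
* The 20% rule is evaluated against the simulated group designs only; no
  claim is made about its operating point on real data.
* Masks are taken as given per acquisition; no registration or segmentation
  is performed or validated.
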