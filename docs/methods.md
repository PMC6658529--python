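# Methods

## Problem and model

`stagedefw` estimates fetal/birth weight from the four standard 2D
ultrasound biometry measurements — biparietal diameter (BPD), head
circumference (HC), abdominal circumference (AC) and femur length (FL),
all in centimetres internally — for deliveries between 28 and 43
(exclusive) weeks' gestation. Because third-trimester growth velocity is
far from constant (weekly weight gain rises to a peak around 34 weeks
and declines towards term), a single estimated-fetal-weight (EFW)
equation fitted over the whole range trades off bias across gestational
ages. The package therefore works with *staged* models: gestational age
is partitioned into five half-open 3-week bins,

    [28,31), [31,34), [34,37), [37,40), [40,43)  (weeks),

and a separate equation is dispatched per bin. The half-open convention
on decimal weeks is the only one that makes the five conventional
labels ("28–30" … "40–42 weeks") an exact partition; a delivery at 40+0
belongs to the upper bin.

Three model families are supported, each fitted per stage:

* **Interaction MLR** — ordinary least squares of log10(weight in g) on
  the four biometry mains and their six pairwise products, reduced by
  backward elimination (drop the largest-p term while any p ≥ α;
  default α = 0.05; ties broken by removing the later term in
  declaration order). Higher-order products are excluded; none appear
  in the fitted staged equations.
* **Fractional-polynomial regression (FPR)** — for each strictly
  positive composite predictor (pair products and single
  circumferences, scaled by 10/100/1000 into an order-one range), a
  Royston–Altman power search with powers S = {−2, −1, −0.5, 0, 0.5,
  1, 2, 3}, degree ≤ 2: 8 FP1 models plus 36 FP2 models (8 repeated
  powers, C(8,2) = 28 distinct pairs). Power 0 denotes ln x; a repeated
  power (p, p) contributes x^p and x^p·ln x. Candidates are compared by
  Gaussian deviance n·log(RSS/n); each composite's best basis enters a
  multivariable pool which then passes through the same backward
  elimination. The FP transforms use natural log; the *response* is
  log10 weight — the two are deliberately distinct operators in the
  formula representation. The per-composite search is marginal (one
  pass), not the full iterated multivariable-FP cycling; with the
  strong signal of weight-on-biometry regressions the selected powers
  are stable, and the subsequent elimination handles redundancy among
  composites.
* **Volume-based model (VM)** — weight as a sum of a head-volume and a
  trunk-volume term, W = a·head + b·FL·AC², fitted through the origin
  on the gram scale (the family has no intercept by construction). The
  head basis is selected among {HC³, BPD³, BPD·HC², BPD²·HC} by
  exhaustive residual-sum-of-squares comparison; a candidate whose
  fitted a or b is non-positive is rejected as physically meaningless.
  By default the fit is unweighted least squares, so the classical
  normal-equation identities hold; `fit(weighting="relative")`
  iteratively reweights by 1/fitted², which is the efficient estimator
  when the error is multiplicative (constant CV) and is what the
  parameter-recovery experiments use.

The recommended staged set uses VM for the three bins from 28–36 weeks,
MLR for 37–39 and FPR for 40–42; `fit_staged(..., families="auto")`
instead fits all three families per stage and keeps the one with the
smallest absolute in-sample systematic error. No smoothing is applied
across stage boundaries: the staged equations are discontinuous there
by construction, and the package preserves that.

## Formula representation

Every equation — fitted or published — is data, not code: an optional
intercept plus terms `coef × Π (prod(vars)/divisor)^power ×
ln(prod/divisor)^log_power`, with a declared response scale (g, kg,
log10 g, log10 kg, or natural-log g) and per-variable input units (cm
or mm; some published equations mix units within one formula). This
keeps printed coefficients bit-exact, auditable in a YAML registry, and
round-trippable: models written by `fit` reload and evaluate
identically. The shipped registry contains the fifteen staged equations
plus 21 published comparison formulas (six Hadlock variants,
Intergrowth-21st, three Woo variants, Combs, two Warsof variants,
Vintzileos, Shepard, three Jordaan variants, Shinozuka, Hsieh, Ott),
each with a citation string; entries whose coefficient transcription
could not be re-verified against the primary source are marked
`transcription: unverified-rounding` in the registry comments.

## Accuracy framework

Percentage error is PE = (EFW − BW)/BW × 100. A report carries the
systematic error (mean PE), random error (sample SD of PE), RMSE in
grams (gram scale confirmed by the magnitudes involved, ~250–500 g),
the proportions within 1/5/10% (inclusive, |PE| ≤ k) and a two-sided
one-sample t-test of mean PE against zero (NaN for degenerate series).
Model comparison reports, for a designated reference, the minimum
relative decrease over all other models of |systematic error| and of
RMSE: 100·(minₒₜₕₑᵣ m − m_ref)/m_ref.

Diagnostic accuracy classifies small/large-for-gestational-age (SGA:
BW < 10th centile at the completed week; LGA: > 90th) and macrosomia
(BW ≥ 4000 g, boundary inclusive) from the EFW using *the same*
thresholds applied to the prediction — the only choice that needs no
extra threshold convention. Sensitivity, specificity, PPV, NPV,
+LR = sens/(1−spec), −LR = (1−sens)/spec and overall accuracy
(TP+TN)/total are computed from the confusion matrix; undefined ratios
are NaN, never silently zero. Formatted rows round half-away-from-zero
to two decimals; internal values are never rounded.

`reconstruct_confusion` inverts a published (sens, spec, PPV, NPV, n)
row to the integer matrices consistent with it by exhaustive search
over compositions of n; published rows at n = 1933 admit unique
solutions, which lets printed tables serve as exact fixtures for the
metric identities.

## Synthetic cohort generator

No patient-level data ship with the package; the generator reproduces
the statistical structure the analysis assumes:

* Gestational age at delivery: stage probabilities 0.19 / 0.80 / 4.13 /
  60.75 / 34.14 % (a term-heavy mix with a sparse preterm tail),
  uniform within a stage except the post-term bin, which tapers
  linearly to zero at 43 weeks.
* Biometry: monotone mean curves (PCHIP through weekly anchors chosen
  from standard third-trimester charts, then calibrated once so that
  the implied median birth weight is ~3.3 kg and the weekly weight-gain
  velocity of the noise-free mean path peaks at week 34) plus
  correlated Gaussian deviations (pairwise correlation 0.6; SDs 0.28 /
  0.95 / 1.55 / 0.24 cm for BPD/HC/AC/FL).
* Weight: truth model (default: the recommended staged set itself)
  times multiplicative log-normal noise, ε ~ N(0, σ²) on the log scale
  with σ = sqrt(log(1 + CV²)), CV defaulting to 0.07 — chosen to
  mimic observed random errors of ~7–8% and within-10% rates of ~85%.
  Note E[e^(−ε)] = e^(σ²/2) ≈ 1.0025, so the mean PE of the generating
  model is ≈ +0.25%, not exactly zero; calibration experiments use
  slice sizes at which this is negligible against the t-test's
  resolution.
* Centile reference: empirical weekly P10/P90 from an independent
  calibration draw (default 50 000 records) of the same process,
  monotonised across weeks; SGA/LGA prevalence is therefore ~10% by
  construction.
* Inert realism: sex, ultrasound-to-delivery interval (0–3 days),
  gestational-diabetes and preeclampsia labels are generated but never
  used in fitting.

What the generator does *not* emulate: operator- and machine-dependent
measurement error structure, biometry–weight residual correlation
beyond the single Gaussian copula, demographic covariate effects, and
secular or site differences. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not clinical performance
on real populations.

## Numerical and design choices

* Elimination threshold α = 0.05 everywhere, matching the overall
  two-sided 0.05 significance convention.
* Greedy backward elimination coincides with exhaustive best-admissible
  -subset search on well-conditioned designs with clear signal (checked
  by a raw-numpy oracle on randomized trials); with heavily collinear
  candidate pools (biometry products), spurious interaction terms are
  retained at the usual selection rates — a property of the method,
  not a defect of the implementation.
* The VM recovery experiment uses a uniform stage mix and relative
  weighting: under the term-heavy cohort mix the head and trunk columns
  are nearly collinear and the head coefficient's sampling error is
  several-fold larger. Identifiability experiments should spread the
  design; cohort-emulation defaults are unchanged.
* Split fraction defaults to 1933/19310, giving a 17377:1933 allocation
  at full cohort size (`round(n·f)` validation records, sampled without
  replacement).
* Degenerate inputs: zero-variance PE series report a NaN p-value;
  zero-denominator diagnostic ratios are NaN; non-positive inputs to
  log or fractional powers raise domain errors naming the offending
  variable; empty stages and rank-deficient post-elimination designs
  raise fitting errors naming the stage/context.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; cohort and centile draws use independent spawned
  streams of one `SeedSequence`.

## Known limitations

* Published-formula coefficients were transcribed from the compendium
  literature; entries flagged `unverified-rounding` may differ in the
  last digit from the primary sources.
* The FP search is marginal per composite (see above); an iterated
  multivariable-FP algorithm could select different power sets on weak
  signals.
* The mm/cm auto-detection of cohort CSVs relies on header suffixes;
  ambiguous headers are rejected rather than guessed.
* Stage-boundary discontinuities of the staged set are deliberate and
  can produce a visible jump (~50–100 g at the 36/37-week boundary of
  the shipped equations) in longitudinal applications.
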