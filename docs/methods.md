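# Methods

This note documents the models, conventions and numerical choices behind
`audioclust`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Slope features

A contralateral audiogram is the threshold vector
t(f), f ∈ {250, 500, 1000, 2000, 4000, 8000} Hz, in dB HL. Audiograms are
drawn on an octave axis, so all fits use the octave index
x = log₂(f / 250) ∈ {0, …, 5}; slopes are therefore in dB/octave, the
audiological convention. Three segments are fitted by ordinary least
squares:

* line a: x ∈ {0, 1, 2} (250–1000 Hz) → slope ka,
* line b: x ∈ {3, 4, 5} (2000–8000 Hz) → slope kb,
* line c: x ∈ {4, 5} (4000–8000 Hz) → slope kc (two points, so the OLS
  slope is the exact step).

The raw dB-vs-octave slope is *positive* when thresholds worsen with
frequency; each slope is negated after fitting so that **positive = the
audiogram trends upward** (hearing improves with frequency), negative = a
descending segment, zero = flat. Consequences used as test invariants:
adding a constant to all thresholds leaves (ka, kb, kc) unchanged;
reflecting an audiogram about a flat line negates all three.

"No response" at a frequency is imputed to the audiometer ceiling
(120 dB HL by default, configurable) and tracked in a per-audiogram
censored set; censored values enter means and slopes at the ceiling.

## Clustering

Features are z-scored with the training cohort's mean and *population*
(÷ n) standard deviation; both are stored in the model so a new patient is
transformed exactly as the training data were. K-means uses k-means++
seeding and Lloyd iterations (converged when assignments stop changing,
cap 300), with 50 independent restarts seeded deterministically from the
model seed (default 20220801) and the lowest-inertia restart kept. An
empty cluster is repaired by reseeding its centroid at the point farthest
from its assigned centroid. The test-suite verifies that the
best-of-restarts solution attains the global optimum (by enumeration of
all 2-partitions) on hundreds of small random instances, and that inertia
is non-increasing across Lloyd iterations.

The cluster count is chosen by the mean silhouette coefficient
s = (b − a)/max(a, b) (Euclidean distances, singleton clusters score 0),
maximized over candidate k with ties to the smallest k. On the default
synthetic cohort the silhouette peaks at k = 2 (≈ 0.54) and falls for
k ≥ 3.

K-means label order is arbitrary, so after fitting the centroids are
relabeled: the centroid with the lower mean of its standardized (kb, kc)
components becomes cluster **X** (code 0, descending mid-to-high
frequencies); the other becomes **Y** (code 1). Assignment of new patients
is nearest-centroid with exact ties going to X. Models persist as JSON
(standardization stats, centroids, label map, seed, n_init, inertia) and
are schema-validated on load; no binary pickles.

## Clinical rules

**Diagnostic definitions.** A patient meets a rule when some run of
`min_consecutive` consecutive frequencies shows a loss
(affected-pre minus contralateral) ≥ `min_loss` at every frequency:
20 dB / 2 frequencies (Chinese definition) or 30 dB / 3 frequencies
(international). The contralateral ear serves as the loss reference since
no premorbid audiogram exists. The comparison carries a 1e-9 tolerance
because thresholds live on a 0.01 dB grid and exact float subtraction
would spuriously fail at the boundary. The international rule dominates
the Chinese rule pointwise, so its cohort is provably a subset — asserted
as a property test rather than assumed.

**Audiogram typing** (affected ear, configurable cuts): profound if the
six-frequency mean ≥ 81 dB; else upsloping/downsloping if the
low-frequency triad mean differs from the high-frequency triad mean by
≥ 20 dB in the respective direction; else flat. These cuts are explicit
configuration, not hidden constants.

**Siegel-style grading.** With G = mean(pre) − mean(post) and
F = mean(post): complete recovery if F ≤ 25 dB; partial if G ≥ 15 dB and
F ∈ [25, 45]; slight if G ≥ 15 dB and F > 45; else no improvement
(defaults, all configurable). The implementation evaluates every grade's
predicate and returns the *worst* applicable grade. Because the regions
overlap only at shared boundaries, this reduces to the usual cascade
everywhere except exactly on a boundary — e.g. F = 25 with G ≥ 15
satisfies both the complete and partial definitions and is graded
partial — which is the intended conservative tie-break: ambiguous
audiometric progressions take the inferior classification. Grading is
monotone in the post audiogram (pointwise-better hearing never grades
worse), a property the suite checks on random audiograms.

**Efficacy metrics.** Mean threshold improvement (dB), cure rate
(fraction complete recovery) and improvement rate (fraction above
no-improvement); cure ≤ improvement always.

## Regression battery

The linear analysis regresses per-patient threshold improvement (dB) on:
cluster (indicator for Y, X reference), age (years), audiogram type
(indicators vs upsloping), side (right vs left), sex (female vs male).
OLS is solved by the normal equations; SEs from σ̂²(XᵀX)⁻¹ with
σ̂² = RSS/(n − p); two-sided p and 95% CI from the t distribution with
n − p df. Rank deficiency is reported with the offending columns (via
pivoted QR), not silently dropped. A useful identity, used as an
acceptance check: univariate OLS on a binary indicator equals the
difference of group means exactly.

The logistic analysis codes "no improvement" as 1 and uses the same
covariates except age enters as quartile classes (youngest quartile
reference; sample quartiles by linear interpolation, bins closed on the
right at interior boundaries). Estimation is IRLS/Newton with
step-halving, so the log-likelihood is non-decreasing per iteration;
convergence at gradient max-norm ≤ 1e-8 within 100 iterations. Constant
outcomes raise a degenerate-data error; (quasi-)separation is diagnosed
by diverging estimates (‖β‖∞ > 30) rather than returned silently. Wald z
inference; every term is also reported as OR = exp(β) with exponentiated
CI. On a 2×2 design the fitted OR equals the cross-product ratio — an
acceptance oracle.

Model building follows the univariate-screen rule: variables with
univariate p < 0.05 (minimum over a categorical variable's levels) enter
the multivariate model, in candidate order. In the orchestrated battery a
univariate fit that fails with a diagnostic error (e.g. separation on a
sparse type level) excludes that variable and is reported, instead of
aborting the analysis.

Group comparisons: pooled-variance Student's t (not Welch — the choice is
deliberate and documented); Mann–Whitney U by midranks with the
tie-corrected normal approximation and continuity correction, switching
to the exact null distribution (count recurrence) when the smaller sample
has ≤ 8 untied observations; Pearson chi-square without continuity
correction. p-value tail probabilities come from scipy's t, normal and χ²
distributions; the estimators themselves are in-package and cross-checked
against scipy/statsmodels in the tests.

## Synthetic cohorts

The generator emulates a USSNHL cohort with the latent structure the
pipeline assumes; defaults are the study conditions used throughout the
tests and the acceptance script.

* Latent class: Y with probability 0.75 (≈ 1:3 X:Y).
* Class slope means (dB/octave): X (−2, −15, −20), Y (0, −1, −1);
  between-patient slope sds (1.5, 3, 4). The X/Y separation lives almost
  entirely in (kb, kc), matching the intended interpretation that
  mid-to-high-frequency descent drives the stratification.
* Contralateral audiogram: a low-frequency anchor ~N(15, 6²) dB truncated
  to [0, 60], integrated across octaves so the three segment slopes equal
  the drawn slopes exactly (the 2000 Hz point continues line b across the
  1000→2000 Hz octave; the 8000 Hz point pins the three-point OLS slope;
  the 4000 Hz point pins the two-point step), plus i.i.d. N(0, 2.5²) dB
  noise per frequency, rounded to the 0.01 dB grid and clipped to
  [−10, 120] with ceiling hits recorded as censored. With all sds at 0
  the slope extractor inverts the generator exactly — a test.
* Affected ear (pre): contralateral reference plus a loss profile — one
  of four shape templates (upsloping/downsloping/flat/profound) or, with
  probability 0.23, a "mild" profile whose losses exceed 20 dB at exactly
  two consecutive frequencies but never reach 30 dB. Mild patients
  therefore meet the Chinese definition and fail the international one by
  construction, emulating a cohort whose stricter-criteria subset is
  proper. After adding noise the curve is lifted by any deficit so every
  patient meets the Chinese rule on the rounded values actually written.
* Outcome: improvement G = 27 + 10·1[Y] − 0.25·age + type effect
  (0 / −16 / +2 / +3 dB for up/down/flat/profound) + N(0, 12²) dB,
  applied as a uniform downward shift of the affected ear and clipped to
  the audiometric range. The type covariate entering the outcome model is
  the *classified* type of the generated audiogram, so truth and analysis
  covariates coincide. With age ≈ 50 the class means land near 15 dB (X)
  and 25 dB (Y) improvement, a clinically plausible gap.
* Ages uniform integers 18–82; sex and side Bernoulli(0.5). Everything
  derives from one seed; exports are byte-identical across runs.

### What the experiments show — and don't

On these conditions the pipeline recovers the latent classes with median
adjusted Rand index ≈ 0.96 over 20 cohorts of n = 200 (≥ 0.9 required),
and the multivariate OLS 95% CI covers the true +10 dB cluster effect in
~93 of 100 replicates at n = 300. Coverage sits below the nominal 95%
for a structural reason: the regressor is the *recovered* cluster, and
the ~2% misassignment rate attenuates the coefficient (classical
measurement-error bias), as does outcome clipping at the audiometric
floor for a few mild-loss patients. Both effects are small at the default
separation but would grow if the classes were moved closer together.

Passing these tests shows the machinery is correct and well calibrated
under the generator's assumptions — Gaussian slope scatter, piecewise
linear-in-octave audiograms, a uniform treatment shift, outcome
missingness absent. Real audiograms live on 5 dB steps, show
frequency-correlated noise, non-uniform recovery across frequencies, and
selection effects none of which the generator reproduces; results on
synthetic cohorts therefore validate the software, not the clinical
effect sizes.

## Problem sizes and numerical tolerances

Simulation studies use n = 200 × 20 seeds (cluster recovery),
n = 300 × 100 replicates (CI coverage) and 1000 null replicates at
n = 100 (calibration) — large enough for stable medians and binomial
margins, small enough that the whole suite runs in well under a minute.
Oracle agreement tolerances: slopes vs normal equations 1e-9; silhouette
vs brute force 1e-12; k-means inertia vs enumerated optimum 1e-8.
Degenerate inputs raise typed errors (zero-variance features, fewer
distinct points than clusters, constant outcomes, zero margins) rather
than propagating NaNs.

## Known limitations

* Slopes are fitted on the octave axis; a raw-Hz abscissa would change
  the numeric slope values (cluster geometry is affine-equivalent).
* The Siegel cut-offs and audiogram-type cuts are configurable defaults
  in the tradition of the criteria, not a transcription of any single
  guideline table.
* The logistic battery reports Wald inference; no exact or
  Firth-corrected logistic regression, and no multiplicity adjustment.
* The diagnostic rules judge loss against the contralateral ear; if that
  ear is itself impaired the rules are conservative.
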