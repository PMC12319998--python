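# Methods

This note documents the models the package fits, the synthetic data it
validates them on, the numerical choices behind both, and what the
passing test suite does and does not demonstrate.

## Denoising and run exclusion

Processing starts at the parcellated (node × time) level. Each run is
denoised by (1) least-squares regression of every node series on a
confound design — intercept, 6 rigid-body motion parameters, tissue
signals (white matter, CSF, global), the backward first differences of
both blocks, and a discrete-cosine drift basis — followed by (2) a
zero-phase (forward–backward) order-4 Butterworth low-pass at 0.1 Hz.
The order is fixed: regression first, filter second. Filtering only
afterwards means the regression sees confounds and data on the same
spectral support; the forward–backward application squares the magnitude
response (≈ −28 dB at 1.5× cutoff, unity passband) and introduces no
phase lag, so it cannot create spurious lead–lag structure in
correlations.

The drift basis uses DCT-II columns with periods ≥ 128 s (a conventional
high-pass boundary, configurable), giving k = ⌊2·N·TR/128⌋ columns;
columns are unit-normalized and mutually orthogonal. Rank-deficient
confound designs are reduced by pivoted-QR column selection before the
fit, and confound regression is idempotent by construction.

Run exclusion uses the mean frame-to-frame (relative) RMS displacement:
translations in mm plus rotations converted to arc length at a 50 mm
radius, Euclidean norm per frame transition, averaged over transitions.
A run is dropped when this mean is *strictly greater than* 0.25 mm; a
run exactly at the threshold is kept. Subjects need at least 3 valid
runs with matching questionnaire data to enter the analyses.

Working at the node level rather than voxelwise is an approximation:
parcellation averaging and linear regression commute exactly only when
every voxel in a parcel shares the confound fit. This keeps the package
desk-scale; volumetric preprocessing is out of scope.

## Connectivity representations

Per run, FC is the node × node matrix of pairwise Pearson correlations,
clamped to |r| ≤ 0.999999 (so degenerate inputs stay finite) and
Fisher-z transformed (atanh). The *fingerprint* is the strict lower
triangle in row-major order, with an explicit position → (i, j) index
map; vectorize/reassemble is an exact round trip. The *FNC* matrix
averages FC edges over network pairs; its diagonal is the mean over
distinct node pairs within a network (self-pairs excluded), undefined
(NaN, flagged) for single-node networks. With K networks there are
K(K+1)/2 unique entries — 36 for the default K = 8.

For cross-sectional analyses, runs are concatenated along time after
per-run, per-node z-scoring, so inter-run offsets in mean or scale
cannot masquerade as connectivity; FC is then recomputed from the
concatenated series.

## The random-intercept model

All within-subject analyses use

y_ij = β₀ + β₁ x_ij + u_i + ε_ij, u_i ~ N(0, σ²ᵤ), ε_ij ~ N(0, σ²).

Estimation is REML with the variance ratio λ = σ²ᵤ/σ² profiled out: for
fixed λ the GLS coefficients and residual variance are closed-form in
per-group sufficient statistics, leaving a bounded one-dimensional
minimization over log λ (λ ∈ [10⁻⁸, 10⁶], with the λ = 0 boundary
checked explicitly so the model degrades gracefully to OLS). Agreement
with an independent implementation (statsmodels `MixedLM`) is asserted
in the test suite to 10⁻⁶ on coefficients.

Inference on β₁ is a Wald test with a normal reference by default; a
residual-df t reference (df = N − groups − slopes) is available via
`use_t`. Satterthwaite/Kenward–Roger adjustments are deliberately not
implemented: at the group counts this package targets (≥ 40 subjects,
≥ 3 records each) the normal approximation is accurate, and the
calibration suite verifies the empirical type-I error at α = 0.05 over
200 null simulations.

Standardized coefficients are post-hoc rescalings β̂·σₓ/σᵧ with CI
endpoints transformed identically (refitting on z-scored data is the
alternative; post-hoc rescaling is deterministic given the fit and is
the common convention). R² follows Nakagawa–Schielzeth:
marginal = σ²_f/(σ²_f+σ²ᵤ+σ²), conditional = (σ²_f+σ²ᵤ)/(σ²_f+σ²ᵤ+σ²),
with σ²_f the variance of the fixed-effect predictions.

## CCA with a univariate outcome

The canonical pair comes from the SVD of the whitened cross-covariance
S_xx^(−1/2) S_xy / √S_yy; with a univariate outcome this is a single
vector whose norm is the canonical correlation, which equals the
multiple correlation R of the outcome on the predictor set (asserted
against a least-squares oracle to 10⁻⁸). Whitening uses an
eigendecomposition with a relative tolerance of 10⁻¹⁰; rank-deficient
sets fall back to pseudo-inverse whitening with a warning. The variate
is oriented to correlate positively with the outcome. Significance is
the F test of R² with (rank, n − rank − 1) df, equivalent to Wilks'
lambda in this rank-one setting.

Canonical-variate *scores* default to the product of the
column-standardized predictors with the structure loadings (the
correlations between each predictor and the variate). Scoring by
loadings rather than canonical coefficients is non-standard but is the
convention this pipeline mirrors; `mode="coefficients"` provides the
standard alternative, and both are tested. For correlated predictors
the two differ — loadings-based scores weight shared variance more
heavily — which slightly attenuates downstream path estimates (see
*Known limitations*).

## Mediation

Paths are standardized least-squares coefficients computed in
correlation form: A = r_xm, B = (r_my − r_xm r_xy)/(1 − r²_xm),
C = r_xy, C′ = (r_xy − r_xm r_my)/(1 − r²_xm). The decomposition
C = C′ + A·B is then an algebraic identity (asserted to 10⁻¹⁰). The
indirect effect A·B receives a percentile 95% CI from seeded
case-resampling bootstrap replicates (default 5000; the calibration
suite uses 1000 for runtime and flags it as scaled down), vectorized so
all replicates are computed in one pass. Significance is "CI excludes
zero"; a two-sided bootstrap p-value (twice the smaller tail proportion,
floored at 1/n_boot) is reported so FDR can be applied across
phenotypes. Percentile intervals were chosen over BCa as the simplest
defensible choice; the CI type is recorded in the result object.

## Multiple testing and phenotype screening

Benjamini–Hochberg step-up adjustment is applied within caller-declared
families: the 12 item-level fingerprint tests; one 36-edge family per
item in the network-correlate stage (not 432 pooled); and, across
phenotypes, one family per canonical variate's behavior correlations
plus one for the indirect effects. Degenerate p of exactly 0 or 1 pass
through unmodified. Phenotypes enter the cross-sectional stage only if
at least 90% of subjects have valid data (inclusive boundary);
analyses then use listwise-complete subjects per phenotype. Missing
behavior entries must be encoded as NaN.

## The synthetic generator

The generator emulates the statistical skeleton the analyses assume,
with every latent draw and coefficient recorded as ground truth:

* **Trait.** Each subject has t ~ N(0,1), expressed in FC as an
  additive Fisher-z offset (weight 0.25) on one nominated network-pair
  block (default net1–net2), on top of a common network structure
  (within-network r = 0.35, between 0.08) and a subject fingerprint
  (edge-wise N(0, 0.10²) in z-space).
* **States.** The subject's mean thought state is m = a·t + √(1−a²)·e
  (unit variance); run states add deviations with SD 1.0 that are
  *mean-centered within subject*, so the across-run average identifies
  m exactly. Only the centered deviations perturb FC (weight 0.25 on
  the disjoint net3–net4 block): the mean state therefore reaches
  behavior exclusively through the questionnaire route while
  concatenated-run FC carries only the trait. Without this, the FNC
  canonical variate absorbs the mediator and the planted paths are not
  identifiable — the package's own recovery experiments demonstrated
  exactly that failure mode.
* **Questionnaire.** Item j reads the state as λ_j·s + N(0, 1), mapped
  to the 0–100 grid by a normal-quantile (CDF) transform and rounding
  to the nearest 5 — matching the instrument's response grid while
  preserving rank structure. Default loadings make item 1 a clearly
  dominant, vigilance-like readout (λ₁ = 0.9 vs ≤ 0.45, mixed signs);
  item noise of the same order as the signal is what lets loading
  differences express themselves as detection-strength differences.
* **Behavior.** The `mediated` phenotype is c′·t + b·m̄ + noise with the
  noise variance set so the marginal variance is 1 (hence a, b, c′ are
  standardized paths and the planted indirect effect is a·b); defaults
  a = b = 0.4, c′ = 0.3. A `direct_only` control carries the same total
  effect c′ + a·b with no mediated component, and `null_pheno` is pure
  noise. Missingness is MCAR at 5% by default (an inclusion threshold
  is the only screening rule modeled; no informative mechanism).
* **Timeseries.** Runs are stationary Gaussian AR(1) processes
  (coefficient 0.4, unit marginal variance, 50 burn-in samples) colored
  by the Cholesky factor of the target correlation matrix; identical
  per-channel filtering leaves the instantaneous cross-correlation at
  its target, which ridge repair ((C+εI)/(1+ε), escalating ε) keeps
  positive definite. Defaults: 4 runs × 657 timepoints at TR = 1.4 s,
  50 nodes in 8 nearly balanced networks. One seed drives a
  `SeedSequence` tree (per-purpose and per-subject-run children), so
  regeneration is bit-identical.

What the generator does **not** emulate: physiological
(respiratory/cardiac) noise, motion artifacts, non-stationarity within
runs, spatial autocorrelation beyond the network block structure,
heavy-tailed questionnaire response styles, or informative missingness.
Passing recovery tests therefore show the *estimators* are correct and
calibrated under the assumed data-generating process — not that real
resting-state data satisfy those assumptions.

## Problem sizes used in the validation suites

The replicate experiments run at a reduced but structurally faithful
scale chosen for a single-CPU workstation: 164 subjects × 4 runs,
50 nodes, 120 timepoints per run, 100 replicate cohorts for the
mediation-recovery study (bootstrap 1000), 200 simulations for type-I
and coverage calibration, 500 families for FDR control. At this scale
the planted indirect effect (a·b = 0.16) is detected (FDR-corrected)
in every replicate, the mean estimate is ≈ 0.12–0.15, the pure-direct
control's CI covers zero ≈ 90–95% of the time, and type-I error and
bootstrap coverage sit inside their binomial bands.

## Known limitations

* **In-sample CCA chaining.** Canonical variates are fitted and scored
  on the same sample that feeds the mediation, so variate–behavior
  correlations are optimistically biased; with 36 predictors this is
  material below roughly n ≈ 3p (at n = 60 the pipeline produced
  spuriously significant indirect effects for control phenotypes,
  where at n = 164 it did not). The package mirrors the in-sample
  convention deliberately; cross-validated scoring would be the remedy
  but changes the estimand.
* **Attenuated indirect estimates.** Loadings-based CV scoring plus
  questionnaire quantization attenuate the recovered indirect effect
  by roughly 10–20% relative to the planted a·b; detection calibration
  is unaffected.
* **Overlapping contrasts.** Run-pair MADs sharing a run are dependent,
  and the random intercept does not model that dependence. The
  non-overlapping sensitivity rerun is provided as the remedy rather
  than a bespoke covariance correction.
* Wald-normal inference (no small-sample df correction), percentile
  (not BCa) bootstrap, MCAR-only missingness, and node-level (not
  voxelwise) confound regression, as discussed above.
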