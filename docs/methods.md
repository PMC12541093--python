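# Methods

This note documents the statistical machinery in `pdnorm`, the design
choices made where several defensible options existed, and what the bundled
synthetic cohorts do and do not establish about behaviour on real data.

## Warped Bayesian linear regression brain charts

Each region of interest (ROI) gets an independent normative model

    t_n = φ(y_n) = wᵀ φ(x_n) + ε_s,   ε_s ~ N(0, β_s⁻¹),   w ~ N(0, α⁻¹ I).

**Covariate basis.** `φ(x)` stacks a degree-3 B-spline expansion of age
(default 5 evenly spaced interior knots over the training age range — enough
to trace a lifespan rise-and-decline trajectory without chasing noise; the
count is configurable), a 0/1 sex column, and fixed-site indicator columns
in reference-cell coding (the first site is the baseline). The spline block
is a partition of unity, so no separate intercept is needed. Ages outside
the training domain are clipped to its boundary with a warning rather than
extrapolated, since extrapolating splines is unstable.

**Likelihood warp.** `φ(y)` is a sinh-arcsinh transform with an affine part,

    t = sinh( δ · asinh((y − ξ)/η) − ε ),

strictly increasing for η, δ > 0, reducing to an affine map at ε = 0, δ = 1
(the "identity warp" used wherever a plain Gaussian BLR is wanted). With the
warp off, ξ and η are fixed at the training mean and SD, so the latent space
is always roughly standardised regardless of whether the ROI is a ~2.5 mm
thickness or a ~10⁴ mm³ volume.

**Hyperparameter estimation.** α, the per-site β_s, and (warp on) the four
warp parameters are found by Powell's derivative-free minimisation of the
negative log marginal likelihood, which is available in closed form given
the warp (conjugate Gaussian algebra plus the warp's log-Jacobian). Three
seeded restarts are run with jittered starts; the best optimum wins; an
optimisation that never reports convergence raises an error carrying the
best state found. Tolerance 1e-6, log-scale parameterisation of α and β_s
with clipping at e±20 for numerical safety.

**Canonicalisation of the warp.** The warp's affine part and the latent
Gaussian's location/scale are jointly near-redundant: moving (ξ, η) can be
almost exactly compensated by (w, β), producing a flat likelihood ridge
along which the *distributional* fit barely changes but the individual warp
parameters wander. Two consequences were observed at n = 5000: the fitted
(ε, δ) could land far from the generative values at a marginal likelihood
*better* than the truth's, while calibration stayed perfect. Fitting
therefore adds a small penalty `λ (mean(t)² + log² sd(t))` (λ = 20) on the
warped response, pinning the latent space to zero mean and unit SD. This
selects the canonical point on the ridge — the convention in which the
generator's latent residuals are exactly N(0,1) — making warp parameters
identifiable and reportable; the stored marginal likelihood is the pure
(unpenalised) value at the optimum. An alternative would have been to fix
(ξ, η) at data moments and fit only (ε, δ); that restores identifiability
too, but places the generative truth outside the model class whenever the
response is skewed, which breaks tail calibration. The penalty keeps both.

**Scoring.** Deviation scores are computed in the latent space:
`z = (t − ŷ) / sqrt(σ_d² + σ*²)` with `σ_d² = 1/β_s` for the record's site
and `σ*² = φ(x)ᵀ A⁻¹ φ(x)` from the posterior weight covariance. Centile
curves at level q are the inverse warp of `ŷ + Φ⁻¹(q)·sqrt(total variance)`;
monotonicity of the warp guarantees non-crossing curves, and an observation
lying on the q-curve scores exactly `Φ⁻¹(q)` (round-trip property, tested).

## Site adaptation

A fitted reference model is moved to an unseen site using held-out controls
from that site. Controls are split 50–50 **by subject** (both visits travel
together, preventing visit-level leakage); with an odd count the extra
subject goes to the test half, favouring evaluation power. In the latent
space, the adaptation offset is the mean control residual against the
reference prediction (new-site design rows use reference-cell coding with a
zero site block) and the variance scale is the ratio of the controls'
residual variance to the model-predicted total variance; predictions at the
site add the offset and multiply the total variance by the scale. Fewer than
5 adaptation subjects triggers a warning (the estimates are noisy, SE ≈
n⁻¹ᐟ²); a single record fixes the offset and falls back to scale 1.
Adaptation and test subject sets are enforced disjoint.

## Longitudinal z-diff

For a subject with visits 1 and 2, the numerator is the change in latent
residual against the age-appropriate adapted prediction — so the expected
drift along a centile is subtracted out and a centile-tracking subject
scores ≈ 0. The denominator is, per ROI, the empirical SD of the same
quantity across control pairs, taken **from the adaptation subset** so test
controls remain held out for calibration checks. This empirical-denominator
construction captures measurement noise and within-subject correlation
without needing the reference model's internal noise split; whether the
method's formal version adds an explicit model-uncertainty term is left
open, and the empirical denominator is the documented behaviour here. At
least 5 control pairs are required (below that the denominator is too
unstable to interpret); subjects missing a visit are skipped and listed.
z-diff is not rescaled per year by default — the emulated design has a fixed
~2-year interval — but an `annualize` flag divides each change by its own
interval.

## Downstream statistics

Bought, not built: Mann–Whitney U, Wilcoxon signed-rank, Kruskal–Wallis and
Spearman come from scipy.stats; BH-FDR from statsmodels; PCA from
scikit-learn. Choices on top of them:

* **Extreme deviations**: boundary inclusive (|z| ≥ 1.96, the threshold
  implied by the 2.5th/97.5th tail centiles); counts reported per direction
  and per visit; cortical and subcortical ROIs pooled in the count, with
  per-atlas breakdowns available from the same matrices.
* **Case–control count test**: one-tailed (patients > controls for negative
  counts — the atrophy direction), exact enumeration for tie-free groups of
  ≤ 20, tie-corrected normal approximation otherwise; an all-tied input is
  flagged degenerate with p = 0.5 rather than erroring.
* **Signed change maps**: per-ROI Wilcoxon of z-diff against zero, sign
  taken from the median direction, BH across all ROIs in the map.
* **PCA**: columns centred but not re-standardised (they are already z
  scores; a flag exists for sensitivity analysis); deterministic
  orientation: the largest-|loading| entry of each component is made
  positive. Component counts default to 3 (cross-sectional) and 8
  (longitudinal); a maximum-curvature elbow pick is available and recorded
  in the decomposition.
* **BH family**: all (component × measure) tests within one analysis run
  form one declared family; zero-variance measures are flagged and excluded
  from the family with a note in the report.
* **Subtype contrast**: Kruskal–Wallis with tie correction, then Dunn's
  pairwise z with tie-corrected variance and Bonferroni over all C(k, 2)
  pairs among included groups (the pair count is recorded). The 'undefined'
  group participates by default since its missingness may be informative;
  it can be excluded by flag.
* **Dunn's test is hand-written** (no suitable pre-installed implementation)
  and cross-checked against the Kruskal–Wallis ↔ squared rank-sum-z identity
  in the two-group tie-free case.

## Euler-characteristic QC

The scan-quality filter excludes a subject when, at any visit, the
site-normalised Euler statistic `|EC − site median| / (1.4826 · MAD)`
exceeds the cutoff (default 5). Median/MAD normalisation is scale-free and
robust to the very outliers the filter hunts; the variant is configurable.
Sites with fewer than 3 records are passed through with a warning — a
robust scale cannot be estimated there. Exclusion order is QC first, then
the both-visits completeness requirement; both reports conserve record
counts and the cascade is idempotent.

## The synthetic cohorts

`generate_reference` emulates a multi-site lifespan reference sample: per
ROI, a cubic-spline mean trajectory through control points (childhood peak
between ages 7–12, monotone decline thereafter; thickness peaks 2.4–3.1 mm
with residual SD 0.10–0.18 mm, volumes 1.6–20 × 10³ mm³ with 7% residual
SD), an additive sex effect, per-site offsets (SD 0.3 residual-SD) and
noise multipliers (±20%). Residuals are generated by pushing N(0,1) noise
through the inverse of the engine's own warp family — `y = W⁻¹(W(mean) + g)`
— so the model class contains the generative truth exactly and
parameter-recovery tests are well-posed. With skew 0 this is the plain
additive model. Euler characteristics are dispersed integers (site base −
Poisson(6)); their natural spread stays below the QC cutoff so that the
*configured* failure plan alone determines exclusions, and injected failures
(base − 600) supply the heavy tail the filter works on.

`generate_clinical` draws a two-visit cohort at one new site mirroring the
emulated study: 457 patients + 56 controls in, with 18 injected Euler
failures and 34 single-visit subjects placed so that exactly 408 patients
and 53 controls with the configured subtype counts (191 MMP / 135 IM /
39 DM / 43 undefined) survive QC. Patient measures carry a baseline shift
(−0.3 SD, heterogeneity 0.2) plus subtype-specific annualised decline in SD
units — DM 0.25 > IM 0.15 > MMP 0.08, undefined 0.12 — amplified ×2.5 in
the caudate/putamen focus structures. The unit residual splits into a
subject random intercept (SD 0.8) and visit noise (SD 0.6), giving a
control change SD of ≈ √2·0.6 ≈ 0.85 latent units; by design calculation
the DM caudate then drifts ≈ −1.5 control-SD over two years, an extreme
z-diff overlap of roughly 30–40% against under 10% for MMP, which is the
regime the subtype contrast is meant to resolve. Clinical scores hang off a
latent atrophy factor (the negated subject intercept plus a subtype
severity shift): MoCA with a link coefficient of 1.2 points/SD and noise SD
1.8, UPDRS III items as Binomial(4, p) draws whose base probabilities
reproduce visit totals of 31.75 → 37.76, shifted by 0.05/SD of severity.
Item-level correlation structure beyond the shared factor is not modelled
and is treated as a free parameter of the spec. The 'undefined' subtype
masks MoCA and/or UPDRS fields (non-random missingness). The latent factor
is exported in the table (`latent_atrophy`) as generator ground truth for
testing.

**What passing tests show — and don't.** The generator's ROIs are
conditionally independent given the subject intercept, its residuals are
exactly in the model family, and its site effects are additive in the
latent space. Calibration, recovery and power results under these
conditions validate the machinery, not the biology: real morphometry has
spatially correlated residuals (stronger than a single shared factor),
scanner effects that are not purely location/scale, age-varying skew, and
QC failures correlated with disease severity. None of those features are
claimed to be handled beyond what the model class expresses.

## Problem sizes and numerical choices

Simulation-based tests run at desk scale, chosen so the full suite and the
acceptance script each finish in minutes on one CPU core: reference
cohorts of 1500–2500 subjects, 10–12 ROIs, 500 held-out controls, 100
control pairs, 20-seed repetitions for the stochastic claims. Degenerate
inputs have defined behaviour throughout (empty cohorts keep their header;
zero-spread Euler sites exclude no one; all-tied rank tests flag
degeneracy; zero-baseline percent changes are missing, not infinite).
Floating-point ties in splits and sign conventions are resolved by seeded
RNGs and deterministic rules, so equal configs reproduce byte-identical
pipeline outputs.

## Known limitations

* One model per ROI: no spatial pooling or multivariate normative model.
* Site adaptation is location/scale only; nonlinear scanner effects remain.
* Two visits only; no ≥3-visit trajectory modelling.
* The subtype labels are inputs; the package does not derive them.
* The warp canonicalisation penalty trades a vanishing amount of marginal
  likelihood for identifiability; on heavily mis-specified data the
  reported warp parameters should be read as the canonical-form fit, not as
  estimates of a "true" warp.
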