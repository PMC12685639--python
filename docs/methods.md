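# Methods

## The random-intercept mixed model

All cohort-side estimates come from the Gaussian linear mixed model
with one subject-level random intercept,

    y_ij = x_ij' β + b_i + e_ij,   b_i ~ N(0, σ²_subject),
                                   e_ij ~ N(0, σ²_resid),

for subject i at visit j. Writing the marginal covariance as
σ²_resid·(I + λ Z Z') with λ = σ²_subject/σ²_resid, the REML criterion
is profiled down to a one-dimensional function of λ and minimised by
bounded search on log λ over [1e-10, 1e6] (`scipy.optimize.
minimize_scalar`, xatol 1e-10); β then follows by generalized least
squares at λ̂, with cov(β̂) = σ̂²_resid (X'Λ⁻¹X)⁻¹. The boundary λ → 0
is evaluated explicitly and reported as σ²_subject = 0 exactly, where
the fit coincides with pooled OLS. The criterion and all solves are
computed from per-subject cross-products (X'X, X'y, y'y per group),
pooled by group-size class, so one objective evaluation costs O(K p²)
with K ≤ 7 distinct visit counts.

Inference on fixed effects is Wald with a normal reference. With
roughly a thousand subjects the difference from Satterthwaite or
Kenward–Roger degrees of freedom is negligible; the joint Wald
chi-square on a coefficient block is used for trend, interaction and
spline tests. Likelihood-ratio alternatives are deliberately out of
scope.

Inclusion rule: subjects need at least two outcome measurements to
enter any fit; rows are complete-case filtered per fitted model
(covariate missingness handling is complete-case, logged, as no
imputation layer is provided). Subjects failing the rule stay in the
parsed table so the exclusion is auditable.

### Restricted cubic splines

`rcs_basis` implements the restricted (natural) truncated-power basis:
k knots give k−1 columns — the identity plus k−2 cubic terms that are
constrained linear beyond the boundary knots and normalised by
(t_k − t_1)². Default knots sit at conventional quantiles
(0.05, 0.35, 0.65, 0.95 for the default k = 4); no knot scheme is
standard for this analysis, so the choice is a package default, not a
claim. The nonlinearity test is the joint Wald test on the nonlinear
columns under the full covariate model.

### Dose–response layer

Exposure codings: continuous log10-cortisol; baseline quartiles at the
empirical 25/50/75 percentiles (ties assigned to the lower quartile);
the trend test enters the quartile index 1–4 as a single ordinal
regressor (the analysis this emulates does not define its trend
construction; this is the most common choice); high-vs-low contrasts
Q3∪Q4 against Q1∪Q2. Benjamini–Hochberg adjustment is applied within
the family of exposure rows of one model — the family definition is a
package decision and is recorded in every output. The per-window
ANOVA regresses baPWV on quartile indicators plus continuous
follow-up time within each window (baseline, (0.5,1.5], (1.5,2.5],
>2.5 years by default) and F-tests the quartile block; windows with
fewer than two quartile groups are marked not testable.

## Mediation

Per candidate mediator M, three mixed models: step 1, M on exposure
plus covariates (β₁); step 2, outcome on M plus exposure plus
covariates (β₂); and the total-effect model without M (β₃). Step 2
runs only when the step-1 exposure coefficient is significant at α
(the gate). Indirect effect β₁β₂; mediated proportion 100·β₁β₂/β₃.

Two reporting rules, both design decisions of this package:

* When the mediator is itself a blood-pressure variable (SBP, DBP,
  MAP), mean arterial pressure is removed from the adjustment set of
  all three models, so the blood-pressure path is not conditioned on
  itself.
* The mediated proportion — a ratio — is reported only when the total
  effect is significant at α. When β₃ is statistically
  indistinguishable from zero the ratio is numerically unstable and
  scientifically undefined as an "effect share" (a single replicate
  with β₃ ≈ 0.04 produced a proportion of 342% in validation runs);
  the indirect effect itself is reported whenever the gate passes.

Uncertainty comes from a subject-level (cluster) bootstrap, B = 1000
by default with percentile intervals: whole subjects are resampled
with replacement and all three models refitted per replicate, which
respects the within-subject correlation without distributional
assumptions about the product term. Refits reuse the per-subject
cross-products — a resampled subject drawn twice contributes as two
independent clusters with identical data, which is algebraically the
same as refitting on the stacked rows. Intervals are reported only
when at least 200 usable replicates exist; replicates with
non-convergent fits are dropped and counted, and a result with more
than 10% dropped is flagged unreliable. The bootstrap p-value is
2·min(P̂(indirect ≤ 0), P̂(indirect ≥ 0)). A mediator whose indirect
effect opposes the total effect is flagged as masking. Only
single-mediator models are fitted; no multiple-mediator decomposition
and no exposure–mediator interaction formulas.

## Two-sample MR

Harmonization matches on rsid and aligns the outcome table's effect
allele to the exposure's: identical pairs kept, swapped pairs
sign-flipped with mirrored frequency, opposite-strand pairs
complemented first. Palindromic (A/T, C/G) variants are orientable
only through allele frequencies: both sides must be present with
minor-allele frequency below 0.42; concordant frequencies keep the
nominal alignment, discordant ones flip it, anything else is dropped
as ambiguous. The audit table records an action per input rsid, and
harmonization is idempotent.

IVW pools per-SNP Wald ratios with weights β²_exp/se²_out —
equivalently origin-constrained weighted least squares of outcome on
exposure betas. The default model is multiplicative random effects:
the fixed-effect SE is inflated by max(1, √(Q/(k−1))) and never
deflated, the standard choice when heterogeneity may be present.
MR-Egger re-orients rows so every exposure beta is nonnegative (the
slope/intercept split is otherwise unidentified), fits the
free-intercept weighted regression, inflates SEs by
max(1, √(RSS/(k−2))) and uses a t reference with k−2 degrees of
freedom — appropriate because cortisol analyses may run on as few as
three instruments; IVW p-values use the normal. Cochran's Q needs two
kept SNPs, Egger three. Instrument strength is the per-SNP
F = (β/se)², flagged weak at mean F ≤ 10. Weighted-median/mode
estimators, MR-PRESSO and Steiger filtering are out of scope, as is
LD-aware instrument selection (instrument lists are inputs).

Two-step MR mediation composes three univariable IVW stages — total
(exposure→outcome), A (exposure→mediator), B (mediator→outcome) — each
on an independently harmonized set, gating stage B on stage-A
significance. The mediated effect is βA·βB (βB on the log-odds scale
for binary outcomes) with delta-method SE √(βA²se²_B + βB²se²_A); the
delta method rather than a bootstrap because the inputs are summary
statistics. No mediated proportion is reported on the odds-ratio
scale: the odds ratio is non-collapsible, so the product and the total
are not on commensurate scales for a ratio.

## Synthetic data

The cohort generator emulates a diabetes-clinic follow-up study:
n subjects (default 1,200) with 2–8 visits over ~5.5 years, a
lognormal baseline cortisol truncated to 5–22.5 µg/dl (ln-scale mean
2.47, SD 0.32 — median ≈ 11.8 µg/dl, matching the interquartile span
of published cohorts of this kind), time-varying mediators linear in
log10-exposure with subject- and visit-level noise, and an outcome

    y = baseline + β_direct·log10(X) + Σ_m γ_m·M_m + β_time·t
        + b_subject + e,

where each γ_m is sized so the product-path indirect effect equals the
requested fraction of the total effect exactly — the ground truth
object carries the implied indirect effects and proportions by
construction. Noise defaults (σ_subject = σ_resid = 1.0 m/s) are
calibrated so a cohort of ~1,200 subjects estimates the continuous
exposure effect with a standard error near 0.22 m/s, the precision a
real cohort of that size reports; mediator path strengths (e.g. SBP
slope 10 mmHg per log10 unit) are sized to be clearly detectable at
that n, the regime in which two-step mediation is run at all.
Covariates (age, sex, lipids, lifestyle categories, agent use) are
drawn with realistic prevalences but have zero outcome effects unless
set — confounding is opt-in, so default runs measure estimator
behaviour under a correctly specified model. What the generator does
not emulate: measurement error in the exposure, informative visit
timing or dropout, covariate–outcome confounding unless requested, and
real biological nonlinearity; passing recovery tests therefore
validates the estimators, not the robustness of any real-data
conclusion.

The GWAS generator emits exposure/mediator/outcome summary triplets
for k independent instruments (no LD, as after clumping): per-SNP
exposure effects sized to a requested per-SNP R² (so F ≈
R²(n−2)/(1−R²)), standard errors from the two-sample approximation
se ≈ 1/√(2f(1−f)n), mediator and outcome true effects linear in the
exposure effect through paths A and (direct + A·B), per-SNP slope
heterogeneity with SD `heterogeneity_sd` (zero keeps Cochran's Q
chi-square calibrated), directional pleiotropy as a constant shift
`pleiotropy_mean` of mediator- and outcome-stage betas, and a
configurable fraction of palindromic allele pairs to exercise
harmonization.

## Numerical and reproducibility notes

- All randomness derives from one master seed through keyed
  `SeedSequence` substreams; the same `RunConfig` reproduces every
  number, bootstrap intervals included, and CLI stages are
  byte-identical under reruns.
- REML agrees with the balanced-design ANOVA moment estimators and
  with an independent mixed-model implementation to ~1e-8 in
  validation; the optimizer boundary is reported as exactly 0 with a
  logged note.
- Rank-deficient designs fail fast, naming the collinear columns (QR
  diagnostic); degenerate inputs (constant exposure for splines,
  fewer than four distinct values for quartiles, fewer than two
  subjects) raise targeted errors rather than fitting.
- Validation problem sizes: exposure-effect recovery uses 200
  cohorts of 2,000 subjects; mediated-proportion recovery 100 cohorts
  of 2,000 subjects with B = 500 bootstrap replicates; gate and Q
  calibration 1,000 replicates each; two-step MR null coverage 500
  triplets. These sizes put Monte-Carlo error comfortably below the
  tolerances they are checked against while keeping a full validation
  run in the minutes range.
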