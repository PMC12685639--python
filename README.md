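# cortmed

Repeated-measures association, mixed-model mediation, and two-step
Mendelian randomization (MR) for studying how morning serum cortisol
relates to arterial stiffness — with synthetic-data generators so that
every stage of the pipeline can be exercised and validated without
access to individual-level cohort or biobank data.

The package is aimed at biostatisticians and epidemiologists analysing
longitudinal cardiometabolic cohorts: repeated brachial-ankle pulse
wave velocity (baPWV, m/s) outcomes, a baseline hormonal exposure, and
candidate mediators such as blood pressure, together with GWAS
summary statistics for the genetic arm of the same question.

## What it computes

**Cohort arm.** A Gaussian linear mixed model with a subject-level
random intercept,

    y_ij = x_ij' β + b_i + e_ij,    b_i ~ N(0, σ²_subject),
                                    e_ij ~ N(0, σ²_resid),

estimated by REML with the variance ratio λ = σ²_subject/σ²_resid
profiled out and optimised in one dimension. On top of this engine:

- dose–response tables for log10-exposure (continuous, baseline
  quartiles, trend, high-vs-low) across a crude / Model 1 / Model 2
  covariate ladder, with Benjamini–Hochberg adjustment;
- interaction scans, restricted-cubic-spline nonlinearity tests,
  per-follow-up-window ANOVA and leave-one-out sensitivity refits;
- two-step mediation: β₁ (exposure→mediator), β₂ (mediator→outcome
  adjusted for exposure), β₃ (total effect); the indirect effect is
  β₁β₂, the mediated proportion 100·β₁β₂/β₃, with uncertainty from a
  cluster bootstrap that resamples whole subjects.

**Genetic arm.** Two-sample MR from summary statistics: allele
harmonization (including frequency-based handling of palindromic
variants), per-SNP Wald ratios, inverse-variance-weighted (IVW)
pooling, MR-Egger slope and intercept, Cochran's Q, instrument-strength
F-statistics, and two-step MR mediation (total effect, direct effects
A and B, and the mediated product βA·βB with a delta-method SE).

## Worked example

```python
import cortmed as cm
from cortmed.lmm import DesignSpec

params = cm.SynthCohortParams(n_subjects=1200,
                              mediated_fraction_per_mediator={"sbp": 0.19})
table, truth = cm.generate_cohort(params, seed=11)
table = cm.derive_variables(table)           # MAP, log10 exposure

spec = DesignSpec(outcome="bapwv", continuous=["log10_cortisol", "visit_time"])
print(cm.fit_lmm(table, spec).summary())
```

```
Random-intercept LMM (REML)
  n_obs=6012  n_subjects=1200  converged=True
  sigma2_subject=1.02583  sigma2_resid=1.03412  llf=-9671.7864
                estimate     se       z      p  ci_lower  ci_upper
Intercept        14.2990 0.2762 51.7742 0.0000   13.7577   14.8403
log10_cortisol    0.6669 0.2560  2.6054 0.0092    0.1652    1.1687
visit_time        0.3377 0.0079 42.8552 0.0000    0.3222    0.3531
```

Each unit increase in log10-cortisol raises baPWV by an estimated
0.67 m/s (95% CI 0.17–1.17) — the generator was built with a true
total effect of 0.67, which the fit recovers. Mediation through
systolic blood pressure:

```python
cfg = cm.RunConfig(seed=11, n_bootstrap=1000)
res = cm.LMEMediation(table, ["sbp"], spec, "log10_cortisol", cfg).fit()
print(res.summary())
```

```
mediator   beta1  beta1_p  gate_passed  beta2  beta2_p  beta3  ...  proportion_pct  proportion_ci_lower  proportion_ci_upper  bootstrap_p
     sbp 10.3368   0.0004         True 0.0148   0.0000 0.6669  ...         23.0026               9.4019              91.3598       0.0000
```

The exposure moves SBP by 10.3 mmHg per log10 unit (β₁), SBP moves
baPWV by 0.015 m/s per mmHg (β₂), and the product path accounts for an
estimated 23% (bootstrap 95% CI 9–91%) of the total effect — the
generating truth was 19%. The same `RunConfig` seed always reproduces
these numbers exactly, bootstrap intervals included.

The MR arm runs from summary tables alone (`cm.TwoSampleMR`,
`cm.two_step_mr`) and reports IVW odds ratios, Egger intercepts,
Cochran's Q and the mediated product; `cortmed --help` exposes all six
pipeline stages (`simulate-cohort`, `simulate-gwas`, `cohort-assoc`,
`mediate`, `mr`, `mr-mediate`) as shell commands.

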