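"""Synthetic cohort and GWAS-summary generators with known ground truth.

The cohort generator emulates a diabetes-clinic follow-up study: ~1,200
subjects, 2-8 visits each, a baseline morning-cortisol exposure
(lognormal, truncated to roughly 5-22.5 ug/dl), time-varying
blood-pressure mediators, a subject-level random intercept on the
arterial-stiffness outcome (baPWV, m/s) and a positive total exposure
effect partially routed through the mediators.

The GWAS generator emits per-SNP summary triplets (exposure, mediator,
outcome) with configurable instrument strength, heterogeneity and
directional pleiotropy, for exercising the two-sample MR stack.
Instruments are independent (as after LD clumping) and no
individual-level genotypes are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import CohortTable, GwasSummary, spawn_rng

# Mediator effect-scale defaults: slope of the mediator on log10-exposure,
# in mediator units per log10 unit (blood pressure in mmHg).  Sized so a
# cohort of ~1,200 subjects detects the exposure-mediator path clearly,
# the regime in which two-step mediation is run at all.
_DEFAULT_MEDIATOR_SLOPES = {"sbp": 10.0, "dbp": 5.0, "vfa": -8.49, "bmi": 1.0}
_MEDIATOR_BASELINES = {"sbp": 130.1, "dbp": 76.1, "vfa": 108.6, "bmi": 26.2}
_MEDIATOR_SUBJECT_SD = {"sbp": 12.0, "dbp": 8.0, "vfa": 14.0, "bmi": 3.8}
_MEDIATOR_VISIT_SD = {"sbp": 8.0, "dbp": 5.0, "vfa": 10.0, "bmi": 0.8}


class ParameterError(ValueError):
    """Generative parameters are internally inconsistent."""


@dataclass
class SynthCohortParams:
    """Generative settings for the longitudinal cohort.

    ``beta_total`` is the total exposure effect on the outcome per unit
    log10-exposure (m/s); ``mediated_fraction_per_mediator`` routes the
    stated fraction of that total through each mediator via a
    product-of-paths construction, so the implied indirect effect is
    fraction * beta_total by design.  Covariate effects on the outcome
    default to zero, making confounding opt-in.
    """

    n_subjects: int = 1200
    visits_min: int = 2
    visits_max: int = 8
    beta_total: float = 0.67
    mediated_fraction_per_mediator: dict = field(default_factory=lambda: {"sbp": 0.19})
    mediator_slopes: dict = field(default_factory=dict)
    sigma_subject: float = 1.0
    sigma_resid: float = 1.0
    beta_time: float = 0.33
    outcome_baseline: float = 15.0
    exposure_logmean: float = 2.47  # natural-log scale; median ~ 11.8 ug/dl
    exposure_logsd: float = 0.32
    exposure_range: tuple = (5.0, 22.5)
    followup_years: float = 5.5
    covariate_effects: dict = field(default_factory=dict)
    mediator_noise_scale: float = 1.0  # scales mediator subject/visit SDs

    def __post_init__(self) -> None:
        if self.visits_min < 2 or self.visits_max < self.visits_min:
            raise ParameterError("need visits_max >= visits_min >= 2")
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ParameterError("noise SDs must be nonnegative")
        total_frac = sum(self.mediated_fraction_per_mediator.values())
        if not -1.0 <= total_frac <= 1.0:
            raise ParameterError("sum of mediated fractions must lie in [-1, 1]")
        unknown = set(self.mediated_fraction_per_mediator) - set(_DEFAULT_MEDIATOR_SLOPES)
        if unknown - set(self.mediator_slopes):
            raise ParameterError(f"no effect scale for mediators: {sorted(unknown)}")


@dataclass
class SynthGwasParams:
    """Generative settings for a summary-statistic triplet.

    ``true_beta_exposure_mediator`` is the causal path A (mediator units
    per exposure unit), ``true_beta_mediator_outcome`` path B and
    ``true_direct_effect`` the unmediated path, both on the log-odds
    scale for the binary outcome.  ``instrument_strength`` is the
    per-SNP exposure variance explained (R^2), which with the exposure
    sample size fixes the expected F-statistic.
    """

    n_instruments: int = 50
    true_beta_exposure_mediator: float = 0.6
    true_beta_mediator_outcome: float = 0.005
    true_direct_effect: float = 0.002
    pleiotropy_mean: float = 0.0
    heterogeneity_sd: float = 0.0
    instrument_strength: float = 0.002
    n_exposure: int = 12597
    n_mediator: int = 100000
    n_outcome: int = 100000
    palindromic_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ParameterError("n_instruments must be >= 1")
        if self.heterogeneity_sd < 0:
            raise ParameterError("heterogeneity_sd must be >= 0")
        if not 0 < self.instrument_strength < 1:
            raise ParameterError("instrument_strength is a per-SNP R^2 in (0,1)")


@dataclass
class GroundTruth:
    """All generative parameters plus the quantities they imply."""

    params: dict
    true_total_effect: float = 0.0
    true_direct_effect: float = 0.0
    true_indirect: dict = field(default_factory=dict)
    true_mediated_proportion: dict = field(default_factory=dict)
    mediator_slopes: dict = field(default_factory=dict)
    mediator_outcome_effects: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _truncated_lognormal(rng, n, logmean, logsd, lo, hi):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(logmean, logsd, size=2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(params: SynthCohortParams, seed: int):
    """Simulate a long-format cohort table.

    Returns ``(CohortTable, GroundTruth)``.  The outcome is

        y = baseline + beta_direct * log10(exposure) + sum_m gamma_m * M
            + beta_time * t + covariate terms + b_subject + noise,

    with each mediator M generated as slope_m * log10(exposure) plus
    subject- and visit-level noise, so the product-path indirect effect
    through mediator m equals fraction_m * beta_total exactly.
    """
    rng = spawn_rng(seed, 1)
    n = params.n_subjects
    slopes = dict(_DEFAULT_MEDIATOR_SLOPES)
    slopes.update(params.mediator_slopes)

    fractions = params.mediated_fraction_per_mediator
    gamma = {}  # mediator -> outcome coefficient
    for m, frac in fractions.items():
        if frac == 0:
            gamma[m] = 0.0
        elif slopes[m] == 0:
            raise ParameterError(f"mediator {m} has zero exposure slope but nonzero fraction")
        else:
            gamma[m] = frac * params.beta_total / slopes[m]
    beta_direct = params.beta_total * (1.0 - sum(fractions.values()))

    exposure = _truncated_lognormal(
        rng, n, params.exposure_logmean, params.exposure_logsd, *params.exposure_range
    )
    lx = np.log10(exposure)
    lx_c = lx - lx.mean()

    visits = rng.integers(params.visits_min, params.visits_max + 1, size=n)
    subj_int = rng.normal(0.0, params.sigma_subject, size=n)

    # baseline covariates (prevalences mirror a diabetes-clinic population)
    age = rng.normal(54.3, 11.3, n)
    sex = (rng.random(n) < 0.653).astype(int)  # 1 = male
    diabetes_duration = np.clip(rng.normal(106.8, 93.2, n), 0, None)
    sfa = np.clip(rng.normal(193.6, 68.0, n), 40, None)
    waist = rng.normal(93.7, 10.3, n)
    hip = rng.normal(99.0, 8.0, n)
    ldl = np.clip(rng.normal(2.89, 0.94, n), 0.5, None)
    hba1c = np.clip(rng.normal(7.86, 1.77, n), 4.5, None)
    tc = np.clip(rng.normal(4.04, 0.75, n), 1.5, None)
    tg = np.clip(rng.lognormal(0.45, 0.6, n), 0.2, None)
    hdl = np.clip(rng.normal(1.18, 0.31, n), 0.4, None)
    fbg = np.clip(rng.normal(8.52, 3.05, n), 3.0, None)
    smoking = rng.choice(
        ["current", "former_le12mo", "never_or_gt12mo"], size=n, p=[0.2375, 0.0353, 0.7272]
    )
    drinking = (rng.random(n) < 0.119).astype(int)
    sleep = rng.choice(["lt7", "7to9", "gt9"], size=n, p=[0.164, 0.706, 0.130])
    cvd_history = (rng.random(n) < 0.156).astype(int)
    antihyp = (rng.random(n) < 0.421).astype(int)
    lipidlow = (rng.random(n) < 0.254).astype(int)
    covs = {
        "age": age,
        "sex": sex,
        "diabetes_duration": diabetes_duration,
        "sfa": sfa,
        "waist": waist,
        "hip": hip,
        "ldl": ldl,
        "hba1c": hba1c,
        "tc": tc,
        "tg": tg,
        "hdl": hdl,
        "fbg": fbg,
        "drinking": drinking,
        "cvd_history": cvd_history,
        "antihypertensive": antihyp,
        "lipidlowering": lipidlow,
    }

    # mediators: subject-level mean linear in log10-exposure, redrawn per visit
    med_names = ["sbp", "dbp", "vfa", "bmi"]
    med_subject = {}
    for m in med_names:
        med_subject[m] = (
            _MEDIATOR_BASELINES[m]
            + slopes[m] * lx_c
            + rng.normal(0.0, params.mediator_noise_scale * _MEDIATOR_SUBJECT_SD[m], n)
        )

    subj_index = np.repeat(np.arange(n), visits)
    n_rows = len(subj_index)
    # visit times: baseline 0 then sorted uniform over the follow-up window
    times = np.zeros(n_rows)
    pos = 0
    for i in range(n):
        k = visits[i]
        t = np.sort(rng.uniform(0.5, params.followup_years, size=k - 1))
        times[pos + 1 : pos + k] = t
        pos += k

    med_visit = {}
    for m in med_names:
        med_visit[m] = med_subject[m][subj_index] + rng.normal(
            0.0, params.mediator_noise_scale * _MEDIATOR_VISIT_SD[m], n_rows
        )

    linpred = (
        params.outcome_baseline
        + beta_direct * lx_c[subj_index]
        + params.beta_time * times
        + subj_int[subj_index]
    )
    for m, g in gamma.items():
        linpred = linpred + g * (med_visit[m] - _MEDIATOR_BASELINES[m])
    for name, eff in params.covariate_effects.items():
        linpred = linpred + eff * np.asarray(covs[name], dtype=float)[subj_index]
    y = linpred + rng.normal(0.0, params.sigma_resid, n_rows)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in subj_index],
            "visit_time": times,
            "bapwv": y,
            "cortisol": exposure[subj_index],
            "sbp": med_visit["sbp"],
            "dbp": med_visit["dbp"],
            "vfa": med_visit["vfa"],
            "bmi": med_visit["bmi"],
            "smoking": smoking[subj_index],
            "sleep": sleep[subj_index],
        }
    )
    for name, arr in covs.items():
        df[name] = np.asarray(arr)[subj_index]
    df["map"] = df["sbp"] / 3.0 + 2.0 * df["dbp"] / 3.0

    truth = GroundTruth(
        params={"cohort": vars(params).copy(), "seed": seed},
        true_total_effect=params.beta_total,
        true_direct_effect=beta_direct,
        true_indirect={m: f * params.beta_total for m, f in fractions.items()},
        true_mediated_proportion={m: 100.0 * f for m, f in fractions.items()},
        mediator_slopes={m: slopes[m] for m in med_names},
        mediator_outcome_effects=gamma,
    )
    table = CohortTable(df=df)
    counts = df.groupby("subject_id").size()
    table.flagged_subjects = sorted(counts.index[counts < 2])
    return table, truth


_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def generate_gwas_triplet(params: SynthGwasParams, seed: int):
    """Simulate exposure / mediator / outcome GWAS summary tables.

    Per SNP j with effect-allele frequency f_j, the true exposure beta
    is sized so the variant explains the requested R^2 of a
    unit-variance exposure; standard errors follow the two-sample
    approximation se ~ 1/sqrt(2 f (1-f) n).  Mediator and outcome true
    betas are linear in the exposure beta through paths A and
    (direct + A*B); heterogeneity perturbs the per-SNP slope and
    directional pleiotropy shifts mediator- and outcome-stage betas.
    """
    rng = spawn_rng(seed, 2)
    k = params.n_instruments
    A = params.true_beta_exposure_mediator
    B = params.true_beta_mediator_outcome
    total = params.true_direct_effect + A * B

    eaf = rng.uniform(0.10, 0.90, size=k)
    var_g = 2.0 * eaf * (1.0 - eaf)
    beta_exp_true = np.sqrt(params.instrument_strength / var_g) * rng.choice([-1.0, 1.0], k)
    se_exp = 1.0 / np.sqrt(var_g * params.n_exposure)
    se_med = 1.0 / np.sqrt(var_g * params.n_mediator)
    se_out = 1.0 / np.sqrt(var_g * params.n_outcome)

    het_med = rng.normal(0.0, params.heterogeneity_sd, k) if params.heterogeneity_sd else 0.0
    het_out = rng.normal(0.0, params.heterogeneity_sd, k) if params.heterogeneity_sd else 0.0
    beta_med_true = (A + het_med) * beta_exp_true + params.pleiotropy_mean
    beta_out_true = (total + het_out) * beta_exp_true + params.pleiotropy_mean

    beta_exp = beta_exp_true + rng.normal(0.0, se_exp)
    beta_med = beta_med_true + rng.normal(0.0, se_med)
    beta_out = beta_out_true + rng.normal(0.0, se_out)

    pal = rng.random(k) < params.palindromic_fraction
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), k)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), k)
    ea = np.where(pal, [p[0] for p in np.array(_PALINDROMIC_PAIRS, dtype=object)[pal_idx]],
                  [p[0] for p in np.array(_ALLELE_PAIRS, dtype=object)[pair_idx]])
    oa = np.where(pal, [p[1] for p in np.array(_PALINDROMIC_PAIRS, dtype=object)[pal_idx]],
                  [p[1] for p in np.array(_ALLELE_PAIRS, dtype=object)[pair_idx]])

    def table(beta, se, n, trait):
        z = beta / se
        return GwasSummary(
            df=pd.DataFrame(
                {
                    "snp": [f"rs{100000 + j}" for j in range(k)],
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": beta,
                    "se": se,
                    "pval": 2 * _st.norm.sf(np.abs(z)),
                    "n": n,
                }
            ),
            trait=trait,
        )

    exp_t = table(beta_exp, se_exp, params.n_exposure, "exposure")
    med_t = table(beta_med, se_med, params.n_mediator, "mediator")
    out_t = table(beta_out, se_out, params.n_outcome, "outcome")

    truth = GroundTruth(
        params={"gwas": vars(params).copy(), "seed": seed},
        true_total_effect=total,
        true_direct_effect=params.true_direct_effect,
        true_indirect={"mediator": A * B},
        mediator_slopes={"A": A},
        mediator_outcome_effects={"B": B},
    )
    if k < 3:
        truth.warnings.append("fewer than 3 instruments: MR-Egger will not be computable")
    return exp_t, med_t, out_t, truth
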