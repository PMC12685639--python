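"""Two-step mixed-model mediation with subject-level bootstrap.

For each candidate mediator M, three random-intercept models are fitted:

* step 1 (exposure -> mediator):  M ~ exposure + covariates,
  giving beta1, the exposure effect on the mediator;
* step 2 (mediator -> outcome):   y ~ M + exposure + covariates,
  giving beta2, the mediator effect adjusted for exposure;
* total effect:                   y ~ exposure + covariates,
  giving beta3.

Step 2 is run only when the step-1 association is significant at the
configured alpha (the gate).  The indirect effect is the product
beta1 * beta2 and the mediated proportion is 100 * beta1*beta2 / beta3.
Uncertainty comes from a cluster bootstrap: whole subjects are resampled
with replacement and all three models are refitted per replicate, which
respects the within-subject correlation of the repeated measures.
Refits reuse per-subject sufficient statistics (cross-products), making
a replicate a resample-and-sum rather than a pass over the rows —
numerically identical to refitting on the stacked resampled data.

A mediator whose indirect effect opposes the sign of the total effect
is flagged as masking (its mediated proportion is negative).

The mediated proportion is a ratio with the total effect in the
denominator and is numerically meaningless when that denominator is
indistinguishable from zero; following standard mediation practice the
proportion (and its interval) is reported only when the total effect
is itself significant at the configured alpha.  The indirect effect
beta1 * beta2 is reported whenever the step-1 gate passes.

When a mediator is itself a blood-pressure variable (SBP, DBP or MAP),
mean arterial pressure is removed from the adjustment covariates of all
three models, so the blood-pressure path is not conditioned on itself.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import CohortTable, spawn_rng
from .lmm import DesignSpec, GroupStats, build_design, collapse, fit_from_stats, group_stats

logger = logging.getLogger("cortmed")

_BP_MEDIATORS = {"sbp", "dbp", "map"}
_MIN_BOOT_FOR_CI = 200


@dataclass
class MediationResult:
    """Decomposition for one candidate mediator."""

    mediator: str
    beta1: float
    beta1_se: float
    beta1_p: float
    gate_passed: bool
    beta2: float | None = None
    beta2_se: float | None = None
    beta2_p: float | None = None
    beta3: float | None = None
    beta3_se: float | None = None
    beta3_p: float | None = None
    indirect: float | None = None
    proportion: float | None = None  # percent of the total effect
    indirect_ci: tuple | None = None
    proportion_ci: tuple | None = None
    bootstrap_p: float | None = None
    total_significant: bool = False
    masking: bool = False
    n_bootstrap: int = 0
    n_dropped_replicates: int = 0
    unreliable: bool = False
    seed: int | None = None


def _adjusted_spec(adjust: DesignSpec, mediator: str) -> DesignSpec:
    """Drop MAP from the covariates when the mediator is a BP variable."""
    if mediator in _BP_MEDIATORS and "map" in adjust.continuous:
        logger.info("mediator %s: removing MAP from the adjustment set", mediator)
        return adjust.without_terms(["map"])
    return adjust.without_terms([mediator])


def step1_exposure_mediator(data, mediator: str, adjust: DesignSpec, exposure: str):
    """Random-intercept LMM of the mediator on baseline log10-exposure."""
    spec = _adjusted_spec(adjust, mediator)
    spec = DesignSpec(
        outcome=mediator,
        continuous=[c for c in spec.continuous if c != spec.outcome],
        categorical=spec.categorical,
        interactions=spec.interactions,
        group=spec.group,
    )
    from .lmm import fit_lmm

    return fit_lmm(data, spec)


def step2_mediator_outcome(data, mediator: str, adjust: DesignSpec, exposure: str):
    """Random-intercept LMM of the outcome on mediator + exposure + covariates."""
    spec = _adjusted_spec(adjust, mediator).with_terms(continuous=[mediator])
    from .lmm import fit_lmm

    return fit_lmm(data, spec)


class LMEMediation:
    """Model object for product-of-coefficients mediation.

    Parameters
    ----------
    data : CohortTable or DataFrame
        Long-format repeated measures.
    mediators : list of str
        Candidate time-varying mediators (columns of ``data``).
    adjust : DesignSpec
        The total-effect model: outcome on exposure plus covariates;
        its ``continuous`` list must contain ``exposure``.
    exposure : str
        Name of the exposure column (baseline log10-cortisol).
    config : RunConfig
        Seed, bootstrap size and gate alpha.
    """

    def __init__(self, data, mediators, adjust: DesignSpec, exposure: str,
                 config: RunConfig | None = None):
        if exposure not in adjust.continuous:
            raise ValueError("the adjustment spec must contain the exposure term")
        self.data = data.analysis_subset() if isinstance(data, CohortTable) else data
        self.mediators = list(mediators)
        self.adjust = adjust
        self.exposure = exposure
        self.config = config or RunConfig()

    # -- sufficient-statistic machinery ---------------------------------

    def _stats_for(self, spec: DesignSpec):
        y, X, groups = build_design(self.data, spec)
        st = group_stats(y.to_numpy(), X.to_numpy(), groups.to_numpy(), list(X.columns))
        order = pd.unique(groups)
        return st, list(order)

    def fit(self) -> "MediationResults":
        results = [self._fit_one(m) for m in self.mediators]
        return MediationResults(self, results)

    def _fit_one(self, mediator: str) -> MediationResult:
        cfg = self.config
        base = _adjusted_spec(self.adjust, mediator)
        spec1 = DesignSpec(
            outcome=mediator,
            continuous=[c for c in base.continuous],
            categorical=base.categorical,
            interactions=base.interactions,
            group=base.group,
        )
        spec2 = base.with_terms(continuous=[mediator])
        spec3 = base

        st1, subj1 = self._stats_for(spec1)
        fit1 = _point_fit(st1)
        b1 = _coef(fit1, self.exposure)
        gate = b1["p"] < cfg.alpha
        result = MediationResult(
            mediator=mediator,
            beta1=b1["est"],
            beta1_se=b1["se"],
            beta1_p=b1["p"],
            gate_passed=bool(gate),
            seed=cfg.seed,
        )
        if not gate:
            logger.info("mediator %s failed the step-1 gate (p=%.3g)", mediator, b1["p"])
            return result

        st2, subj2 = self._stats_for(spec2)
        st3, subj3 = self._stats_for(spec3)
        fit2 = _point_fit(st2)
        fit3 = _point_fit(st3)
        b2 = _coef(fit2, mediator)
        b3 = _coef(fit3, self.exposure)
        indirect = b1["est"] * b2["est"]
        result.beta2, result.beta2_se, result.beta2_p = b2["est"], b2["se"], b2["p"]
        result.beta3, result.beta3_se, result.beta3_p = b3["est"], b3["se"], b3["p"]
        result.indirect = indirect
        result.total_significant = bool(b3["p"] < cfg.alpha)
        result.masking = bool(np.sign(indirect) != np.sign(b3["est"]) and indirect != 0)
        if result.total_significant:
            result.proportion = 100.0 * indirect / b3["est"]
        else:
            logger.info(
                "mediator %s: total effect not significant (p=%.3g); "
                "mediated proportion not reported", mediator, b3["p"],
            )

        # cluster bootstrap over subjects, shared draw across the 3 models
        subjects = sorted(set(subj1) | set(subj2) | set(subj3))
        pos = {s: i for i, s in enumerate(subjects)}
        maps = []
        for subj in (subj1, subj2, subj3):
            m = np.full(len(subjects), -1, dtype=np.int64)
            for j, s in enumerate(subj):
                m[pos[s]] = j
            maps.append(m)
        stats_all = (st1, st2, st3)
        coef_cols = (
            st1.columns.index(self.exposure),
            st2.columns.index(mediator),
            st3.columns.index(self.exposure),
        )
        B = cfg.n_bootstrap
        rng = spawn_rng(cfg.seed, 3, zlib.crc32(mediator.encode()) % (2**31))
        n_subj = len(subjects)
        boot = np.full((B, 3), np.nan)
        dropped = 0
        for rep in range(B):
            draw = rng.integers(0, n_subj, size=n_subj)
            try:
                for k in range(3):
                    idx = maps[k][draw]
                    idx = idx[idx >= 0]
                    w = np.bincount(idx, minlength=stats_all[k].n_groups)
                    fit = fit_from_stats(collapse(stats_all[k], w), xtol=1e-8)
                    boot[rep, k] = fit["params"][coef_cols[k]]
            except (np.linalg.LinAlgError, ValueError):
                boot[rep] = np.nan
                dropped += 1
        ok = ~np.isnan(boot).any(axis=1)
        n_ok = int(ok.sum())
        result.n_bootstrap = n_ok
        result.n_dropped_replicates = int(B - n_ok)
        result.unreliable = (B - n_ok) > 0.10 * B
        if n_ok >= _MIN_BOOT_FOR_CI:
            ind = boot[ok, 0] * boot[ok, 1]
            result.indirect_ci = tuple(np.percentile(ind, [2.5, 97.5]))
            if result.total_significant:
                prop = 100.0 * ind / boot[ok, 2]
                result.proportion_ci = tuple(np.percentile(prop, [2.5, 97.5]))
            frac_le = np.mean(ind <= 0)
            frac_ge = np.mean(ind >= 0)
            result.bootstrap_p = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
        else:
            logger.warning(
                "mediator %s: %d usable replicates < %d, no CI reported",
                mediator, n_ok, _MIN_BOOT_FOR_CI,
            )
        return result


def _point_fit(st: GroupStats) -> dict:
    return fit_from_stats(st)


def _coef(fit: dict, name: str) -> dict:
    from scipy import stats as _st

    i = fit["columns"].index(name)
    est = fit["params"][i]
    se = float(np.sqrt(fit["cov_params"][i, i]))
    z = est / se
    return {"est": float(est), "se": se, "p": float(2 * _st.norm.sf(abs(z)))}


@dataclass
class MediationResults:
    """Results object: one :class:`MediationResult` per candidate mediator."""

    model: LMEMediation
    results: list[MediationResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, mediator: str) -> MediationResult:
        for r in self.results:
            if r.mediator == mediator:
                return r
        raise KeyError(mediator)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "mediator": r.mediator,
                    "beta1": r.beta1,
                    "beta1_p": r.beta1_p,
                    "gate_passed": r.gate_passed,
                    "beta2": r.beta2,
                    "beta2_p": r.beta2_p,
                    "beta3": r.beta3,
                    "total_significant": r.total_significant,
                    "indirect": r.indirect,
                    "proportion_pct": r.proportion,
                    "proportion_ci_lower": None if r.proportion_ci is None else r.proportion_ci[0],
                    "proportion_ci_upper": None if r.proportion_ci is None else r.proportion_ci[1],
                    "bootstrap_p": r.bootstrap_p,
                    "masking": r.masking,
                    "n_bootstrap": r.n_bootstrap,
                    "unreliable": r.unreliable,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        head = (
            f"LME mediation ({len(self.results)} mediators, "
            f"B={self.model.config.n_bootstrap}, alpha={self.model.config.alpha}, "
            f"seed={self.model.config.seed})\n"
        )
        return head + df.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def mediate(data, mediators, adjust: DesignSpec, config: RunConfig,
            exposure: str = "log10_cortisol") -> list[MediationResult]:
    """Functional front end over :class:`LMEMediation`."""
    return LMEMediation(data, mediators, adjust, exposure, config).fit().results
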