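"""Two-step Mendelian-randomization mediation from summary statistics.

Three univariable IVW stages:

* total effect      — exposure instruments against the outcome;
* direct effect A   — exposure instruments against the mediator;
* direct effect B   — mediator instruments against the outcome.

Stage B runs only when stage A is significant at the configured alpha
(the step-one gate).  The mediated effect is the product
beta_A * beta_B (beta_B on the log-odds scale for binary outcomes) with
the delta-method standard error sqrt(betaA^2 seB^2 + betaB^2 seA^2).
Per-stage Cochran's Q and MR-Egger intercepts provide heterogeneity and
pleiotropy diagnostics.  No mediated proportion is reported on the
odds-ratio scale (the odds ratio is non-collapsible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import GwasSummary
from .mr import (
    EggerInterceptResult,
    HarmonizedSet,
    HeterogeneityResult,
    MREstimate,
    egger,
    harmonize,
    ivw,
)


@dataclass
class StageResult:
    """One univariable MR stage plus its diagnostics."""

    name: str
    estimate: MREstimate | None
    heterogeneity: HeterogeneityResult | None
    egger_intercept: EggerInterceptResult | None
    harmonized: HarmonizedSet | None
    computable: bool = True
    reason: str = ""


@dataclass
class TwoStepResult:
    """Decomposition for one mediator (Results object)."""

    mediator: str
    total: StageResult
    direct_a: StageResult
    direct_b: StageResult | None
    proceed: bool
    mediated_effect: float | None = None
    mediated_se: float | None = None
    mediated_ci: tuple | None = None
    mediated_p: float | None = None

    def to_row(self) -> dict:
        def unpack(stage, prefix, as_or=False):
            out = {}
            if stage is None or not stage.computable or stage.estimate is None:
                out[f"{prefix}_beta"] = np.nan
                out[f"{prefix}_p"] = np.nan
                return out
            e = stage.estimate
            if as_or and e.binary_outcome:
                lo, hi = e.or_ci
                out[f"{prefix}_or"] = e.odds_ratio
                out[f"{prefix}_or_ci_lower"] = lo
                out[f"{prefix}_or_ci_upper"] = hi
            out[f"{prefix}_beta"] = e.beta
            out[f"{prefix}_ci_lower"] = e.ci_lower
            out[f"{prefix}_ci_upper"] = e.ci_upper
            out[f"{prefix}_p"] = e.p
            return out

        row = {"mediator": self.mediator, "proceed": self.proceed}
        row.update(unpack(self.total, "total", as_or=True))
        row.update(unpack(self.direct_a, "direct_a"))
        row.update(unpack(self.direct_b, "direct_b", as_or=True))
        row["mediated_effect"] = self.mediated_effect
        row["mediated_se"] = self.mediated_se
        if self.mediated_ci is not None:
            row["mediated_ci_lower"], row["mediated_ci_upper"] = self.mediated_ci
        row["mediated_p"] = self.mediated_p
        return row

    def summary(self) -> str:
        df = pd.DataFrame([self.to_row()])
        return df.to_string(index=False, float_format=lambda v: f"{v:.4g}")


class TwoStepMRMediation:
    """Model object composing three univariable IVW analyses."""

    def __init__(
        self,
        exposure: GwasSummary,
        mediator: GwasSummary,
        outcome: GwasSummary,
        instruments_exposure,
        instruments_mediator,
        config: RunConfig | None = None,
        mediator_name: str = "mediator",
        binary_outcome: bool = True,
    ):
        if not len(instruments_exposure) or not len(instruments_mediator):
            raise ValueError("instrument lists must be nonempty")
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.instruments_exposure = list(instruments_exposure)
        self.instruments_mediator = list(instruments_mediator)
        self.config = config or RunConfig()
        self.mediator_name = mediator_name
        self.binary_outcome = binary_outcome

    def _stage(self, exp: GwasSummary, out: GwasSummary, instruments, name,
               binary) -> StageResult:
        try:
            h = harmonize(exp.restrict(instruments), out, self.config)
        except ValueError as exc:
            return StageResult(name, None, None, None, None, False, str(exc))
        est, het = ivw(h, model=self.config.ivw_model, binary_outcome=binary)
        _, intercept = egger(h, binary_outcome=binary)
        return StageResult(name, est, het, intercept, h)

    def fit(self) -> TwoStepResult:
        total = self._stage(
            self.exposure, self.outcome, self.instruments_exposure, "total",
            self.binary_outcome,
        )
        direct_a = self._stage(
            self.exposure, self.mediator, self.instruments_exposure, "direct_a", False
        )
        proceed = bool(
            direct_a.computable
            and direct_a.estimate is not None
            and direct_a.estimate.p < self.config.alpha
        )
        direct_b = None
        result = TwoStepResult(
            mediator=self.mediator_name,
            total=total,
            direct_a=direct_a,
            direct_b=None,
            proceed=proceed,
        )
        if proceed:
            direct_b = self._stage(
                self.mediator, self.outcome, self.instruments_mediator, "direct_b",
                self.binary_outcome,
            )
            result.direct_b = direct_b
            if direct_b.computable and direct_b.estimate is not None:
                bA, seA = direct_a.estimate.beta, direct_a.estimate.se
                bB, seB = direct_b.estimate.beta, direct_b.estimate.se
                med = bA * bB
                se = float(np.sqrt(bA**2 * seB**2 + bB**2 * seA**2))
                z = med / se if se > 0 else np.inf
                zq = 1.959963984540054
                result.mediated_effect = float(med)
                result.mediated_se = se
                result.mediated_ci = (med - zq * se, med + zq * se)
                result.mediated_p = float(2 * stats.norm.sf(abs(z)))
        return result


def two_step_mr(
    exposure: GwasSummary,
    mediator: GwasSummary,
    outcome: GwasSummary,
    instruments_exposure,
    instruments_mediator,
    config: RunConfig | None = None,
    mediator_name: str = "mediator",
    binary_outcome: bool = True,
) -> TwoStepResult:
    """Functional front end over :class:`TwoStepMRMediation`."""
    return TwoStepMRMediation(
        exposure, mediator, outcome, instruments_exposure, instruments_mediator,
        config, mediator_name, binary_outcome,
    ).fit()


def sensitivity_suite(result: TwoStepResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-stage heterogeneity and pleiotropy diagnostics.

    Cochran's Q needs at least 2 kept SNPs, the MR-Egger intercept at
    least 3; stages below these counts are marked not computable.
    """
    rows = []
    for stage in (result.total, result.direct_a, result.direct_b):
        if stage is None:
            continue
        row = {"stage": stage.name, "computable": stage.computable}
        het = stage.heterogeneity
        row["Q"] = het.Q if het else np.nan
        row["Q_df"] = het.df if het else np.nan
        row["Q_p"] = het.p if het else np.nan
        row["heterogeneity_flag"] = bool(het and het.p < alpha)
        ei = stage.egger_intercept
        row["egger_intercept"] = ei.intercept if ei else np.nan
        row["egger_p"] = ei.p if ei else np.nan
        row["egger_computable"] = ei is not None
        row["pleiotropy_flag"] = bool(ei and ei.p < alpha)
        rows.append(row)
    return pd.DataFrame(rows)
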