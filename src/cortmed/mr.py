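"""Two-sample Mendelian randomization from GWAS summary statistics.

Implements allele harmonization between an exposure and an outcome
summary table, the per-SNP Wald ratio, inverse-variance-weighted (IVW)
pooling with Cochran's Q, the MR-Egger slope/intercept regression, and
per-SNP instrument-strength F-statistics.

Conventions: IVW is equivalent to origin-constrained weighted least
squares of outcome betas on exposure betas with weights 1/se_out^2; the
default "random" model inflates the fixed-effect standard error by
max(1, sqrt(Q/(k-1))) (multiplicative random effects, never deflating
below the fixed-effect SE).  MR-Egger p-values use a t reference with
k-2 degrees of freedom, appropriate for the small instrument counts of
cortisol analyses; IVW p-values use the normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import GwasSummary

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(ValueError):
    pass


@dataclass
class MREstimate:
    """One MR causal estimate (log-odds scale for binary outcomes)."""

    method: str
    beta: float
    se: float
    p: float
    ci_lower: float
    ci_upper: float
    n_snp: int
    binary_outcome: bool = False

    @property
    def odds_ratio(self):
        return float(np.exp(self.beta)) if self.binary_outcome else None

    @property
    def or_ci(self):
        if not self.binary_outcome:
            return None
        return (float(np.exp(self.ci_lower)), float(np.exp(self.ci_upper)))


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p: float


@dataclass
class EggerInterceptResult:
    intercept: float
    se: float
    p: float


@dataclass
class InstrumentStrength:
    f_stats: np.ndarray
    mean_f: float
    weak: bool  # mean F <= 10


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome pairing with an action audit.

    ``table`` holds every input rsid with an ``action`` column in
    {kept, sign_flipped, strand_complemented, dropped_palindromic,
    dropped_unmatched}; :attr:`kept` is the analysable subset.
    """

    table: pd.DataFrame

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["action"].isin(("kept", "sign_flipped", "strand_complemented"))]

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    config: RunConfig | None = None,
) -> HarmonizedSet:
    """Align the outcome table's effect alleles to the exposure table.

    Matching is on rsid.  Identical allele pairs are kept; swapped
    effect/other alleles flip the outcome beta's sign and mirror its
    frequency; opposite-strand pairs are complemented first.
    Palindromic (A/T, C/G) pairs are orientable only from allele
    frequencies: both sides must be present with minor-allele frequency
    below ``palindrome_maf_limit``; concordant frequencies keep the
    nominal alignment, discordant ones flip it, anything else is
    dropped as ambiguous.
    """
    cfg = config or RunConfig()
    maf_lim = cfg.palindrome_maf_limit
    exp = exposure.df.set_index("snp")
    out = outcome.df.set_index("snp")

    records = []
    for rsid, erow in exp.iterrows():
        rec = {
            "snp": rsid,
            "effect_allele": erow["effect_allele"],
            "other_allele": erow["other_allele"],
            "beta_exposure": erow["beta"],
            "se_exposure": erow["se"],
            "eaf_exposure": erow.get("eaf", np.nan),
            "beta_outcome": np.nan,
            "se_outcome": np.nan,
            "eaf_outcome": np.nan,
            "action": "dropped_unmatched",
        }
        if rsid in out.index:
            orow = out.loc[rsid]
            rec.update(_align(erow, orow, maf_lim))
        records.append(rec)
    table = pd.DataFrame(records)
    if not (table["action"].isin(("kept", "sign_flipped", "strand_complemented"))).any():
        raise HarmonizationError("no SNPs kept after harmonization")
    return HarmonizedSet(table=table)


def _align(erow, orow, maf_lim):
    e1, e2 = erow["effect_allele"], erow["other_allele"]
    o1, o2 = orow["effect_allele"], orow["other_allele"]
    beta, se = float(orow["beta"]), float(orow["se"])
    eaf_o = float(orow["eaf"]) if "eaf" in orow.index and pd.notna(orow.get("eaf")) else np.nan
    eaf_e = float(erow["eaf"]) if "eaf" in erow.index and pd.notna(erow.get("eaf")) else np.nan

    action = None
    if (o1, o2) == (e1, e2):
        action = "kept"
    elif (o1, o2) == (e2, e1):
        beta, eaf_o = -beta, 1.0 - eaf_o
        action = "sign_flipped"
    else:
        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if (c1, c2) == (e1, e2):
            action = "strand_complemented"
        elif (c1, c2) == (e2, e1):
            beta, eaf_o = -beta, 1.0 - eaf_o
            action = "sign_flipped"
        else:
            return {"action": "dropped_unmatched"}

    if _is_palindromic(e1, e2):
        mafs_ok = (
            np.isfinite(eaf_e)
            and np.isfinite(eaf_o)
            and min(eaf_e, 1 - eaf_e) < maf_lim
            and min(eaf_o, 1 - eaf_o) < maf_lim
        )
        if not mafs_ok:
            return {"action": "dropped_palindromic"}
        if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
            # frequencies disagree on orientation: the strands differ
            beta, eaf_o = -beta, 1.0 - eaf_o
            action = "sign_flipped"

    return {
        "beta_outcome": beta,
        "se_outcome": se,
        "eaf_outcome": eaf_o,
        "action": action,
    }


def wald_ratio(beta_exposure, beta_outcome, se_outcome, binary_outcome=False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The first-order standard error |se_out / beta_exp| ignores exposure
    uncertainty, adequate for strong instruments.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("undefined Wald ratio: exposure beta is 0")
    beta = beta_outcome / beta_exposure
    se = abs(se_outcome / beta_exposure)
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return MREstimate(
        method="wald_ratio",
        beta=float(beta),
        se=float(se),
        p=float(p),
        ci_lower=float(beta - 1.959963984540054 * se),
        ci_upper=float(beta + 1.959963984540054 * se),
        n_snp=1,
        binary_outcome=binary_outcome,
    )


def ivw(h: HarmonizedSet, model: str = "random", binary_outcome: bool = False):
    """Inverse-variance-weighted estimate and Cochran's Q.

    Weights w_j = beta_exp_j^2 / se_out_j^2 pool the per-SNP Wald
    ratios; equivalently an origin-constrained WLS of outcome betas on
    exposure betas.  Returns ``(MREstimate, HeterogeneityResult | None)``
    (Q needs at least two instruments).
    """
    kept = h.kept
    if len(kept) == 0:
        raise ValueError("no kept SNPs")
    bx = kept["beta_exposure"].to_numpy(dtype=float)
    by = kept["beta_outcome"].to_numpy(dtype=float)
    so = kept["se_outcome"].to_numpy(dtype=float)
    k = len(bx)
    if k == 1:
        est = wald_ratio(bx[0], by[0], so[0], binary_outcome)
        return est, None
    r = by / bx
    w = bx**2 / so**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (r - beta) ** 2))
    df = k - 1
    het = HeterogeneityResult(Q=Q, df=df, p=float(stats.chi2.sf(Q, df)))
    se = se_fixed
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(Q / df))
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    zq = 1.959963984540054
    est = MREstimate(
        method="ivw",
        beta=beta,
        se=float(se),
        p=float(p),
        ci_lower=beta - zq * se,
        ci_upper=beta + zq * se,
        n_snp=k,
        binary_outcome=binary_outcome,
    )
    return est, het


def egger(h: HarmonizedSet, binary_outcome: bool = False):
    """MR-Egger regression: slope (causal) and intercept (pleiotropy).

    Rows are re-oriented so every exposure beta is nonnegative (the
    slope/intercept decomposition is otherwise unidentified), then a
    weighted regression with free intercept is solved; standard errors
    are inflated by max(1, sqrt(RSS/(k-2))) and p-values use a t with
    k-2 degrees of freedom.  Returns ``(None, None)`` wrapped in a
    not-computable marker when fewer than 3 instruments are kept.
    """
    kept = h.kept
    k = len(kept)
    if k < 3:
        return None, None
    bx = kept["beta_exposure"].to_numpy(dtype=float).copy()
    by = kept["beta_outcome"].to_numpy(dtype=float).copy()
    so = kept["se_outcome"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip], by[flip] = -bx[flip], -by[flip]

    w = 1.0 / so**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    A = X.T @ WX
    b = WX.T @ by
    coef = np.linalg.solve(A, b)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    df = k - 2
    phi = max(1.0, rss / df)
    cov = phi * np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov))
    tvals = coef / ses
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    tq = stats.t.ppf(0.975, df)
    slope = MREstimate(
        method="egger_slope",
        beta=float(coef[1]),
        se=float(ses[1]),
        p=float(pvals[1]),
        ci_lower=float(coef[1] - tq * ses[1]),
        ci_upper=float(coef[1] + tq * ses[1]),
        n_snp=k,
        binary_outcome=binary_outcome,
    )
    intercept = EggerInterceptResult(
        intercept=float(coef[0]), se=float(ses[0]), p=float(pvals[0])
    )
    return slope, intercept


def instrument_strength(exposure: GwasSummary) -> InstrumentStrength:
    """Per-SNP F = (beta/se)^2 with the conventional weak threshold 10."""
    df = exposure.df
    f = (df["beta"].to_numpy(dtype=float) / df["se"].to_numpy(dtype=float)) ** 2
    mean_f = float(f.mean())
    return InstrumentStrength(f_stats=f, mean_f=mean_f, weak=mean_f <= 10.0)


class TwoSampleMR:
    """Model-style front end: harmonize once, then estimate.

    ``TwoSampleMR(exposure, outcome, config).fit()`` returns a
    :class:`TwoSampleMRResults` bundling IVW, MR-Egger, Cochran's Q and
    instrument strength.
    """

    def __init__(
        self,
        exposure: GwasSummary,
        outcome: GwasSummary,
        config: RunConfig | None = None,
        instruments=None,
        binary_outcome: bool = False,
    ):
        self.config = config or RunConfig()
        self.exposure = exposure.restrict(instruments) if instruments else exposure
        self.outcome = outcome
        self.binary_outcome = binary_outcome
        self.harmonized = harmonize(self.exposure, outcome, self.config)

    def fit(self) -> "TwoSampleMRResults":
        est, het = ivw(self.harmonized, model=self.config.ivw_model,
                       binary_outcome=self.binary_outcome)
        slope, intercept = egger(self.harmonized, binary_outcome=self.binary_outcome)
        strength = instrument_strength(self.exposure)
        return TwoSampleMRResults(self, est, het, slope, intercept, strength)


@dataclass
class TwoSampleMRResults:
    model: TwoSampleMR
    ivw: MREstimate
    heterogeneity: HeterogeneityResult | None
    egger_slope: MREstimate | None
    egger_intercept: EggerInterceptResult | None
    strength: InstrumentStrength

    def summary(self) -> str:
        lines = [
            f"Two-sample MR ({self.ivw.n_snp} SNPs, "
            f"{'binary' if self.ivw.binary_outcome else 'continuous'} outcome)",
            f"  IVW beta={self.ivw.beta:.4g} se={self.ivw.se:.4g} p={self.ivw.p:.3g}",
        ]
        if self.ivw.binary_outcome:
            lo, hi = self.ivw.or_ci
            lines.append(f"  IVW OR={self.ivw.odds_ratio:.4g} (95% CI {lo:.4g}, {hi:.4g})")
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"  Cochran's Q={h.Q:.3f} df={h.df} p={h.p:.3g}")
        if self.egger_intercept is not None:
            e = self.egger_intercept
            lines.append(f"  Egger intercept={e.intercept:.4g} p={e.p:.3g}")
        lines.append(f"  mean F={self.strength.mean_f:.1f} weak={self.strength.weak}")
        return "\n".join(lines)
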