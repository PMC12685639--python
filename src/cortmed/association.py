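"""Dose-response analysis layer for the longitudinal cohort.

Derived variables (MAP, log10-exposure), baseline-quartile coding of
the exposure, the crude / Model 1 / Model 2 covariate ladder, trend and
high-vs-low contrasts, an exposure-by-covariable interaction scan, a
restricted-cubic-spline nonlinearity test, per-follow-up-window ANOVA,
leave-one-out sensitivity refits and Benjamini-Hochberg adjustment.

Model 1 adjusts for age, sex and MAP; Model 2 additionally adjusts for
diabetes duration, VFA, LDL-C, HbA1c, smoking, drinking, sleep, CVD
history and antihypertensive / lipid-lowering agents.  Baseline
covariates are carried forward (time-fixed); only the outcome is
time-varying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .lmm import DesignSpec, LMMResults, fit_lmm, rcs_basis


def derive_variables(data: CohortTable | pd.DataFrame) -> CohortTable | pd.DataFrame:
    """Fill derived columns: MAP, log10 exposure, mean left/right baPWV.

    MAP = (1/3) SBP + (2/3) DBP wherever it is absent; cortisol must be
    strictly positive for the log10 transform.
    """
    table = data
    df = data.df if isinstance(data, CohortTable) else data
    df = df.copy()
    if "bapwv_left" in df.columns and "bapwv_right" in df.columns:
        df["bapwv"] = (pd.to_numeric(df["bapwv_left"]) + pd.to_numeric(df["bapwv_right"])) / 2.0
    if "map" not in df.columns or df["map"].isna().any():
        if "sbp" not in df.columns or "dbp" not in df.columns:
            if "map" not in df.columns:
                raise KeyError("need sbp and dbp columns to derive map")
        else:
            derived = pd.to_numeric(df["sbp"]) / 3.0 + 2.0 * pd.to_numeric(df["dbp"]) / 3.0
            if "map" in df.columns:
                df["map"] = df["map"].fillna(derived)
            else:
                df["map"] = derived
    if "cortisol" in df.columns:
        cort = pd.to_numeric(df["cortisol"])
        if (cort <= 0).any():
            raise ValueError("cortisol must be positive for the log10 transform")
        df["log10_cortisol"] = np.log10(cort)
    if isinstance(table, CohortTable):
        return CohortTable(
            df=df,
            flagged_subjects=table.flagged_subjects,
            n_dropped_missing_outcome=table.n_dropped_missing_outcome,
        )
    return df


def mean_arterial_pressure(sbp, dbp):
    """(1/3) SBP + (2/3) DBP."""
    return np.asarray(sbp, dtype=float) / 3.0 + 2.0 * np.asarray(dbp, dtype=float) / 3.0


@dataclass
class ExposureCoding:
    """Baseline-quartile coding of the exposure.

    ``cut_points`` are the empirical 25/50/75 percentiles of the
    baseline exposure; a value equal to a cut point falls in the lower
    quartile.  ``labels`` are 1-4 per entry; ``high`` is the binary
    Q3-Q4 indicator.
    """

    cut_points: np.ndarray
    labels: np.ndarray

    @property
    def high(self) -> np.ndarray:
        return (self.labels >= 3).astype(int)


def assign_quartiles(exposure) -> ExposureCoding:
    """Quartile coding at empirical 25/50/75 percentiles (ties go low)."""
    x = np.asarray(exposure, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct exposure values")
    cuts = np.percentile(x, [25, 50, 75])
    labels = 1 + (x[:, None] > cuts[None, :]).sum(axis=1)
    return ExposureCoding(cut_points=cuts, labels=labels)


@dataclass
class ModelLadder:
    """Crude / Model 1 / Model 2 adjustment sets as design specs."""

    outcome: str = "bapwv"
    exposure: str = "log10_cortisol"
    group: str = "subject_id"
    model1_continuous: tuple = ("age", "map")
    model1_categorical: dict = field(default_factory=lambda: {"sex": "0"})
    model2_extra_continuous: tuple = ("diabetes_duration", "vfa", "ldl", "hba1c")
    model2_extra_categorical: dict = field(
        default_factory=lambda: {
            "smoking": "never_or_gt12mo",
            "drinking": "0",
            "sleep": "7to9",
            "cvd_history": "0",
            "antihypertensive": "0",
            "lipidlowering": "0",
        }
    )

    def specs(self) -> dict:
        crude = DesignSpec(outcome=self.outcome, continuous=[self.exposure], group=self.group)
        m1 = DesignSpec(
            outcome=self.outcome,
            continuous=[self.exposure] + list(self.model1_continuous),
            categorical=dict(self.model1_categorical),
            group=self.group,
        )
        m2 = DesignSpec(
            outcome=self.outcome,
            continuous=list(m1.continuous) + list(self.model2_extra_continuous),
            categorical={**m1.categorical, **self.model2_extra_categorical},
            group=self.group,
        )
        return {"crude": crude, "model1": m1, "model2": m2}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone nondecreasing in the sorted order, capped at 1, invariant
    to the input ordering (each adjusted value stays attached to its
    hypothesis).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _exposure_term_rows(fit: LMMResults, terms: list, model: str, coding_name: str):
    ci = fit.conf_int()
    rows = []
    for t in terms:
        rows.append(
            {
                "coding": coding_name,
                "term": t,
                "model": model,
                "beta": fit.params[t],
                "ci_lower": ci.loc[t, "lower"],
                "ci_upper": ci.loc[t, "upper"],
                "p": fit.pvalues[t],
            }
        )
    return rows


def baseline_exposure(df: pd.DataFrame, exposure: str = "cortisol") -> pd.Series:
    """Per-subject baseline (earliest-visit) exposure values."""
    return df.sort_values("visit_time").groupby("subject_id")[exposure].first()


def run_model_ladder(
    data: CohortTable | pd.DataFrame,
    ladder: ModelLadder | None = None,
    codings=("continuous", "quartiles", "categories"),
) -> pd.DataFrame:
    """Fit every coding x model combination and assemble the table.

    Codings: ``continuous`` (per 1-unit log10 increase), ``quartiles``
    (Q2-Q4 vs Q1 indicators plus an ordinal trend term) and
    ``categories`` (Q3-Q4 vs Q1-Q2).  Benjamini-Hochberg adjustment is
    applied within the family of exposure rows of each model.
    """
    ladder = ladder or ModelLadder()
    df = data.analysis_subset() if isinstance(data, CohortTable) else data
    base = baseline_exposure(df, ladder.exposure)
    coding = assign_quartiles(base.to_numpy())
    dfq = df.copy()
    lab = pd.Series(coding.labels, index=base.index)
    dfq["exposure_quartile"] = "Q" + dfq["subject_id"].map(lab).astype(int).astype(str)
    dfq["exposure_rank"] = dfq["subject_id"].map(lab).astype(float)
    dfq["exposure_high"] = (dfq["exposure_rank"] >= 3).astype(float)

    specs = ladder.specs()
    rows = []
    for model_name, spec in specs.items():
        model_rows = []
        if "continuous" in codings:
            fit = fit_lmm(dfq, spec)
            model_rows += _exposure_term_rows(fit, [ladder.exposure], model_name, "continuous")
        if "quartiles" in codings:
            qspec = spec.without_terms([ladder.exposure]).with_terms(
                categorical={"exposure_quartile": "Q1"}
            )
            fit = fit_lmm(dfq, qspec)
            terms = [f"exposure_quartile[Q{k}]" for k in (2, 3, 4)]
            model_rows += _exposure_term_rows(fit, terms, model_name, "quartiles")
            tspec = spec.without_terms([ladder.exposure]).with_terms(
                continuous=["exposure_rank"]
            )
            tfit = fit_lmm(dfq, tspec)
            _, _, p_trend = tfit.wald_test("exposure_rank")
            model_rows.append(
                {
                    "coding": "quartiles",
                    "term": "trend",
                    "model": model_name,
                    "beta": tfit.params["exposure_rank"],
                    "ci_lower": tfit.conf_int().loc["exposure_rank", "lower"],
                    "ci_upper": tfit.conf_int().loc["exposure_rank", "upper"],
                    "p": p_trend,
                }
            )
        if "categories" in codings:
            cspec = spec.without_terms([ladder.exposure]).with_terms(
                continuous=["exposure_high"]
            )
            fit = fit_lmm(dfq, cspec)
            model_rows += _exposure_term_rows(fit, ["exposure_high"], model_name, "categories")
        ps = np.array([r["p"] for r in model_rows])
        adj = bh_adjust(ps)
        for r, a in zip(model_rows, adj):
            r["p_adj"] = a
        rows += model_rows
    return pd.DataFrame(rows)


def interaction_scan(
    data: CohortTable | pd.DataFrame,
    spec: DesignSpec,
    covariables,
    exposure: str = "log10_cortisol",
) -> pd.DataFrame:
    """One refit per covariable adding exposure x covariable products.

    Returns a table of joint Wald p-values per covariable with a
    Benjamini-Hochberg column.
    """
    rows = []
    for cov in covariables:
        ispec = spec.with_terms(interactions=[(exposure, cov)])
        fit = fit_lmm(data, ispec)
        terms = [c for c in fit.params.index if c.startswith(f"{exposure}:")]
        stat, dfree, p = fit.wald_test(terms)
        rows.append({"covariable": cov, "wald_chi2": stat, "df": dfree, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def rcs_nonlinearity_test(
    data: CohortTable | pd.DataFrame,
    spec: DesignSpec,
    exposure: str = "log10_cortisol",
    n_knots: int = 4,
) -> tuple:
    """Spline-based departure-from-linearity test under the given model.

    The exposure enters through a restricted cubic spline basis; the
    joint Wald test on the nonlinear basis columns gives
    ``p_nonlinear`` and the joint test on all exposure columns gives
    ``p_overall``.
    """
    df = (data.analysis_subset() if isinstance(data, CohortTable) else data).copy()
    basis, knots = rcs_basis(df[exposure].to_numpy(dtype=float), n_knots)
    names = [exposure] + [f"{exposure}_rcs{j}" for j in range(1, basis.shape[1])]
    for j, nm in enumerate(names[1:], start=1):
        df[nm] = basis[:, j]
    sspec = spec.without_terms([exposure]).with_terms(continuous=names)
    fit = fit_lmm(df, sspec)
    _, _, p_nonlinear = fit.wald_test(names[1:])
    _, _, p_overall = fit.wald_test(names)
    return p_nonlinear, p_overall


def followup_window_anova(
    data: CohortTable | pd.DataFrame,
    coding: ExposureCoding | None = None,
    windows=((0.0, 0.0), (0.5, 1.5), (1.5, 2.5), (2.5, np.inf)),
    exposure: str = "cortisol",
) -> pd.DataFrame:
    """Quartile F-test within each follow-up window.

    Within a window, baPWV is regressed on quartile indicators plus
    continuous follow-up time; the F-test is on the quartile block.
    Windows with fewer than two quartile groups represented are marked
    not testable.  The first window (0, 0) denotes baseline visits.
    """
    df = data.analysis_subset() if isinstance(data, CohortTable) else data
    base = baseline_exposure(df, exposure)
    if coding is None:
        coding = assign_quartiles(base.to_numpy())
    lab = pd.Series(coding.labels, index=base.index)
    q = df["subject_id"].map(lab).to_numpy(dtype=float)
    t = df["visit_time"].to_numpy(dtype=float)
    y = df["bapwv"].to_numpy(dtype=float)

    rows = []
    for lo, hi in windows:
        if lo == hi:
            mask = t == lo
        else:
            mask = (t > lo) & (t <= hi)
        sub_q, sub_t, sub_y = q[mask], t[mask], y[mask]
        present = np.unique(sub_q[~np.isnan(sub_q)])
        if mask.sum() < 6 or len(present) < 2:
            rows.append({"window": f"({lo},{hi}]", "n": int(mask.sum()),
                         "F": np.nan, "df1": np.nan, "df2": np.nan,
                         "p": np.nan, "testable": False})
            continue
        dummies = np.column_stack([(sub_q == g).astype(float) for g in present[1:]])
        X_full = np.column_stack([np.ones(mask.sum()), sub_t, dummies])
        X_null = np.column_stack([np.ones(mask.sum()), sub_t])
        rss_full = _rss(X_full, sub_y)
        rss_null = _rss(X_null, sub_y)
        df1 = dummies.shape[1]
        df2 = mask.sum() - X_full.shape[1]
        if df2 <= 0 or rss_full <= 0:
            rows.append({"window": f"({lo},{hi}]", "n": int(mask.sum()),
                         "F": np.nan, "df1": df1, "df2": df2,
                         "p": np.nan, "testable": False})
            continue
        F = ((rss_null - rss_full) / df1) / (rss_full / df2)
        p = float(stats.f.sf(F, df1, df2))
        rows.append({"window": f"({lo},{hi}]", "n": int(mask.sum()),
                     "F": float(F), "df1": df1, "df2": df2, "p": p, "testable": True})
    return pd.DataFrame(rows)


def _rss(X, y):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


_REMOVABLE_GROUPS = {"agents": ("antihypertensive", "lipidlowering")}


def sensitivity_leave_one_out(
    data: CohortTable | pd.DataFrame,
    model2: DesignSpec,
    removable,
    exposure: str = "log10_cortisol",
) -> pd.DataFrame:
    """One full refit per removed covariate (or covariate group).

    The special name ``agents`` removes the antihypertensive and
    lipid-lowering indicators jointly.  The first row is the intact
    main model.
    """
    rows = []

    def one(name, spec):
        fit = fit_lmm(data, spec)
        ci = fit.conf_int()
        return {
            "removed": name,
            "beta": fit.params[exposure],
            "se": fit.bse[exposure],
            "ci_lower": ci.loc[exposure, "lower"],
            "ci_upper": ci.loc[exposure, "upper"],
            "p": fit.pvalues[exposure],
        }

    rows.append(one("none", model2))
    for name in removable:
        drop = _REMOVABLE_GROUPS.get(name, (name,))
        rows.append(one(name, model2.without_terms(drop)))
    return pd.DataFrame(rows)
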