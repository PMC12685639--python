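"""Random-intercept linear mixed model estimated by REML.

The model for subject *i*, visit *j* is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma2_subject),
                                      e_ij ~ N(0, sigma2_resid),

the standard Gaussian repeated-measures model with a single
subject-level random intercept.  Writing the marginal covariance as
sigma2_resid * (I + lambda * Z Z') with lambda the variance ratio
sigma2_subject / sigma2_resid, the REML criterion is profiled down to a
one-dimensional function of lambda, which is minimized by bounded
search on the log scale; the fixed effects then follow by generalized
least squares at the optimum.

Everything is computed from per-subject cross-products (X'X, X'y, y'y
per group), which makes a fit O(G p^2) per objective evaluation and
lets the subject-level bootstrap in :mod:`cortmed.mediation` resample
groups without touching row-level data.

Inference on fixed effects is Wald (normal reference); with roughly a
thousand subjects the difference from finite-sample degree-of-freedom
corrections is negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CohortTable

logger = logging.getLogger("cortmed")

_LOG_LAMBDA_LO = np.log(1e-10)
_LOG_LAMBDA_HI = np.log(1e6)
_BOUNDARY_LAMBDA = 2e-10


class RankDeficientError(ValueError):
    """Design matrix is not full rank; names the collinear columns."""


@dataclass
class DesignSpec:
    """Fixed-effect layout for one mixed-model fit.

    ``continuous`` entries are numeric columns entered as-is (spline
    basis columns prepared upstream count as continuous terms);
    ``categorical`` maps a column to its reference level, expanded to
    one-hot indicators for the remaining levels; ``interactions`` are
    pairs of term names whose expanded columns are multiplied.
    """

    outcome: str
    continuous: list = field(default_factory=list)
    categorical: dict = field(default_factory=dict)
    interactions: list = field(default_factory=list)
    group: str = "subject_id"

    def variables(self) -> list:
        """All data columns the spec touches (for complete-case filtering)."""
        cols = [self.outcome, self.group]
        cols += list(self.continuous) + list(self.categorical)
        for a, b in self.interactions:
            for t in (a, b):
                if t not in cols:
                    cols.append(t)
        return cols

    def with_terms(self, continuous=(), categorical=None, interactions=()) -> "DesignSpec":
        """A copy with extra terms appended."""
        cat = dict(self.categorical)
        cat.update(categorical or {})
        return DesignSpec(
            outcome=self.outcome,
            continuous=list(self.continuous) + list(continuous),
            categorical=cat,
            interactions=list(self.interactions) + list(interactions),
            group=self.group,
        )

    def without_terms(self, drop) -> "DesignSpec":
        """A copy with the named terms removed (continuous or categorical)."""
        drop = set(drop)
        return DesignSpec(
            outcome=self.outcome,
            continuous=[t for t in self.continuous if t not in drop],
            categorical={k: v for k, v in self.categorical.items() if k not in drop},
            interactions=[p for p in self.interactions if not (set(p) & drop)],
            group=self.group,
        )


def _expand_term(data: pd.DataFrame, term: str, spec: DesignSpec) -> pd.DataFrame:
    if term in spec.categorical:
        ref = spec.categorical[term]
        levels = [lv for lv in pd.unique(data[term].astype(str)) if lv != str(ref)]
        cols = {
            f"{term}[{lv}]": (data[term].astype(str) == lv).astype(float)
            for lv in sorted(levels)
        }
        return pd.DataFrame(cols, index=data.index)
    return pd.DataFrame({term: pd.to_numeric(data[term]).astype(float)}, index=data.index)


def build_design(data: pd.DataFrame | CohortTable, spec: DesignSpec):
    """Construct (y, X, groups) from a data frame and a design spec.

    Applies complete-case filtering on the spec's variables and the
    inclusion rule that a subject contributes at least two rows.
    """
    if isinstance(data, CohortTable):
        data = data.analysis_subset()
    cols = spec.variables()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    sub = data[cols].dropna()
    counts = sub.groupby(spec.group)[spec.outcome].size()
    keep = counts.index[counts >= 2]
    sub = sub[sub[spec.group].isin(keep)]
    if sub[spec.group].nunique() < 2:
        raise ValueError("need at least 2 subjects with >= 2 complete rows each")
    sub = sub.sort_values(spec.group, kind="stable")

    parts = [pd.DataFrame({"Intercept": np.ones(len(sub))}, index=sub.index)]
    expanded: dict[str, pd.DataFrame] = {}
    for term in list(spec.continuous) + list(spec.categorical):
        expanded[term] = _expand_term(sub, term, spec)
        parts.append(expanded[term])
    for a, b in spec.interactions:
        ea = expanded.get(a, _expand_term(sub, a, spec))
        eb = expanded.get(b, _expand_term(sub, b, spec))
        prod = {
            f"{ca}:{cb}": ea[ca].to_numpy() * eb[cb].to_numpy()
            for ca in ea.columns
            for cb in eb.columns
        }
        parts.append(pd.DataFrame(prod, index=sub.index))
    X = pd.concat(parts, axis=1)
    y = pd.to_numeric(sub[spec.outcome]).astype(float)
    groups = sub[spec.group]
    _check_rank(X)
    return y, X, groups


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = [X.columns[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise RankDeficientError(f"design matrix rank deficient; collinear terms: {bad}")


# ---------------------------------------------------------------------------
# sufficient statistics and the profiled REML criterion


@dataclass
class GroupStats:
    """Per-subject cross-products; everything a REML fit needs.

    With the intercept as the first design column, the column sums
    X_i'1 and y_i'1 and the group size n_i are all slices of XtX/Xty,
    so only three arrays are stored.
    """

    xtx: np.ndarray  # (G, p, p)
    xty: np.ndarray  # (G, p)
    yty: np.ndarray  # (G,)
    columns: list

    @property
    def n_groups(self) -> int:
        return self.xtx.shape[0]

    @property
    def n_obs(self) -> int:
        return float(self.xtx[:, 0, 0].sum())

    def subset(self, idx: np.ndarray) -> "GroupStats":
        """Resampled/sub-selected copy (bootstrap draws pass indices)."""
        return GroupStats(self.xtx[idx], self.xty[idx], self.yty[idx], self.columns)


def group_stats(y: np.ndarray, X: np.ndarray, groups: np.ndarray, columns=None) -> GroupStats:
    """Accumulate per-group cross-products (rows must be group-sorted)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(groups, sort=True)
    order = np.argsort(codes, kind="stable")
    X, y, codes = X[order], y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    outer = X[:, :, None] * X[:, None, :]
    xtx = np.add.reduceat(outer, starts, axis=0)
    xty = np.add.reduceat(X * y[:, None], starts, axis=0)
    yty = np.add.reduceat(y * y, starts, axis=0)
    if columns is None:
        columns = [f"x{i}" for i in range(X.shape[1])]
    return GroupStats(xtx, xty, yty, list(columns))


@dataclass
class CollapsedStats:
    """Group stats pooled by group-size class.

    The per-group shrinkage weight in the GLS normal equations depends
    on lambda only through the group size n_i, so groups of equal size
    can be pooled once; every objective evaluation during the lambda
    search is then O(K p^2) with K the number of distinct sizes.
    ``collapse`` accepts per-group multiplicities, which is exactly a
    cluster-bootstrap resample (a subject drawn twice contributes as
    two independent clusters with identical data).
    """

    xtx: np.ndarray  # (p, p) total
    xty: np.ndarray  # (p,) total
    yty: float
    sizes: np.ndarray  # (K,) distinct group sizes
    counts: np.ndarray  # (K,) groups per size class (weighted)
    S: np.ndarray  # (K, p, p) sum of (X_i'1)(X_i'1)' per class
    u: np.ndarray  # (K, p) sum of (y_i'1)(X_i'1) per class
    v: np.ndarray  # (K,) sum of (y_i'1)^2 per class
    columns: list
    n_groups: int

    @property
    def n_obs(self) -> float:
        return float(np.dot(self.sizes, self.counts))


def collapse(st: GroupStats, weights: np.ndarray | None = None) -> CollapsedStats:
    """Pool per-group stats by group size, optionally with multiplicities."""
    n_i = np.rint(st.xtx[:, 0, 0]).astype(np.int64)
    s = st.xtx[:, :, 0]  # X_i' 1
    t = st.xty[:, 0]  # y_i' 1
    outer = s[:, :, None] * s[:, None, :]
    ts = t[:, None] * s
    tt = t * t
    if weights is None:
        w = np.ones(len(n_i))
    else:
        w = np.asarray(weights, dtype=float)
    sizes = np.unique(n_i[w > 0]) if np.any(w > 0) else np.unique(n_i)
    K, p = len(sizes), st.xtx.shape[1]
    S = np.empty((K, p, p))
    u = np.empty((K, p))
    v = np.empty(K)
    counts = np.empty(K)
    for k, nk in enumerate(sizes):
        mask = n_i == nk
        wk = w[mask]
        counts[k] = wk.sum()
        S[k] = np.einsum("g,gij->ij", wk, outer[mask])
        u[k] = wk @ ts[mask]
        v[k] = wk @ tt[mask]
    xtx = np.einsum("g,gij->ij", w, st.xtx)
    xty = w @ st.xty
    yty = float(w @ st.yty)
    return CollapsedStats(
        xtx=xtx, xty=xty, yty=yty, sizes=sizes, counts=counts,
        S=S, u=u, v=v, columns=st.columns, n_groups=int(round(w.sum())),
    )


def _assemble(cs: CollapsedStats, lam: float):
    """GLS normal equations at variance ratio lam."""
    c = lam / (1.0 + cs.sizes * lam)  # shrinkage weight per size class
    A = cs.xtx - np.einsum("k,kij->ij", c, cs.S)
    b = cs.xty - c @ cs.u
    q = cs.yty - np.dot(c, cs.v)
    return A, b, q


def _profiled_neg2_reml(log_lam: float, cs: CollapsedStats) -> float:
    lam = np.exp(log_lam)
    A, b, q = _assemble(cs, lam)
    n = cs.n_obs
    p = A.shape[0]
    try:
        cho = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss_w = q - b @ beta
    if rss_w <= 0:
        return np.inf
    sigma2 = rss_w / (n - p)
    logdet_lambda = np.dot(cs.counts, np.log1p(cs.sizes * lam))
    logdet_A = 2.0 * np.log(np.diag(cho)).sum()
    return (n - p) * (np.log(2 * np.pi) + np.log(sigma2) + 1.0) + logdet_lambda + logdet_A


def fit_from_stats(st: GroupStats | CollapsedStats, xtol: float = 1e-10):
    """REML fit from sufficient statistics.

    Returns a dict with point estimates, covariance of the fixed
    effects, variance components, the REML log-likelihood and a
    convergence flag.  The variance-ratio boundary (lambda -> 0) is
    detected and reported as sigma2_subject = 0 exactly, where the fit
    coincides with ordinary least squares on the pooled rows.
    """
    cs = collapse(st) if isinstance(st, GroupStats) else st
    res = optimize.minimize_scalar(
        _profiled_neg2_reml,
        bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
        args=(cs,),
        method="bounded",
        options={"xatol": xtol},
    )
    lam = float(np.exp(res.x))
    crit = float(res.fun)
    # candidate at the lambda -> 0 boundary (pooled OLS)
    crit0 = _profiled_neg2_reml(_LOG_LAMBDA_LO, cs)
    if crit0 <= crit + 1e-9:
        lam, crit = np.exp(_LOG_LAMBDA_LO), crit0
    boundary = lam <= _BOUNDARY_LAMBDA
    if boundary:
        logger.info("variance ratio at boundary; sigma2_subject reported as 0")
        lam_eff = 0.0
    else:
        lam_eff = lam
    A, b, q = _assemble(cs, lam_eff)
    n = cs.n_obs
    p = A.shape[0]
    beta = np.linalg.solve(A, b)
    rss_w = q - b @ beta
    sigma2_resid = rss_w / (n - p)
    sigma2_subject = 0.0 if boundary else lam_eff * sigma2_resid
    cov = sigma2_resid * np.linalg.inv(A)
    return {
        "params": beta,
        "cov_params": cov,
        "sigma2_subject": float(sigma2_subject),
        "sigma2_resid": float(sigma2_resid),
        "llf": -0.5 * crit,
        "n_obs": int(round(n)),
        "n_groups": cs.n_groups,
        "converged": bool(res.success) or boundary,
        "columns": cs.columns,
    }


# ---------------------------------------------------------------------------
# model / results objects


class RandomInterceptLMM:
    """Random-intercept linear mixed model (Model object).

    Construct from arrays, or from a data frame plus a
    :class:`DesignSpec` via :meth:`from_spec`; :meth:`fit` returns a
    :class:`LMMResults`.
    """

    def __init__(self, endog, exog: pd.DataFrame, groups):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.groups = np.asarray(groups)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self._stats = group_stats(
            self.endog, exog.to_numpy(), self.groups, columns=list(exog.columns)
        )

    @classmethod
    def from_spec(cls, data, spec: DesignSpec) -> "RandomInterceptLMM":
        y, X, groups = build_design(data, spec)
        model = cls(y.to_numpy(), X, groups.to_numpy())
        model.spec = spec
        return model

    def fit(self) -> "LMMResults":
        return LMMResults(self, fit_from_stats(self._stats))


class LMMResults:
    """REML estimates with Wald inference (Results object)."""

    def __init__(self, model, raw: dict):
        self.model = model
        self._raw = raw
        cols = raw["columns"]
        self.params = pd.Series(raw["params"], index=cols)
        self.cov_params = pd.DataFrame(raw["cov_params"], index=cols, columns=cols)
        self.bse = pd.Series(np.sqrt(np.diag(raw["cov_params"])), index=cols)
        self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=cols
        )
        self.sigma2_subject = raw["sigma2_subject"]
        self.sigma2_resid = raw["sigma2_resid"]
        self.llf = raw["llf"]
        self.n_obs = raw["n_obs"]
        self.n_groups = raw["n_groups"]
        self.converged = raw["converged"]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def wald_test(self, terms) -> tuple:
        """Joint Wald chi-square test on the named coefficients.

        Returns ``(statistic, df, p)``; a single term reduces to z^2.
        """
        if isinstance(terms, str):
            terms = [terms]
        unknown = [t for t in terms if t not in self.params.index]
        if unknown:
            raise KeyError(f"unknown terms: {unknown}")
        b = self.params[terms].to_numpy()
        C = self.cov_params.loc[terms, terms].to_numpy()
        stat = float(b @ np.linalg.solve(C, b))
        df = len(terms)
        return stat, df, float(stats.chi2.sf(stat, df))

    def coef_table(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
            }
        )

    def summary(self) -> str:
        head = (
            f"Random-intercept LMM (REML)\n"
            f"  n_obs={self.n_obs}  n_subjects={self.n_groups}  "
            f"converged={self.converged}\n"
            f"  sigma2_subject={self.sigma2_subject:.6g}  "
            f"sigma2_resid={self.sigma2_resid:.6g}  llf={self.llf:.4f}\n"
        )
        return head + self.coef_table().to_string(float_format=lambda v: f"{v:.4f}")


def fit_lmm(data, spec: DesignSpec) -> LMMResults:
    """Convenience wrapper: build the design and fit by REML."""
    return RandomInterceptLMM.from_spec(data, spec).fit()


# ---------------------------------------------------------------------------
# restricted cubic spline basis

_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def rcs_basis(x, n_knots: int = 4, knots=None):
    """Restricted (natural) cubic spline basis.

    Returns ``(basis, knots)`` where ``basis`` has ``n_knots - 1``
    columns: the identity term followed by the restricted truncated
    cubic terms, linear beyond the boundary knots.  Knots default to
    conventional quantiles of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots < 3:
            raise ValueError("n_knots must be >= 3")
        qs = _KNOT_QUANTILES.get(n_knots)
        if qs is None:
            qs = np.linspace(0.05, 0.95, n_knots)
        if len(np.unique(x)) <= n_knots:
            raise ValueError("not enough distinct values to place the knots")
        knots = np.quantile(x, qs)
        if len(np.unique(knots)) < n_knots:
            raise ValueError("knot locations are not distinct")
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols), knots
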