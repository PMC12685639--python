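"""Readers and writers for the package's tabular formats.

Two dialects, both tab-separated with a header line, '.' decimal point
and empty fields for missing values:

* the long-format cohort table (one row per subject-visit), and
* GWAS summary statistics (one row per SNP), column-compatible with the
  common two-sample exposure/outcome layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cortmed")

#: canonical internal name <- accepted file column names
COHORT_SCHEMA: dict[str, str] = {
    "subject_id": "subject_id",
    "visit_time_years": "visit_time",
    "visit_time": "visit_time",
    "bapwv_ms": "bapwv",
    "bapwv": "bapwv",
    "cortisol_ugdl": "cortisol",
    "cortisol": "cortisol",
    "map_mmHg": "map",
    "sbp_mmHg": "sbp",
    "dbp_mmHg": "dbp",
    "diabetes_duration_months": "diabetes_duration",
    "vfa_cm2": "vfa",
    "sfa_cm2": "sfa",
    "waist_cm": "waist",
    "hip_cm": "hip",
    "ldl_mmoll": "ldl",
    "hba1c_pct": "hba1c",
    "tc_mmoll": "tc",
    "tg_mmoll": "tg",
    "hdl_mmoll": "hdl",
    "fbg_mmoll": "fbg",
}

REQUIRED_COHORT_COLUMNS = ("subject_id", "visit_time", "bapwv")

GWAS_REQUIRED = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
GWAS_OPTIONAL = ("eaf", "n")

VALID_ALLELES = frozenset("ACGT")


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class ValidationError(ValueError):
    """Row-level content violates the format contract."""


@dataclass
class CohortTable:
    """Long-format repeated-measures cohort records.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per subject-visit, canonical column names.
    flagged_subjects : list
        Subjects with fewer than two outcome measurements; retained in
        the table but excluded by the mixed-model inclusion rule.
    n_dropped_missing_outcome : int
        Rows removed at read time because the outcome was missing.
    """

    df: pd.DataFrame
    flagged_subjects: list = field(default_factory=list)
    n_dropped_missing_outcome: int = 0

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def analysis_subset(self) -> pd.DataFrame:
        """Rows belonging to subjects with >= 2 outcome measurements."""
        return self.df[~self.df["subject_id"].isin(self.flagged_subjects)]


def _canonicalize(df: pd.DataFrame, schema: dict[str, str] | None) -> pd.DataFrame:
    mapping = dict(COHORT_SCHEMA)
    if schema:
        mapping.update(schema)
    rename = {c: mapping[c] for c in df.columns if c in mapping}
    return df.rename(columns=rename)


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort TSV into a :class:`CohortTable`.

    Rows with a missing outcome are dropped (with a logged count) and
    subjects with fewer than two remaining visits are flagged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    df = _canonicalize(df, schema)
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col}")
    bad = df.index[pd.to_numeric(df["bapwv"], errors="coerce").isna() & df["bapwv"].notna()]
    if len(bad):
        raise SchemaError(f"non-numeric outcome value at row index {bad[0]}")
    df["bapwv"] = pd.to_numeric(df["bapwv"])
    n_before = len(df)
    df = df.dropna(subset=["bapwv"]).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing outcome", n_dropped)
    counts = df.groupby("subject_id").size()
    flagged = sorted(counts.index[counts < 2])
    if flagged:
        logger.info("flagged %d subjects with <2 outcome measurements", len(flagged))
    max_visits = int(counts.max()) if len(counts) else 0
    if max_visits > 8:
        logger.warning("subject with %d visits exceeds the expected 2-8 range", max_visits)
    return CohortTable(df=df, flagged_subjects=flagged, n_dropped_missing_outcome=n_dropped)


def write_cohort(table: CohortTable | pd.DataFrame, path: str | Path) -> None:
    df = table.df if isinstance(table, CohortTable) else table
    df.to_csv(path, sep="\t", index=False, na_rep="")


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics (effect sizes on the effect allele)."""

    df: pd.DataFrame
    trait: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def restrict(self, rsids) -> "GwasSummary":
        """Row filter to an explicit instrument list (order preserved)."""
        keep = self.df[self.df["snp"].isin(set(rsids))].reset_index(drop=True)
        return GwasSummary(df=keep, trait=self.trait)


def read_gwas_summary(path: str | Path, trait: str = "") -> GwasSummary:
    """Read and validate a GWAS summary TSV.

    Rejects non-positive standard errors, duplicated rsids and alleles
    outside {A, C, G, T}; alleles are uppercased.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_gwas(df, trait=trait)


def validate_gwas(df: pd.DataFrame, trait: str = "") -> GwasSummary:
    for col in GWAS_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col}")
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("effect_allele", "other_allele"):
        bad = df.loc[~df[col].isin(VALID_ALLELES), col]
        if len(bad):
            raise ValidationError(f"allele outside A/C/G/T in column {col}: {bad.iloc[0]!r}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValidationError(f"duplicated snp identifier: {dup}")
    if (pd.to_numeric(df["se"]) <= 0).any():
        raise ValidationError("standard error must be positive for every row")
    for col in ("beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col])
    if "eaf" in df.columns:
        df["eaf"] = pd.to_numeric(df["eaf"])
    df = df.reset_index(drop=True)
    return GwasSummary(df=df, trait=trait)


def write_gwas_summary(summary: GwasSummary | pd.DataFrame, path: str | Path) -> None:
    df = summary.df if isinstance(summary, GwasSummary) else summary
    df.to_csv(path, sep="\t", index=False, na_rep="")


def spawn_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic substream derived from a master seed.

    Every source of randomness in the package flows from one master
    seed through this helper; the ``path`` integers identify the stage
    (and, for bootstrap replicates, the replicate index), so substreams
    are reproducible and non-overlapping.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(path))
    return np.random.default_rng(ss)
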