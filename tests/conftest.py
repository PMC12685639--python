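import numpy as np
import pandas as pd
import pytest

import cortmed as cm
from cortmed.lmm import DesignSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic synthetic cohort (400 subjects) with derived columns."""
    table, truth = cm.generate_cohort(cm.SynthCohortParams(n_subjects=400), seed=7)
    return cm.derive_variables(table), truth


@pytest.fixture(scope="session")
def gwas_triplet():
    """Deterministic summary triplet with 50 strong instruments."""
    params = cm.SynthGwasParams(n_instruments=50)
    exp, med, out, truth = cm.generate_gwas_triplet(params, seed=11)
    return exp, med, out, truth


@pytest.fixture()
def total_effect_spec():
    return DesignSpec(outcome="bapwv", continuous=["log10_cortisol", "visit_time"])


@pytest.fixture()
def cohort_file(tmp_path):
    """A tiny hand-written cohort TSV: 2 subjects x 2 visits."""
    path = tmp_path / "cohort.tsv"
    df = pd.DataFrame(
        {
            "subject_id": ["A", "A", "B", "B"],
            "visit_time_years": [0.0, 1.0, 0.0, 2.0],
            "bapwv_ms": [15.0, 15.5, 17.0, 18.0],
            "cortisol_ugdl": [10.0, 10.0, 14.0, 14.0],
            "sbp_mmHg": [120.0, 122.0, 135.0, 133.0],
            "dbp_mmHg": [70.0, 72.0, 85.0, 84.0],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def balanced_anova_components(y, groups):
    """Closed-form one-way ANOVA variance components for balanced designs.

    For g groups of m replicates, REML equals sigma2_resid = MSW and
    sigma2_subject = (MSB - MSW) / m when the latter is positive.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    m = len(y) // len(levels)
    means = np.array([y[groups == g].mean() for g in levels])
    grand = y.mean()
    msb = m * np.sum((means - grand) ** 2) / (len(levels) - 1)
    msw = sum(np.sum((y[groups == g] - means[i]) ** 2) for i, g in enumerate(levels))
    msw /= len(levels) * (m - 1)
    return msw, (msb - msw) / m
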