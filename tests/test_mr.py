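import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import cortmed as cm
from cortmed.io import GwasSummary, validate_gwas
from cortmed.mr import HarmonizationError, egger, harmonize, ivw, wald_ratio


def _summary(rows, trait=""):
    return validate_gwas(pd.DataFrame(rows), trait=trait)


def _row(snp, ea, oa, beta, se=0.01, eaf=0.3, pval=1e-9):
    return {
        "snp": snp, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
    }


class TestHarmonize:
    def test_identical_alleles_kept(self):
        exp = _summary([_row("rs1", "A", "G", 0.1)])
        out = _summary([_row("rs1", "A", "G", 0.05)])
        h = harmonize(exp, out)
        assert h.table.iloc[0]["action"] == "kept"
        assert h.table.iloc[0]["beta_outcome"] == 0.05

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = _summary([_row("rs1", "A", "G", 0.1, eaf=0.3)])
        out = _summary([_row("rs1", "G", "A", 0.05, eaf=0.7)])
        h = harmonize(exp, out)
        row = h.table.iloc[0]
        assert row["action"] == "sign_flipped"
        assert row["beta_outcome"] == -0.05
        assert row["eaf_outcome"] == pytest.approx(0.3)

    def test_strand_complement_aligned(self):
        exp = _summary([_row("rs1", "A", "G", 0.1)])
        out = _summary([_row("rs1", "T", "C", 0.05)])
        h = harmonize(exp, out)
        row = h.table.iloc[0]
        assert row["action"] == "strand_complemented"
        assert row["beta_outcome"] == 0.05

    def test_ambiguous_palindromic_dropped(self):
        exp = _summary([_row("rs1", "A", "T", 0.1, eaf=0.50), _row("rs2", "A", "G", 0.1)])
        out = _summary([_row("rs1", "A", "T", 0.05, eaf=0.30), _row("rs2", "A", "G", 0.05)])
        h = harmonize(exp, out)
        assert h.table.set_index("snp").loc["rs1", "action"] == "dropped_palindromic"

    def test_orientable_palindromic_kept(self):
        exp = _summary([_row("rs1", "A", "T", 0.1, eaf=0.2), _row("rs2", "C", "A", 0.1)])
        out = _summary([_row("rs1", "A", "T", 0.05, eaf=0.22), _row("rs2", "C", "A", 0.05)])
        h = harmonize(exp, out)
        assert h.table.set_index("snp").loc["rs1", "action"] == "kept"

    def test_discordant_palindromic_frequencies_flip(self):
        exp = _summary([_row("rs1", "A", "T", 0.1, eaf=0.2), _row("rs2", "C", "A", 0.1)])
        out = _summary([_row("rs1", "A", "T", 0.05, eaf=0.8), _row("rs2", "C", "A", 0.05)])
        h = harmonize(exp, out)
        row = h.table.set_index("snp").loc["rs1"]
        assert row["action"] == "sign_flipped"
        assert row["beta_outcome"] == -0.05

    def test_unmatched_rsid_dropped(self):
        exp = _summary([_row("rs1", "A", "G", 0.1), _row("rs2", "C", "T", 0.1)])
        out = _summary([_row("rs1", "A", "G", 0.05)])
        h = harmonize(exp, out)
        assert h.table.set_index("snp").loc["rs2", "action"] == "dropped_unmatched"
        assert h.n_kept == 1

    def test_no_kept_rows_is_error(self):
        exp = _summary([_row("rs1", "A", "G", 0.1)])
        out = _summary([_row("rs9", "A", "G", 0.05)])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_idempotent(self, gwas_triplet):
        exp, _, out, _ = gwas_triplet
        h1 = harmonize(exp, out)
        kept = h1.kept
        exp2 = GwasSummary(df=pd.DataFrame({
            "snp": kept["snp"], "effect_allele": kept["effect_allele"],
            "other_allele": kept["other_allele"], "eaf": kept["eaf_exposure"],
            "beta": kept["beta_exposure"], "se": kept["se_exposure"],
            "pval": 1e-9,
        }))
        out2 = GwasSummary(df=pd.DataFrame({
            "snp": kept["snp"], "effect_allele": kept["effect_allele"],
            "other_allele": kept["other_allele"], "eaf": kept["eaf_outcome"],
            "beta": kept["beta_outcome"], "se": kept["se_outcome"],
            "pval": 1e-9,
        }))
        h2 = harmonize(exp2, out2)
        assert np.allclose(h2.kept["beta_outcome"], kept["beta_outcome"])
        assert (h2.table["action"] == "kept").all()


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.01)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.1, 0.0, 0.01).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.01)

    def test_first_order_se_close_to_delta_method(self):
        # second-order delta expansion adds a (se_exp/beta_exp)^2 term;
        # with a strong instrument the two agree within 5%
        beta_exp, se_exp, beta_out, se_out = 0.1, 0.005, 0.02, 0.01
        first = wald_ratio(beta_exp, beta_out, se_out).se
        second = np.sqrt(
            se_out**2 / beta_exp**2
            + beta_out**2 * se_exp**2 / beta_exp**4
        )
        assert first == pytest.approx(second, rel=0.05)


def _hset(bx, by, so, eaf=None):
    k = len(bx)
    table = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(k)],
        "effect_allele": ["A"] * k, "other_allele": ["G"] * k,
        "beta_exposure": bx, "se_exposure": [0.01] * k,
        "eaf_exposure": eaf if eaf is not None else [0.3] * k,
        "beta_outcome": by, "se_outcome": so,
        "eaf_outcome": eaf if eaf is not None else [0.3] * k,
        "action": ["kept"] * k,
    })
    return cm.mr.HarmonizedSet(table=table)


class TestIVW:
    def test_homogeneous_ratios(self):
        h = _hset([0.1, 0.2, 0.4], [0.01, 0.02, 0.04], [0.01, 0.01, 0.01])
        est, het = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.1)
        assert het.Q == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_weighted_mean_and_q(self):
        # ratios (0.1, 0.2, 0.3) with equal weights 100 -> beta 0.2,
        # Q = 100*(0.01 + 0 + 0.01) = 2
        h = _hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.01, 0.01, 0.01])
        est, het = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.2)
        assert het.Q == pytest.approx(2.0)
        assert het.df == 2

    def test_matches_origin_constrained_wls(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = rng.integers(3, 30)
            bx = rng.normal(0.1, 0.05, k)
            by = rng.normal(0.02, 0.02, k)
            so = rng.uniform(0.005, 0.05, k)
            est, _ = ivw(_hset(bx, by, so), model="fixed")
            ref = sm.WLS(by, bx, weights=1.0 / so**2).fit()
            assert est.beta == pytest.approx(ref.params[0], abs=1e-10)
            assert est.se == pytest.approx(ref.bse[0] / np.sqrt(ref.scale), abs=1e-10)

    def test_single_snp_delegates_to_wald_ratio(self):
        h = _hset([0.1], [0.02], [0.01])
        est, het = ivw(h)
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.2)
        assert het is None

    def test_random_model_never_deflates_se(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0.1, 0.02, 10)
        by = 0.2 * bx + rng.normal(0, 0.03, 10)
        so = np.full(10, 0.01)
        fixed, _ = ivw(_hset(bx, by, so), model="fixed")
        random, _ = ivw(_hset(bx, by, so), model="random")
        assert random.se >= fixed.se

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, c):
        bx = np.array([0.1, 0.15, 0.2])
        by = np.array([0.02, 0.02, 0.05])
        so = np.array([0.01, 0.02, 0.01])
        base, _ = ivw(_hset(bx, by, so))
        scaled, _ = ivw(_hset(c * bx, by, so))
        assert scaled.beta * c == pytest.approx(base.beta, rel=1e-9)


class TestEgger:
    def test_exact_line_recovers_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.3 * bx
        slope, intercept = egger(_hset(bx, by, [0.01] * 4))
        assert intercept.intercept == pytest.approx(0.01, abs=1e-8)
        assert slope.beta == pytest.approx(0.3, abs=1e-8)

    def test_fewer_than_three_snps_not_computable(self):
        slope, intercept = egger(_hset([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))
        assert slope is None and intercept is None

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            k = int(rng.integers(5, 25))
            bx = np.abs(rng.normal(0.1, 0.05, k))
            by = rng.normal(0.02, 0.03, k)
            so = rng.uniform(0.005, 0.05, k)
            slope, intercept = egger(_hset(bx, by, so))
            X = sm.add_constant(bx)
            ref = sm.WLS(by, X, weights=1.0 / so**2).fit()
            assert slope.beta == pytest.approx(ref.params[1], abs=1e-10)
            assert intercept.intercept == pytest.approx(ref.params[0], abs=1e-10)
            # statsmodels always scales by sqrt(RSS/df); ours floors at 1
            scale = max(1.0, ref.scale) / ref.scale
            assert slope.se == pytest.approx(ref.bse[1] * np.sqrt(scale), rel=1e-8)

    def test_negative_exposure_rows_reoriented(self):
        bx = np.array([0.05, -0.1, 0.15, -0.2])
        by = 0.01 + 0.3 * bx
        # flipping both betas of a row leaves the regression through
        # reoriented points identical
        slope, intercept = egger(_hset(bx, by, [0.01] * 4))
        bx2 = np.abs(bx)
        by2 = np.where(bx < 0, -by, by)
        slope2, intercept2 = egger(_hset(bx2, by2, [0.01] * 4))
        assert slope.beta == pytest.approx(slope2.beta, abs=1e-12)
        assert intercept.intercept == pytest.approx(intercept2.intercept, abs=1e-12)

    def test_type_one_error_of_intercept_test(self):
        # no-pleiotropy simulation: intercept rejection near alpha
        rng = np.random.default_rng(11)
        reps, rej = 500, 0
        for _ in range(reps):
            k = 20
            bx = np.abs(rng.normal(0.1, 0.03, k))
            so = np.full(k, 0.01)
            by = 0.2 * bx + rng.normal(0, so)
            _, intercept = egger(_hset(bx, by, so))
            rej += intercept.p < 0.05
        rate = rej / reps
        band = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < band + 0.01


class TestInstrumentStrength:
    def test_strong_instrument(self):
        s = cm.instrument_strength(_summary([_row("rs1", "A", "G", 0.1, se=0.01)]))
        assert s.f_stats[0] == pytest.approx(100.0)
        assert not s.weak

    def test_weak_instrument(self):
        s = cm.instrument_strength(_summary([_row("rs1", "A", "G", 0.01, se=0.01)]))
        assert s.f_stats[0] == pytest.approx(1.0)
        assert s.weak


class TestTwoSampleMRModel:
    def test_fit_bundles_all_diagnostics(self, gwas_triplet):
        exp, _, out, truth = gwas_triplet
        res = cm.TwoSampleMR(exp, out, binary_outcome=True).fit()
        assert res.ivw.method == "ivw"
        assert res.ivw.odds_ratio == pytest.approx(np.exp(res.ivw.beta))
        assert res.heterogeneity is not None and res.egger_intercept is not None
        assert res.strength.mean_f > 10
        assert "IVW" in res.summary()

    def test_instrument_restriction(self, gwas_triplet):
        exp, _, out, _ = gwas_triplet
        instr = list(exp.df["snp"][:5])
        model = cm.TwoSampleMR(exp, out, instruments=instr)
        assert model.exposure.n_snps == 5
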