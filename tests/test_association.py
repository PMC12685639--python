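import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import cortmed as cm
from cortmed.association import (
    ModelLadder,
    assign_quartiles,
    baseline_exposure,
    bh_adjust,
    derive_variables,
    followup_window_anova,
    interaction_scan,
    mean_arterial_pressure,
    rcs_nonlinearity_test,
    run_model_ladder,
    sensitivity_leave_one_out,
)
from cortmed.lmm import DesignSpec


class TestDerivedVariables:
    @pytest.mark.parametrize(
        "sbp,dbp,expected",
        [
            (130.1, 76.1, 94.1),  # total-cohort means
            (129.8, 77.5, 94.9),  # male
            (130.7, 73.5, 92.6),  # female
            (80.0, 80.0, 80.0),  # equality case
        ],
    )
    def test_mean_arterial_pressure(self, sbp, dbp, expected):
        assert mean_arterial_pressure(sbp, dbp) == pytest.approx(expected, abs=0.05)

    def test_log10_exposure(self):
        df = pd.DataFrame(
            {"subject_id": ["A"], "visit_time": [0.0], "bapwv": [15.0],
             "cortisol": [10.0], "sbp": [120.0], "dbp": [70.0]}
        )
        out = derive_variables(df)
        assert out["log10_cortisol"].iloc[0] == pytest.approx(1.0)
        assert out["map"].iloc[0] == pytest.approx(120 / 3 + 140 / 3)

    def test_nonpositive_cortisol_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["A"], "visit_time": [0.0], "bapwv": [15.0],
             "cortisol": [0.0], "sbp": [120.0], "dbp": [70.0]}
        )
        with pytest.raises(ValueError, match="positive"):
            derive_variables(df)

    def test_bapwv_averaged_from_sides(self):
        df = pd.DataFrame(
            {"subject_id": ["A"], "visit_time": [0.0],
             "bapwv_left": [15.0], "bapwv_right": [17.0],
             "bapwv": [np.nan], "cortisol": [10.0],
             "sbp": [120.0], "dbp": [70.0]}
        )
        out = derive_variables(df)
        assert out["bapwv"].iloc[0] == 16.0


class TestQuartiles:
    def test_value_on_published_cuts_lands_in_q3(self):
        # quartile bounds reported for the exposure: Q2 ends at 11.89,
        # Q3 spans 11.90-14.73, so 12.0 must land in Q3
        cuts = np.array([9.525, 11.895, 14.735])
        coding = cm.ExposureCoding(cut_points=cuts, labels=np.array([]))
        label = 1 + int(np.sum(12.0 > cuts))
        assert label == 3

    def test_equal_spaced_values_one_per_quartile(self):
        coding = assign_quartiles(np.array([1.0, 2.0, 3.0, 4.0]))
        assert sorted(coding.labels) == [1, 2, 3, 4]

    def test_tie_goes_to_lower_quartile(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        coding = assign_quartiles(x)
        cut = np.percentile(x, 25)
        at_cut = x == cut
        if at_cut.any():
            assert (coding.labels[at_cut] == 1).all()

    def test_uniform_draws_balanced(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=1000)
        coding = assign_quartiles(x)
        counts = np.bincount(coding.labels)[1:]
        assert counts.sum() == 1000
        assert np.all(np.abs(counts - 250) <= 4 * np.sqrt(250 * 0.75))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles(np.array([1.0, 1.0, 2.0, 2.0]))

    def test_high_is_upper_half(self):
        coding = assign_quartiles(np.arange(8.0))
        assert list(coding.high) == [0, 0, 0, 0, 1, 1, 1, 1]


class TestBH:
    def test_hand_executed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_matches_statsmodels_and_permutation_invariant(self, ps, rnd):
        ours = bh_adjust(ps)
        _, ref, _, _ = multipletests(ps, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        permuted = bh_adjust([ps[i] for i in perm])
        assert np.allclose(permuted, ours[perm], atol=1e-12)


class TestModelLadder:
    def test_ladder_nesting(self):
        specs = ModelLadder().specs()
        crude = set(specs["crude"].continuous)
        m1 = set(specs["model1"].continuous) | set(specs["model1"].categorical)
        m2 = set(specs["model2"].continuous) | set(specs["model2"].categorical)
        assert crude <= m1 <= m2

    def test_table_shape_and_adjustment_monotone(self, small_cohort):
        table, _ = small_cohort
        out = run_model_ladder(table)
        assert set(out["model"]) == {"crude", "model1", "model2"}
        # continuous, Q2-Q4, trend, high-vs-low = 6 rows per model
        assert len(out) == 18
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        trend = out[(out["term"] == "trend")]
        assert len(trend) == 3

    def test_categories_only_coding(self, small_cohort):
        table, _ = small_cohort
        out = run_model_ladder(table, codings=("categories",))
        assert len(out) == 3
        assert set(out["term"]) == {"exposure_high"}

    def test_crude_estimate_recovers_total_effect(self, small_cohort):
        table, truth = small_cohort
        out = run_model_ladder(table, codings=("continuous",))
        row = out[(out["model"] == "crude")].iloc[0]
        se = (row["ci_upper"] - row["ci_lower"]) / (2 * 1.96)
        assert abs(row["beta"] - truth.true_total_effect) < 3.5 * se


class TestInteractionScan:
    def test_empty_covariable_list(self, small_cohort):
        table, _ = small_cohort
        spec = DesignSpec(outcome="bapwv", continuous=["log10_cortisol", "age"])
        out = interaction_scan(table, spec, [])
        assert len(out) == 0

    def test_true_interaction_detected(self):
        rng = np.random.default_rng(14)
        G, m = 800, 3
        g = np.repeat(np.arange(G), m)
        x = rng.normal(size=G)[g]
        z = (rng.random(G) < 0.5).astype(float)[g]
        w = rng.normal(size=G)[g]
        y = 0.3 * x + 0.8 * x * z + rng.normal(0, 1, G)[g] + rng.normal(0, 1, G * m)
        df = pd.DataFrame({"subject_id": g, "y": y, "x": x, "z": z, "w": w})
        spec = DesignSpec(outcome="y", continuous=["x", "z", "w"])
        out = interaction_scan(df, spec, ["z", "w"], exposure="x").set_index("covariable")
        assert out.loc["z", "p"] < 0.01
        assert out.loc["z", "p"] < out.loc["w", "p"]


class TestRCSNonlinearity:
    def test_linear_truth_not_rejected_and_overall_detected(self, small_cohort):
        table, _ = small_cohort
        spec = DesignSpec(outcome="bapwv", continuous=["log10_cortisol", "age"])
        p_nl, p_all = rcs_nonlinearity_test(table, spec)
        assert p_nl > 0.01  # no nonlinear signal in a linear generator
        assert 0 <= p_all <= 1

    def test_quadratic_effect_detected(self):
        rng = np.random.default_rng(15)
        G, m = 1000, 3
        g = np.repeat(np.arange(G), m)
        x = rng.uniform(-2, 2, G)[g]
        y = 0.5 * x**2 + rng.normal(0, 0.8, G)[g] + rng.normal(0, 0.8, G * m)
        df = pd.DataFrame({"subject_id": g, "y": y, "x": x})
        spec = DesignSpec(outcome="y", continuous=["x"])
        p_nl, _ = rcs_nonlinearity_test(df, spec, exposure="x")
        assert p_nl < 0.001

    def test_constant_exposure_rejected(self):
        df = pd.DataFrame(
            {"subject_id": [0, 0, 1, 1], "y": [1.0, 2.0, 3.0, 4.0], "x": [1.0] * 4}
        )
        with pytest.raises(ValueError):
            rcs_nonlinearity_test(df, DesignSpec(outcome="y", continuous=["x"]), exposure="x")


class TestWindowAnova:
    def test_empty_window_marked_not_testable(self, small_cohort):
        table, _ = small_cohort
        out = followup_window_anova(
            table, windows=((0.0, 0.0), (100.0, 200.0))
        )
        assert bool(out.iloc[0]["testable"])
        assert not bool(out.iloc[1]["testable"])

    def test_strong_group_effect_rejected(self, small_cohort):
        table, _ = small_cohort
        df = table.df.copy()
        base = baseline_exposure(df)
        coding = assign_quartiles(base.to_numpy())
        lab = pd.Series(coding.labels, index=base.index)
        df["bapwv"] = df["bapwv"] + 5.0 * df["subject_id"].map(lab)
        out = followup_window_anova(cm.CohortTable(df=df))
        assert (out[out["testable"]]["p"] < 1e-6).all()


class TestSensitivity:
    def test_empty_removable_equals_main_model(self, small_cohort):
        table, _ = small_cohort
        spec = ModelLadder().specs()["model2"]
        out = sensitivity_leave_one_out(table, spec, [])
        assert len(out) == 1 and out.iloc[0]["removed"] == "none"

    def test_null_covariate_removal_barely_moves_estimate(self, small_cohort):
        table, _ = small_cohort
        spec = DesignSpec(
            outcome="bapwv", continuous=["log10_cortisol", "age", "ldl", "hba1c"]
        )
        out = sensitivity_leave_one_out(table, spec, ["ldl", "hba1c"]).set_index("removed")
        main = out.loc["none"]
        for name in ("ldl", "hba1c"):
            assert abs(out.loc[name, "beta"] - main["beta"]) < 0.5 * main["se"]

    def test_agents_removed_jointly(self, small_cohort):
        table, _ = small_cohort
        spec = ModelLadder().specs()["model2"]
        out = sensitivity_leave_one_out(table, spec, ["agents"])
        assert set(out["removed"]) == {"none", "agents"}

    def test_confounder_removal_shifts_toward_crude(self):
        # age confounds: it raises both exposure and outcome
        rng = np.random.default_rng(16)
        G, m = 1500, 3
        g = np.repeat(np.arange(G), m)
        age = rng.normal(size=G)
        x = 0.8 * age + rng.normal(0, 0.6, G)
        y = (0.5 * x + 1.0 * age)[g] + rng.normal(0, 1, G)[g] + rng.normal(0, 1, G * m)
        df = pd.DataFrame({"subject_id": g, "y": y, "x": x[g], "age": age[g]})
        adjusted = sensitivity_leave_one_out(
            df, DesignSpec(outcome="y", continuous=["x", "age"]), ["age"], exposure="x"
        ).set_index("removed")
        crude = cm.fit_lmm(df, DesignSpec(outcome="y", continuous=["x"])).params["x"]
        beta_full = adjusted.loc["none", "beta"]
        beta_wo_age = adjusted.loc["age", "beta"]
        assert abs(beta_wo_age - crude) < abs(beta_full - crude)
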