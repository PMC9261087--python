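"""Rank statistics, correlations, and the VIF redundancy protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from oracles import brute_u1_rbc, brute_vif
from speechgraphs import (
    AnalysisConfig,
    bonferroni,
    collinear_matrix,
    layered_vif,
    mann_whitney_rbc,
    run_analysis,
    spearman,
    vif,
    vif_stepwise,
)
from speechgraphs.feature_pipeline import FEATURE_COLUMNS

floats = st_.floats(allow_nan=False, allow_infinity=False, min_value=-1e6, max_value=1e6)
group = st_.lists(floats, min_size=1, max_size=12)


class TestMannWhitneyRBC:
    def test_complete_separation(self):
        res = mann_whitney_rbc([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0 and res.rbc == -1

    def test_identical_groups_have_zero_effect(self):
        res = mann_whitney_rbc([1, 2, 3], [1, 2, 3])
        assert res.rbc == 0

    def test_full_ties_give_p_one(self):
        res = mann_whitney_rbc([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0 and res.rbc == 0.0

    @settings(deadline=None, derandomize=True)
    @given(x=group, y=group)
    def test_rbc_identity_against_pair_counting(self, x, y):
        res = mann_whitney_rbc(x, y)
        u1, rbc = brute_u1_rbc(x, y)
        assert res.u_statistic == pytest.approx(u1)
        assert res.rbc == pytest.approx(rbc)

    @settings(deadline=None, derandomize=True)
    @given(x=group, y=group)
    def test_swapping_groups_negates_rbc(self, x, y):
        assert mann_whitney_rbc(x, y).rbc == pytest.approx(-mann_whitney_rbc(y, x).rbc)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_rbc([], [1.0])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_toy_vector_is_minus_half(self):
        assert spearman([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)

    def test_reversal_is_minus_one(self):
        x = [1.0, 4.0, 2.0, 8.0]
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_zero_variance_flags_degenerate(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert res.degenerate and res.rho == 0.0

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3).rho == pytest.approx(base)


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(1, 0.05), (100, 0.0005), (500, 0.0001)])
    def test_division(self, n, expected):
        assert bonferroni(0.05, n) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestVIF:
    def test_independent_columns_are_near_one(self):
        X = collinear_matrix(1000, {"f1": None, "f2": None}, seed=1)
        vals = vif(X)
        assert ((vals >= 1.0) & (vals < 1.2)).all()

    def test_exact_linear_combination_is_infinite(self):
        X = collinear_matrix(100, {"f1": None, "f2": None}, seed=2)
        X["f3"] = X["f1"] + X["f2"]
        assert vif(X)["f3"] == np.inf

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        cov = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=400)
        got = vif(pd.DataFrame(X, columns=["a", "b", "c"]))
        expected = brute_vif(X)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        X = collinear_matrix(50, {"f1": None, "f2": None}, seed=4)
        X["c"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            vals = vif(X)
        assert "c" not in vals.index


class TestVIFStepwise:
    def test_orthogonal_set_survives_untouched(self):
        X = collinear_matrix(500, {"f1": None, "f2": None, "f3": None}, seed=5)
        rep = vif_stepwise(X, threshold=5.0)
        assert rep.removal_order == ()
        assert set(rep.survivors) == {"f1", "f2", "f3"}

    def test_redundant_column_removed_and_survivors_below_threshold(self):
        # noise sd so population R^2 = 0.9 -> VIF = 10 for the derived column
        sd = np.sqrt(2 * (1 - 0.9) / 0.9)
        X = collinear_matrix(
            2000, {"f1": None, "f2": None, "f3": {"parents": ["f1", "f2"], "noise_sd": sd}}, seed=6
        )
        rep = vif_stepwise(X, threshold=5.0)
        assert len(rep.removal_order) == 1
        survivors = list(rep.survivors)
        check = brute_vif(X[survivors].to_numpy())
        assert (check < 5.0).all()

    def test_single_feature_survives_trivially(self):
        rep = vif_stepwise(pd.DataFrame({"only": [1.0, 2.0, 3.0]}))
        assert set(rep.survivors) == {"only"}

    def test_terminates_within_feature_count(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((200, 2))
        X = pd.DataFrame(
            {f"f{i}": base @ rng.standard_normal(2) + 0.01 * rng.standard_normal(200)
             for i in range(6)}
        )
        rep = vif_stepwise(X, threshold=5.0)
        assert len(rep.removal_order) <= 5
        finite = [v for v in rep.survivors.values() if np.isfinite(v)]
        assert all(v < 5.0 for v in finite)


def _feature_table(n=40, seed=0, inject=None):
    """Synthetic participant x task table over the canonical 36 columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for task in ("picture", "narrative"):
        block = rng.standard_normal((n, len(FEATURE_COLUMNS)))
        df = pd.DataFrame(block, columns=FEATURE_COLUMNS)
        if inject:
            inject(df, rng)
        df.insert(0, "task", task)
        df.insert(0, "participant_id", [f"P{i:03d}" for i in range(n)])
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestLayeredVIF:
    def test_orthogonal_table_survives_all_layers(self):
        table = _feature_table(n=200, seed=1)
        reports = layered_vif(table)
        finals = [r for r in reports if r.stage == 3]
        assert len(finals) == 2  # one per task
        for rep in finals:
            assert rep.removal_order == ()
        stage1 = [r for r in reports if r.stage == 1]
        assert len(stage1) == 2 * 2 * 2 * 3  # task x graph type x mode x domain

    def test_duplicate_column_removed_at_first_shared_layer(self):
        def inject(df, rng):
            df["S_SEQ_NE"] = df["S_SEQ_NN"]  # same domain block: stage-1 duplicate

        reports = layered_vif(_feature_table(n=100, seed=2, inject=inject))
        checked = 0
        for rep in reports:
            if rep.stage == 1 and rep.layer.endswith("SEQ/S/size"):
                assert rep.removal_order
                feat, v = rep.removal_order[0]
                assert feat in {"S_SEQ_NN", "S_SEQ_NE"} and v > 5
                checked += 1
        assert checked == 2  # one block per task

    def test_cross_block_redundancy_caught_at_stage_2(self):
        def inject(df, rng):
            # duplicate across domains within one graph type and mode:
            # stage-1 blocks stay internally orthogonal
            df["S_SEQ_AWD"] = df["S_SEQ_NN"] + 0.01 * rng.standard_normal(len(df))

        reports = layered_vif(_feature_table(n=100, seed=3, inject=inject))
        stage1_removed = [f for r in reports if r.stage == 1 for f, _ in r.removal_order]
        assert not stage1_removed
        stage2_removed = {f for r in reports if r.stage == 2 for f, _ in r.removal_order}
        assert stage2_removed & {"S_SEQ_AWD", "S_SEQ_NN"}

    def test_output_features_are_subset_of_input(self):
        table = _feature_table(n=60, seed=4)
        for rep in layered_vif(table):
            assert set(rep.survivors) <= set(rep.input_features)
            assert {f for f, _ in rep.removal_order} <= set(rep.input_features)


@pytest.fixture(scope="module")
def cohort_tables():
    rng = np.random.default_rng(12)
    n = 30
    groups = ["PS-"] * n + ["PS+"] * n
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(2 * n)],
            "group": groups,
            "bprs_total": np.where(np.array(groups) == "PS+", 40, 22)
            + rng.normal(0, 5, 2 * n),
        }
    )
    table = _feature_table(n=2 * n, seed=13)
    # explicit group effect: controls (PS-) have larger dynamic NN
    effect = np.where(np.array(groups) == "PS-", 1.5, 0.0)
    for task in ("picture", "narrative"):
        mask = table["task"] == task
        table.loc[mask, "D_SEQ_NN"] = table.loc[mask, "D_SEQ_NN"].to_numpy() + effect
    return table, participants


class TestRunAnalysis:
    def test_group_effect_sign_recovered(self, cohort_tables):
        table, participants = cohort_tables
        report = run_analysis(table, participants, AnalysisConfig(correlate="all"))
        row = report.comparisons.query("feature == 'D_SEQ_NN' and task == 'picture'").iloc[0]
        assert row["rbc"] > 0  # first-named group (PS-) stochastically larger
        assert row["n1"] == 30 and row["n2"] == 30

    def test_report_shapes_and_flags(self, cohort_tables, tmp_path):
        table, participants = cohort_tables
        report = run_analysis(table, participants, AnalysisConfig(correlate="all"))
        assert len(report.comparisons) == 36 * 2
        assert set(report.correlations["clinical_measure"]) == {"bprs_total"}
        assert len(report.correlations) == 36 * 2
        report.to_files(tmp_path)
        for name in ("comparisons.csv", "correlations.csv", "vif_layers.csv",
                     "correlation_heatmap.csv"):
            assert (tmp_path / name).exists()

    def test_permuted_labels_calibrate_near_alpha(self, cohort_tables):
        table, participants = cohort_tables
        rng = np.random.default_rng(99)
        pvals = []
        values = table.query("task == 'picture'")["S_AP_DENSITY"].to_numpy()
        for _ in range(400):
            perm = rng.permutation(values)
            pvals.append(mann_whitney_rbc(perm[:30], perm[30:]).p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.08
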