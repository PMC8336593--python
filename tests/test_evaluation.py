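"""CV scenarios, metrics, the combination synergy score and importances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ltrdose.evaluation import (
    combo_score,
    make_folds,
    permutation_importance,
    regression_metrics,
    score_panel,
    synergy_discrimination,
    weight_norms,
)
from ltrdose.features import MONO, FeatureLayout
from ltrdose.synthetic import PanelSpec, simulate_panel
from ltrdose.trainer import HyperParams, init_params, predict
from conftest import random_extended


@pytest.fixture(scope="module")
def panel_records():
    spec = PanelSpec(n_drugs=8, n_cells=3, n_conc=4, seed=21)
    return simulate_panel(spec).records.reset_index(drop=True)


def pair_key(rec):
    return [tuple(sorted((a, b))) for a, b in zip(rec["drug_a"], rec["drug_b"])]


class TestMakeFolds:
    @pytest.mark.parametrize("scenario", ["S1", "S2", "S3", "S4"])
    def test_leakage_guarantees_hold(self, panel_records, scenario):
        plan = make_folds(panel_records, scenario, k=5, seed=3)
        plan.verify(panel_records)   # raises on any violation
        assert len(plan.folds) == 5

    def test_s2_no_test_pair_in_training(self, panel_records):
        plan = make_folds(panel_records, "S2", k=5, seed=0)
        keys = pair_key(panel_records)
        mono = (panel_records["drug_b"] == MONO).to_numpy()
        for train, test in plan.folds:
            train_pairs = {keys[i] for i in train if not mono[i]}
            test_pairs = {keys[i] for i in test}
            assert not train_pairs & test_pairs
            # monotherapies all present in training
            assert mono[train].sum() == mono.sum()

    def test_s3_training_has_zero_mono_rows(self, panel_records):
        plan = make_folds(panel_records, "S3", k=5, seed=0)
        mono = (panel_records["drug_b"] == MONO).to_numpy()
        for train, _ in plan.folds:
            assert mono[train].sum() == 0

    def test_s1_fold_sizes_balanced_per_matrix(self, panel_records):
        k = 4
        plan = make_folds(panel_records, "S1", k=k, seed=1)
        combos = panel_records[panel_records["drug_b"] != MONO]
        n_matrices = combos.groupby(["drug_a", "drug_b", "cell_line"]).ngroups
        for _, test in plan.folds:
            # each fold receives 16/k = 4 cells from every 4x4 matrix
            assert abs(len(test) - len(combos) / k) <= n_matrices
        # stratification: every matrix appears in every fold's test set
        for _, test in plan.folds:
            sub = panel_records.iloc[test]
            assert sub.groupby(["drug_a", "drug_b", "cell_line"]).ngroups == n_matrices

    def test_s4_same_pair_other_cells_stay_in_training(self, panel_records):
        plan = make_folds(panel_records, "S4", k=5, seed=2)
        keys = pair_key(panel_records)
        mono = (panel_records["drug_b"] == MONO).to_numpy()
        found = False
        for train, test in plan.folds:
            test_pairs = {keys[i] for i in test}
            train_pairs = {keys[i] for i in train if not mono[i]}
            if test_pairs & train_pairs:
                found = True
        assert found, "S4 should keep other-cell matrices of test pairs in training"

    def test_fewer_units_than_folds_raises(self, tiny_records):
        with pytest.raises(ValueError, match="folds|pairs"):
            make_folds(tiny_records, "S2", k=5, seed=0)


class TestRegressionMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(50)
        m = regression_metrics(y, y)
        assert m["rmse"] == 0.0
        assert m["pearson"] == pytest.approx(1.0)
        assert m["spearman"] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        y = rng.standard_normal(50)
        assert regression_metrics(y, -y)["pearson"] == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self, rng):
        y, p = rng.standard_normal(100), rng.standard_normal(100)
        m = regression_metrics(y, p)
        pearson = (np.mean(y * p) - y.mean() * p.mean()) / (y.std() * p.std())
        assert m["pearson"] == pytest.approx(pearson, rel=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((y - p) ** 2)), rel=1e-12)
        ry, rp = stats.rankdata(y), stats.rankdata(p)
        spearman = np.corrcoef(ry, rp)[0, 1]
        assert m["spearman"] == pytest.approx(spearman, rel=1e-12)

    def test_constant_input_warns_and_returns_nan(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            m = regression_metrics(np.ones(10), np.arange(10.0))
        assert np.isnan(m["pearson"])


class TestComboScore:
    def test_identical_matrices_identical_scores(self, rng):
        mat = rng.uniform(-50, 100, size=(4, 4))
        ma, mb = rng.uniform(0, 100, 4), rng.uniform(0, 100, 4)
        assert combo_score(mat, ma, mb) == combo_score(mat.copy(), ma, mb)

    def test_null_deviation_scores_zero(self):
        ma = np.array([80.0, 40.0])
        mb = np.array([50.0, -10.0])
        expected = np.array([[80 * 50 / 100, -10.0], [40 * 50 / 100, -10.0]])
        assert combo_score(expected, ma, mb) == pytest.approx(0.0)

    def test_hand_worked_two_by_two(self):
        """Frozen worked example of the expected-growth convention."""
        ma = np.array([80.0, 60.0])
        mb = np.array([50.0, -20.0])
        combo = np.array([[30.0, 10.0], [45.0, -30.0]])
        # per-cell expectations: 40, -20, 30, -20; deviations: 10,-30,-15,10
        assert combo_score(combo, ma, mb) == pytest.approx(-25.0)

    def test_growth_truncated_at_100(self):
        ma, mb = np.array([150.0]), np.array([50.0])
        combo = np.array([[120.0]])
        # truncated: expected 100*50/100 = 50, observed 100 -> score -50
        assert combo_score(combo, ma, mb) == pytest.approx(-50.0)

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValueError, match="shape|finite"):
            combo_score(np.ones((2, 3)), np.ones(2), np.ones(2))
        with pytest.raises(ValueError, match="finite"):
            combo_score(np.array([[np.nan]]), np.ones(1), np.ones(1))

    def test_score_panel_same_routine_both_sides(self, tiny_records):
        predicted = tiny_records["response"].to_numpy()
        scores = score_panel(tiny_records, predicted)
        assert len(scores) == 1
        assert scores.at[0, "measured_score"] == pytest.approx(
            scores.at[0, "predicted_score"])


class TestSynergyDiscrimination:
    @staticmethod
    def frame(measured, predicted):
        return pd.DataFrame({"measured_score": measured,
                             "predicted_score": predicted})

    def test_perfect_ranking_auroc_one(self, rng):
        s = rng.standard_normal(200)
        out = synergy_discrimination(self.frame(s, s), thresholds=(5, 25, 50))
        assert np.allclose(out["auroc"], 1.0)

    def test_random_scores_auroc_half(self, rng):
        measured = rng.standard_normal(4000)
        predicted = rng.standard_normal(4000)
        out = synergy_discrimination(self.frame(measured, predicted),
                                     thresholds=(50,))
        assert abs(out.at[0, "auroc"] - 0.5) < 0.05

    def test_hand_counted_mann_whitney(self):
        out = synergy_discrimination(
            self.frame([4.0, 3.0, 2.0, 1.0], [4.0, 2.0, 3.0, 1.0]),
            thresholds=(50,))
        # positives {4,3} vs negatives {2,1}; 3 of 4 pairs correctly ordered
        assert out.at[0, "auroc"] == pytest.approx(0.75)

    def test_degenerate_threshold_skipped(self):
        with pytest.warns(RuntimeWarning, match="single class"):
            out = synergy_discrimination(
                self.frame([1.0, 1.0, 1.0], [0.3, 0.2, 0.1]), thresholds=(50,))
        assert len(out) == 0


class TestPermutationImportance:
    @staticmethod
    def layout_for(width):
        layout = FeatureLayout()
        layout.add("raw", [f"x{j}" for j in range(width - 1)])
        layout.add("constant", ["1"])
        layout.homogenized = True
        return layout

    def test_constant_column_exactly_zero(self, rng):
        params, _ = random_extended(rng, n=4, n_y=1)
        X = rng.standard_normal((60, 4))
        X[:, 2] = 1.0
        layout = self.layout_for(4)
        y = rng.standard_normal(60)
        imp = permutation_importance(params, X, y, layout, n_perm=5, seed=0)
        assert imp.loc[imp["column"] == "raw:x2", "importance"].iloc[0] == 0.0
        assert "constant:1" not in set(imp["column"])

    def test_irrelevant_feature_near_zero(self, rng):
        """A column the generating model ignores has ~zero importance."""
        params, _ = random_extended(rng, n=5, n_y=1, activation="identity")
        params.lambda_u[3] = 0.0    # feature 3 cannot influence predictions
        X = rng.standard_normal((300, 5))
        y = predict(params, X)[:, 0] + 0.01 * rng.standard_normal(300)
        imp = permutation_importance(params, X, y, self.layout_for(5),
                                     n_perm=20, seed=1)
        row = imp[imp["column"] == "raw:x3"].iloc[0]
        se = row["importance_sd"] / np.sqrt(20)
        assert abs(row["importance"]) <= max(3 * se, 1e-9)


class TestWeightNorms:
    def test_zero_lambda_u_zeroes_feature(self, rng):
        params, _ = random_extended(rng, n=4)
        params.lambda_u[1] = 0.0
        layout = TestPermutationImportance.layout_for(4)
        feat, _ = weight_norms(params, layout)
        assert feat.loc[feat["column"] == "raw:x1", "l2_norm"].iloc[0] == 0.0

    def test_matches_explicit_loop(self, rng):
        params, _ = random_extended(rng, n=6, n_d=3, n_k=4)
        layout = TestPermutationImportance.layout_for(6)
        feat, block = weight_norms(params, layout)
        for j in range(6):
            acc = 0.0
            for d in range(3):
                for k in range(4):
                    acc += params.U[d][j, k] ** 2
            expected = abs(params.lambda_u[j]) * np.sqrt(acc)
            assert feat.at[j, "l2_norm"] == pytest.approx(expected, rel=1e-12)
        manual_block = np.sqrt(np.sum(feat["l2_norm"][:5] ** 2))
        got = block.loc[block["block"] == "raw", "l2_norm"].iloc[0]
        assert got == pytest.approx(manual_block, rel=1e-12)

    def test_uniform_init_gives_equal_norms(self):
        hyper = HyperParams(n_d=2, n_t=3, n_k=4, epochs=1)
        params = init_params(hyper, 5, 1, seed=0)   # rows normalized, lu = 1
        layout = TestPermutationImportance.layout_for(5)
        feat, _ = weight_norms(params, layout)
        np.testing.assert_allclose(feat["l2_norm"], feat["l2_norm"].iloc[0],
                                   rtol=1e-10)

    def test_width_mismatch_raises(self, rng):
        params, _ = random_extended(rng, n=4)
        with pytest.raises(ValueError, match="width"):
            weight_norms(params, TestPermutationImportance.layout_for(9))
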