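import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from leafturgor import COMBINATIONS, evaluate, feature_importance
from leafturgor import models as m


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rep.r2, rep.mse, rep.rmse, rep.mae) == (1.0, 0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        # Y=[1,2,3], y=[2,2,2]: SSE=2, SST=2 -> R2=0; MSE=MAE=2/3
        rep = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)
        assert rep.mse == pytest.approx(2 / 3)
        assert rep.rmse == pytest.approx(np.sqrt(2 / 3))
        assert rep.mae == pytest.approx(2 / 3)

    def test_constant_prediction_at_mean_gives_zero_r2(self):
        Y = np.array([4.0, 7.0, 10.0, 1.0])
        rep = evaluate(Y, np.full(4, Y.mean()))
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_measured_flagged(self):
        rep = evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.r2) and "zero_variance_measured" in rep.flags

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=50)
        y = Y + rng.normal(scale=0.5, size=50)
        rep = evaluate(Y, y)
        assert abs(rep.r2 - r2_score(Y, y)) < 1e-9
        assert abs(rep.mse - mean_squared_error(Y, y)) < 1e-9
        assert abs(rep.mae - mean_absolute_error(Y, y)) < 1e-9
        assert rep.mse == pytest.approx(rep.rmse**2, abs=1e-12)
        assert rep.mae <= rep.rmse + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1.0, 2.0], [1.0])


class TestCombinationsAndFeatures:
    def test_combination_table_structure(self):
        assert all("SWC" not in COMBINATIONS[i].inputs for i in (1, 2))
        assert all("SWC" in COMBINATIONS[i].inputs for i in (3, 4))
        assert COMBINATIONS[2].output_mode == COMBINATIONS[4].output_mode == "substate"

    def test_feature_table_columns_match_combination(self, small_season):
        dataset, _, labels = small_season
        t1 = m.build_feature_table(dataset, labels, COMBINATIONS[1])
        t3 = m.build_feature_table(dataset, labels, COMBINATIONS[3])
        assert len(t1) == len(dataset)
        assert set(COMBINATIONS[1].inputs) < set(t1.columns)
        assert "SWC" not in COMBINATIONS[1].inputs
        assert "SWC" in t3.columns and len(t3.columns) == len(t1.columns) + 1

    def test_substate_rows_partition_into_observed_states(self, small_season):
        dataset, _, labels = small_season
        t4 = m.build_feature_table(dataset, labels, COMBINATIONS[4])
        assert set(t4["state"].unique()) == set(labels["state"].unique())

    def test_missing_input_column_rejected(self, small_season):
        dataset, _, labels = small_season
        with pytest.raises(ValueError, match="SWC"):
            m.build_feature_table(dataset.drop(columns="SWC"), labels, COMBINATIONS[3])


class TestSplit:
    def test_eighty_twenty_counts(self, small_season):
        dataset, _, labels = small_season
        table = m.build_feature_table(dataset, labels, COMBINATIONS[4])
        out = m.split_train_test(table, seed=0)
        # stratified rounding may shift the total by one row
        assert abs((out["split"] == "train").sum() - 0.8 * len(out)) <= 1.0

    def test_same_seed_same_split(self, small_season):
        dataset, _, labels = small_season
        table = m.build_feature_table(dataset, labels, COMBINATIONS[4])
        a = m.split_train_test(table, seed=42)["split"]
        b = m.split_train_test(table, seed=42)["split"]
        assert (a == b).all()

    def test_stratified_split_preserves_state_fractions(self, small_season):
        dataset, _, labels = small_season
        table = m.build_feature_table(dataset, labels, COMBINATIONS[4])
        out = m.split_train_test(table, seed=0)
        for _, group in out.groupby("state"):
            n_train = (group["split"] == "train").sum()
            assert abs(n_train - 0.8 * len(group)) <= 1.0

    def test_bad_fraction_rejected(self, small_season):
        dataset, _, labels = small_season
        table = m.build_feature_table(dataset, labels, COMBINATIONS[1])
        with pytest.raises(ValueError, match="fraction"):
            m.split_train_test(table, fraction=1.2)


def _affine_table(n=400, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "Rs": rng.uniform(0, 800, n),
            "T": rng.uniform(10, 35, n),
            "RH": rng.uniform(30, 90, n),
            "WS": rng.uniform(0, 1, n),
            "VPD": rng.uniform(0, 3, n),
            "SWC": rng.uniform(14, 26, n),
        }
    )
    y = 5.0 + 0.04 * X["Rs"] - 1.5 * X["SWC"] + noise * rng.normal(size=n)
    table = X.assign(
        P_p=y,
        state="I",
        date=pd.Timestamp("2021-07-01"),
        treatment="TB",
    )
    return m.split_train_test(table, seed=seed, stratify=False)


class TestTrainPredict:
    @pytest.mark.parametrize("technique", m.TECHNIQUES)
    def test_noise_free_affine_target_is_learnable(self, technique):
        table = _affine_table()
        pred = m.train(technique, table, COMBINATIONS[3], seed=0)
        test = table[table["split"] == "test"]
        rep = evaluate(test["P_p"], pred.predict(test))
        assert rep.r2 > 0.99

    def test_shuffled_target_control_has_no_skill(self):
        table = _affine_table()
        rng = np.random.default_rng(1)
        table["P_p"] = rng.permutation(table["P_p"].to_numpy())
        pred = m.train("random_forest", table, COMBINATIONS[3], seed=0)
        test = table[table["split"] == "test"]
        rep = evaluate(test["P_p"], pred.predict(test))
        assert rep.r2 < 0.2

    def test_degenerate_target_yields_constant_predictor(self):
        table = _affine_table()
        table["P_p"] = 7.5
        with pytest.warns(UserWarning, match="degenerate"):
            pred = m.train("random_forest", table, COMBINATIONS[3], seed=0)
        assert np.allclose(pred.predict(table), 7.5)

    def test_fixed_seed_reports_are_identical(self, small_season):
        dataset, _, labels = small_season
        a = m.fit_and_report(dataset, labels, 4, "random_forest", seed=3)
        b = m.fit_and_report(dataset, labels, 4, "random_forest", seed=3)
        assert a.metrics.to_dict() == b.metrics.to_dict()

    def test_substate_predictor_routes_by_state(self, small_season):
        dataset, _, labels = small_season
        table = m.split_train_test(
            m.build_feature_table(dataset, labels, COMBINATIONS[4]), seed=0
        )
        pred = m.train("random_forest", table, COMBINATIONS[4], seed=0)
        assert set(pred.models) == set(table["state"].unique())
        bogus = table.head(5).assign(state="III")
        with pytest.raises(ValueError, match="no sub-model"):
            pred.predict(bogus)


class TestFeatureImportance:
    def test_single_driver_dominates(self):
        table = _affine_table()
        table["P_p"] = 2.0 + 0.1 * table["Rs"]
        pred = m.train("random_forest", table, COMBINATIONS[3], seed=0)
        imp = feature_importance(pred)["pooled"]
        assert imp.index[0] == "Rs" and imp.iloc[0] > 0.95

    def test_importances_normalized(self, small_season):
        dataset, _, labels = small_season
        table = m.split_train_test(
            m.build_feature_table(dataset, labels, COMBINATIONS[4]), seed=0
        )
        pred = m.train("random_forest", table, COMBINATIONS[4], seed=0)
        for series in feature_importance(pred).values():
            assert series.sum() == pytest.approx(1.0, abs=1e-9)

    def test_swc_ranks_first_in_both_states(self, small_season):
        dataset, _, labels = small_season
        table = m.split_train_test(
            m.build_feature_table(dataset, labels, COMBINATIONS[4]), seed=0
        )
        pred = m.train("random_forest", table, COMBINATIONS[4], seed=0)
        imp = feature_importance(pred)
        assert imp["I"].index[0] == "SWC"
        assert imp["II"].index[0] == "SWC"

    def test_svm_falls_back_to_permutation(self):
        table = _affine_table(n=200)
        pred = m.train("svm", table, COMBINATIONS[3], seed=0)
        imp = feature_importance(pred, table)
        assert imp["pooled"].name == "permutation"


class TestMatrix:
    def test_report_count_and_swc_gain(self, small_season):
        dataset, _, labels = small_season
        reports, summary = m.run_experiment_matrix(
            dataset, labels, seed=0,
            techniques=("xgboost",), combinations=(1, 2, 3, 4),
        )
        assert len(reports) == 4
        r2 = summary.set_index("combination")["r2"]
        # adding SWC (1->3, 2->4) never hurts on generator data
        assert r2.loc[3] >= r2.loc[1]
        assert r2.loc[4] >= r2.loc[2]

    def test_failures_recorded_not_raised(self, small_season):
        dataset, _, labels = small_season
        reports, summary = m.run_experiment_matrix(
            dataset.drop(columns="SWC"), labels, seed=0,
            techniques=("xgboost",), combinations=(1, 3),
        )
        by_comb = {r.combination: r for r in reports}
        assert by_comb[1].error is None
        assert "SWC" in by_comb[3].error
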