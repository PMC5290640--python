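"""Feature ranking, CFS, training, grid search, curves, prediction."""

import numpy as np
import pandas as pd
import pytest

from kinconf.ml import (
    SplitSpec,
    TrainedModel,
    cfs_subset,
    evaluate,
    grid_search,
    incremental_feature_accuracy,
    learning_curve,
    predict,
    rank_features,
    train,
)

RNG = np.random.default_rng(99)


def wrapped(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def separated_matrix(factory, n=40, d=6, signal_cols=(0,), sep=160.0, sd=10.0):
    """Class 0 centered at -sep/2, class 1 at +sep/2 on signal columns;
    uniform noise elsewhere."""
    c0 = RNG.uniform(-180, 180, size=(n, d))
    c1 = RNG.uniform(-180, 180, size=(n, d))
    for j in signal_cols:
        c0[:, j] = wrapped(RNG.normal(-sep / 2, sd, n))
        c1[:, j] = wrapped(RNG.normal(sep / 2, sd, n))
    return factory(c0, c1)


class TestRankFeatures:
    def test_perfect_separator_ranks_first(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=50, sep=170.0, sd=8.0)
        ranked = rank_features(fm, folds=5, seed=0)
        assert ranked.names[0] == "Phi_1"
        assert ranked.table.loc["Phi_1", "average_rank"] == pytest.approx(1.0)

    def test_constant_feature_lands_in_worst_band(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=50)
        fm.values["Phi_6"] = 42.0  # constant: zero information
        ranked = rank_features(fm, folds=5, seed=0)
        position = ranked.names.index("Phi_6")
        assert position >= len(ranked.names) // 2

    def test_duplicated_feature_gets_adjacent_ranks(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=50, sep=170.0, sd=8.0)
        fm.values["Phi_2"] = fm.values["Phi_1"]  # exact duplicate
        ranked = rank_features(fm, folds=5, seed=0)
        assert ranked.names[:2] == ["Phi_1", "Phi_2"]  # tie-break: canonical order
        r1 = ranked.table.loc["Phi_1", "average_rank"]
        r2 = ranked.table.loc["Phi_2", "average_rank"]
        assert r2 - r1 == pytest.approx(1.0)

    def test_single_class_raises(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=20)
        fm.labels[:] = "active"
        with pytest.raises(ValueError):
            rank_features(fm, folds=5, seed=0)

    def test_unknown_evaluator_rejected(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=20)
        with pytest.raises(ValueError):
            rank_features(fm, evaluators=("oner", "cfs"), folds=5, seed=0)

    def test_deterministic_given_seed(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30)
        r1 = rank_features(fm, folds=5, seed=3)
        r2 = rank_features(fm, folds=5, seed=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestCfs:
    def test_redundant_duplicate_excluded(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=60, sep=170.0, sd=8.0)
        fm.values["Phi_2"] = fm.values["Phi_1"]
        subset = cfs_subset(fm, seed=0)
        assert len({"Phi_1", "Phi_2"} & set(subset)) == 1

    def test_single_informative_feature_selected(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=60, sep=170.0, sd=8.0)
        subset = cfs_subset(fm, seed=0)
        assert "Phi_1" in subset

    def test_all_noise_yields_tiny_subset(self):
        from conftest import make_angle_matrix

        rng = np.random.default_rng(1234)
        c0 = rng.uniform(-180, 180, size=(40, 5))
        c1 = rng.uniform(-180, 180, size=(40, 5))
        fm = make_angle_matrix(c0, c1)
        assert len(cfs_subset(fm, seed=0)) <= 1


class TestTrainPredict:
    def test_separable_data_trains_to_perfection(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=40, sep=170.0, sd=5.0)
        model = train(fm, seed=0)
        rep = evaluate(model, fm, fm.labels)
        assert rep.accuracy == 1.0

    @pytest.mark.parametrize("algorithm", ["random_forest", "naive_bayes",
                                           "neural_network", "svm"])
    def test_all_algorithms_fit_and_predict(self, angle_matrix_factory, algorithm):
        fm = separated_matrix(angle_matrix_factory, n=30, sep=170.0, sd=5.0)
        model = train(fm, algorithm=algorithm, seed=0)
        pred = predict(model, fm)
        assert set(pred["predicted_state"]) <= {"active", "inactive"}
        assert ((pred["score"] >= 0) & (pred["score"] <= 1)).all()
        assert (pred["predicted_state"] == fm.labels).mean() > 0.9

    def test_same_seed_identical_predictions(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=40, sep=120.0, sd=40.0)
        p1 = predict(train(fm, seed=7), fm)
        p2 = predict(train(fm, seed=7), fm)
        pd.testing.assert_frame_equal(p1, p2)

    def test_shuffled_labels_give_chance_accuracy(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=100, sep=170.0, sd=5.0)
        rng = np.random.default_rng(0)
        shuffled = fm.labels.copy()
        shuffled[:] = rng.permutation(shuffled.values)
        fm.labels = shuffled
        lc = learning_curve(fm, train_sizes=[100], repeats=3, seed=0)
        assert lc.loc[100, "mean_accuracy"] == pytest.approx(0.5, abs=0.1)

    def test_unknown_algorithm_rejected(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=20)
        with pytest.raises(ValueError):
            train(fm, algorithm="decision_stump", seed=0)

    def test_all_features_missing_row_still_predicted(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30, sep=170.0, sd=5.0)
        model = train(fm, seed=0)
        holed = fm.subset([f.name for f in fm.features])
        holed.values.iloc[0, :] = np.nan
        pred = predict(model, holed)
        assert pred["predicted_state"].notna().all()
        assert pred["low_information"].iloc[0]
        assert not pred["low_information"].iloc[1:].any()

    def test_missing_model_feature_is_schema_error(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30)
        model = train(fm, seed=0)
        narrower = fm.subset([f.name for f in fm.features][:-1])
        with pytest.raises(KeyError):
            predict(model, narrower)

    def test_model_archive_round_trip(self, angle_matrix_factory, tmp_path):
        fm = separated_matrix(angle_matrix_factory, n=30, sep=170.0, sd=5.0)
        model = train(fm, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        again = TrainedModel.load(path)
        pd.testing.assert_frame_equal(predict(model, fm), predict(again, fm))


class TestGridSearch:
    def test_singleton_grid_returned(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30)
        best, table = grid_search(fm, None, grid={"n_estimators": [37]}, folds=3, seed=0)
        assert best == {"n_estimators": 37}

    def test_cv_table_row_count(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30)
        grid = {"n_estimators": [10, 20], "max_features": ["sqrt", 0.5]}
        _, table = grid_search(fm, None, grid=grid, folds=3, seed=0)
        assert len(table) == 4 * 3

    def test_reasonable_point_beats_degenerate(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=60, d=8,
                              signal_cols=(0, 1, 2), sep=110.0, sd=45.0)
        grid = {"n_estimators": [1, 100]}
        best, _ = grid_search(fm, None, grid=grid, folds=5, seed=0)
        assert best["n_estimators"] == 100

    def test_empty_grid_rejected(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=20)
        with pytest.raises(ValueError):
            grid_search(fm, None, grid={}, folds=3, seed=0)


class TestCurves:
    def test_incremental_plateau_at_two_signal_features(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=120, d=6,
                              signal_cols=(0, 1), sep=150.0, sd=25.0)
        ranked = rank_features(fm, folds=5, seed=0)
        curve = incremental_feature_accuracy(ranked, fm, k_max=4, seed=0)
        assert curve.loc[2, "test_accuracy"] >= 0.95
        assert curve.loc[4, "test_accuracy"] >= curve.loc[1, "test_accuracy"] - 0.02

    def test_zero_k_rejected(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=30)
        ranked = rank_features(fm, folds=5, seed=0)
        with pytest.raises(ValueError):
            incremental_feature_accuracy(ranked, fm, k_max=0, seed=0)

    def test_learning_curve_monotone_and_deterministic(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=150, sep=150.0, sd=30.0)
        lc1 = learning_curve(fm, train_sizes=[10, 50, 150], repeats=3, seed=0)
        lc2 = learning_curve(fm, train_sizes=[10, 50, 150], repeats=3, seed=0)
        pd.testing.assert_frame_equal(lc1, lc2)
        means = lc1["mean_accuracy"].tolist()
        assert means[-1] >= means[0] - 0.02

    def test_learning_curve_size_exhausts_data(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=25)
        with pytest.raises(ValueError):
            learning_curve(fm, train_sizes=[50], repeats=1, seed=0)


class TestSplitSpec:
    def test_balanced_split(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=40)
        spec = SplitSpec(n_train_per_class=15, seed=0)
        train_idx, test_idx = spec.split(fm.labels)
        counts = fm.labels.loc[train_idx].value_counts()
        assert counts["active"] == counts["inactive"] == 15
        assert len(test_idx) == 80 - 30
        assert len(train_idx.intersection(test_idx)) == 0

    def test_insufficient_rows_raise(self, angle_matrix_factory):
        fm = separated_matrix(angle_matrix_factory, n=10)
        with pytest.raises(ValueError):
            SplitSpec(n_train_per_class=11).split(fm.labels)
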