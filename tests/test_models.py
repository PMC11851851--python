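"""Classifier-family contracts: fitting, prediction, architectures, search."""

import numpy as np
import pytest

import painsense as ps
from painsense.exceptions import ParameterError, ShapeError, TrainingError
from painsense.models import build_cnn, build_rnn, dropout_rates

# small-capacity settings for quick fixtures; dropout eased to suit the
# 16/8-unit dense layers (the default 0.5/0.3 rates target far wider layers)
FAST_CNN = {"conv_filters": (4, 8), "dense_units": (16, 8), "epochs": 30,
            "lr": 0.01, "batch_size": 16,
            "conv_dropout": 0.1, "dense_dropout": (0.2, 0.1)}
FAST_RNN = {"lstm_units": (32,), "dense_units": (32,), "epochs": 10,
            "lr": 0.01, "batch_size": 16, "seq_shape": (4, 5)}


class TestBaselines:
    @pytest.mark.parametrize("family", ["svm", "knn", "rf"])
    def test_separable_data_training_accuracy_one(self, family, separable_table):
        fm, labels = separable_table
        model = ps.train(ps.ModelSpec(family), fm, labels)
        pred, proba = ps.predict(model, fm)
        assert (pred == labels).mean() == 1.0
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_knn_unanimous_neighbourhood(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        model = ps.train(ps.ModelSpec("knn"), X, y)
        pred, _ = ps.predict(model, np.array([[0.1]]))
        assert pred[0] == "a"

    def test_rf_memorizes_separable_training_data(self, separable_table):
        fm, labels = separable_table
        model = ps.train(ps.ModelSpec("rf"), fm, labels)
        pred, _ = ps.predict(model, fm)
        assert (pred == labels).mean() >= 0.99

    @pytest.mark.parametrize("family", ["svm", "knn", "rf"])
    def test_deterministic_under_seed(self, family, separable_table):
        fm, labels = separable_table
        p1, _ = ps.predict(ps.train(ps.ModelSpec(family, seed=4), fm, labels), fm)
        p2, _ = ps.predict(ps.train(ps.ModelSpec(family, seed=4), fm, labels), fm)
        np.testing.assert_array_equal(p1, p2)

    def test_column_permutation_invariance(self, separable_table):
        """Consistently permuting feature columns at train and predict time
        leaves svm/knn/rf predictions unchanged."""
        fm, labels = separable_table
        X = fm.values
        perm = np.random.default_rng(0).permutation(X.shape[1])
        for family in ("svm", "knn", "rf"):
            base, _ = ps.predict(ps.train(ps.ModelSpec(family), X, labels), X)
            permuted, _ = ps.predict(
                ps.train(ps.ModelSpec(family), X[:, perm], labels), X[:, perm]
            )
            np.testing.assert_array_equal(base, permuted)


class TestTrainValidation:
    def test_single_class_rejected(self, rng):
        with pytest.raises(TrainingError):
            ps.train(ps.ModelSpec("svm"), rng.standard_normal((5, 3)), np.zeros(5))

    def test_nan_rejected(self):
        X = np.full((6, 2), np.nan)
        with pytest.raises(TrainingError):
            ps.train(ps.ModelSpec("svm"), X, np.repeat([0, 1], 3))

    def test_feature_count_mismatch_on_predict(self, separable_table):
        fm, labels = separable_table
        model = ps.train(ps.ModelSpec("knn"), fm, labels)
        with pytest.raises(ShapeError):
            ps.predict(model, fm.values[:, :5])

    def test_unknown_family(self):
        with pytest.raises(ParameterError):
            ps.ModelSpec("gru")


class TestArchitectures:
    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_cnn_output_width(self, n_classes):
        layers = build_cnn(n_classes)
        last = layers[-1]
        assert last.kind == "dense"
        assert dict(last.params) == {"units": n_classes, "activation": "softmax"}

    def test_cnn_dropout_sequence(self):
        assert dropout_rates(build_cnn(2)) == [0.25, 0.25, 0.5, 0.3]

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_rnn_output_width(self, n_classes):
        last = build_rnn(n_classes)[-1]
        assert dict(last.params)["units"] == n_classes

    def test_rnn_default_units_in_range(self):
        units = [dict(l.params)["units"] for l in build_rnn(2) if l.kind == "lstm"]
        assert units and all(64 <= u <= 256 for u in units)
        assert units == sorted(units, reverse=True)

    def test_rnn_unit_warning_outside_range(self):
        with pytest.warns(UserWarning, match="32-512"):
            build_rnn(2, lstm_units=(16, 8))

    def test_rnn_lstm_layers_use_tanh_with_dropout(self):
        layers = build_rnn(3)
        kinds = [l.kind for l in layers]
        for i, l in enumerate(layers):
            if l.kind == "lstm":
                assert dict(l.params)["activation"] == "tanh"
                assert kinds[i + 1] == "dropout"


class TestNeuralFamilies:
    def test_cnn_learns_separable_data(self, separable_table):
        fm, labels = separable_table
        spec = ps.ModelSpec("cnn", hyperparameters=FAST_CNN, seed=0)
        model = ps.train(spec, fm, labels)
        pred, proba = ps.predict(model, fm)
        assert (pred == labels).mean() >= 0.9
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert model.history is not None and len(model.history) == FAST_CNN["epochs"]

    def test_cnn_three_class_output_width(self, rng):
        fm, labels = ps.generate_feature_table((20, 20, 20), 12, effect_size=5.0, seed=2)
        spec = ps.ModelSpec("cnn", n_classes=3, hyperparameters=FAST_CNN)
        model = ps.train(spec, fm, labels)
        _, proba = ps.predict(model, fm)
        assert proba.shape == (60, 3)

    def test_rnn_learns_separable_data(self, separable_table):
        fm, labels = separable_table
        spec = ps.ModelSpec("rnn", hyperparameters=FAST_RNN, seed=0)
        model = ps.train(spec, fm, labels)
        pred, _ = ps.predict(model, fm)
        assert (pred == labels).mean() >= 0.9

    def test_rnn_zero_input_gives_constant_rows(self, separable_table):
        fm, labels = separable_table
        spec = ps.ModelSpec("rnn", hyperparameters=FAST_RNN, seed=1)
        model = ps.train(spec, fm, labels)
        _, proba = ps.predict(model, np.zeros((7, fm.n_features)))
        # identical bias-driven distribution for every row
        np.testing.assert_allclose(proba, np.tile(proba[0], (7, 1)), atol=1e-12)

    def test_dropout_zero_forward_deterministic(self, separable_table):
        fm, labels = separable_table
        hp = {**FAST_CNN, "conv_dropout": 0.0, "dense_dropout": (0.0, 0.0),
              "epochs": 2}
        model = ps.train(ps.ModelSpec("cnn", hyperparameters=hp), fm, labels)
        _, p1 = ps.predict(model, fm)
        _, p2 = ps.predict(model, fm)
        np.testing.assert_array_equal(p1, p2)

    def test_permuting_rows_permutes_outputs(self, separable_table):
        fm, labels = separable_table
        model = ps.train(ps.ModelSpec("cnn", hyperparameters=FAST_CNN), fm, labels)
        perm = np.random.default_rng(3).permutation(fm.n_samples)
        _, base = ps.predict(model, fm.values)
        _, permuted = ps.predict(model, fm.values[perm])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_training_loss_decreases_on_separable_data(self):
        """Soft property: final epoch loss below the first in >=90% of seeds."""
        wins = 0
        for seed in range(10):
            fm, labels = ps.generate_feature_table((30, 30), 16, effect_size=4.0,
                                                   seed=seed)
            spec = ps.ModelSpec("cnn", hyperparameters={**FAST_CNN, "epochs": 8},
                                seed=seed)
            model = ps.train(spec, fm, labels)
            hist = model.history
            if hist["loss"].iloc[-1] < hist["loss"].iloc[0]:
                wins += 1
        assert wins >= 9


class TestGridSearch:
    def _data(self):
        return ps.generate_feature_table((25, 25), 10, effect_size=5.0, seed=0)

    def test_single_point_grid_returned(self):
        fm, labels = self._data()
        space = ps.GridSearchSpace((0.1,), (0.01,), (3,))
        spec = ps.ModelSpec("cnn", hyperparameters=FAST_CNN)
        best, results = ps.grid_search(space, fm, labels, folds=2, spec=spec)
        assert best == {"dropout": 0.1, "lr": 0.01, "epochs": 3}
        assert len(results) == 1

    def test_best_member_is_table_maximum(self):
        fm, labels = self._data()
        space = ps.GridSearchSpace((0.0, 0.5), (0.01, 0.3), (2, 4))
        spec = ps.ModelSpec("cnn", hyperparameters=FAST_CNN)
        best, results = ps.grid_search(space, fm, labels, folds=2, spec=spec, seed=1)
        assert len(results) == 8
        top = results["mean_accuracy"].max()
        row = results[
            (results["dropout"] == best["dropout"])
            & (results["lr"] == best["lr"])
            & (results["epochs"] == best["epochs"])
        ]
        assert float(row["mean_accuracy"].iloc[0]) == top
        # closure: returned member comes from the cartesian product
        assert best["dropout"] in space.dropout_rates
        assert best["lr"] in space.learning_rates
        assert best["epochs"] in space.epoch_counts

    def test_validation_split_mode(self):
        fm, labels = self._data()
        space = ps.GridSearchSpace((0.0,), (0.01,), (2,))
        spec = ps.ModelSpec("cnn", hyperparameters=FAST_CNN)
        best, results = ps.grid_search(space, fm, labels, folds=0.25, spec=spec)
        assert len(results) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            ps.GridSearchSpace((), (0.01,), (2,)).validate()

    def test_out_of_range_dropout_rejected(self):
        with pytest.raises(ParameterError):
            ps.GridSearchSpace((0.95,), (0.01,), (2,)).validate()
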