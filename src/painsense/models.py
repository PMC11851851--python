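"""Classifier families for pain-level prediction.

Five families share one train/predict contract: SVM (RBF kernel, C=1.0,
gamma="scale"), k-nearest neighbours (k=3, Euclidean), random forest (100
trees, Gini splits), a 1-D CNN and a stacked-LSTM network — the neural
families trained with Adam on categorical cross-entropy.  Features are
standardised with parameters fitted on the training matrix only; the fitted
scaler travels with the model.  Baseline families are backed by
scikit-learn; the neural families by the package's numpy layers
(:mod:`painsense._nn`).

A grid search over dropout rate, learning rate and epoch count is provided
for the neural families, scored by mean validation accuracy over stratified
folds (or a single validation split).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._nn import CNN1DClassifier, LSTMClassifier, softmax
from .eeg_io import LabelVector
from .exceptions import ParameterError, ShapeError, TrainingError
from .features import FeatureMatrix

FAMILIES = ("svm", "knn", "rf", "cnn", "rnn")

_DEFAULT_HYPERPARAMETERS = {
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale", "platt": False},
    "knn": {"n_neighbors": 3, "metric": "euclidean"},
    "rf": {"n_estimators": 100, "criterion": "gini"},
    "cnn": {
        "conv_filters": (32, 64),
        "kernel_size": 3,
        "pool_size": 2,
        "conv_dropout": 0.25,
        "dense_units": (128, 64),
        "dense_dropout": (0.5, 0.3),
        "lr": 9e-5,
        "epochs": 100,
        "batch_size": 32,
    },
    "rnn": {
        "lstm_units": (128, 64),
        "lstm_dropout": 0.3,
        "dense_units": (64,),
        "seq_shape": None,
        "n_channels": None,
        "lr": 1e-3,
        "epochs": None,  # resolved per task: 100 binary, 50 ternary
        "batch_size": 32,
    },
}


@dataclass
class ModelSpec:
    """One classifier configuration: family, class count, hyperparameters."""

    family: str
    n_classes: int = 2
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_classes not in (2, 3):
            raise ParameterError("n_classes must be 2 or 3")
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        if self.family == "rnn" and merged["epochs"] is None:
            merged["epochs"] = 100 if self.n_classes == 2 else 50
        self.hyperparameters = merged


# ---------------------------------------------------------------------------
# Architecture descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    params: tuple  # sorted (name, value) pairs, hashable


def _layer(kind: str, **params) -> LayerSpec:
    return LayerSpec(kind, tuple(sorted(params.items())))


def build_cnn(n_classes: int, **overrides) -> list[LayerSpec]:
    """Describe the CNN: conv(ReLU)->pool->dropout(0.25) blocks, flatten,
    two dense ReLU layers with dropout 0.5 then 0.3, softmax output."""
    hp = dict(_DEFAULT_HYPERPARAMETERS["cnn"])
    hp.update(overrides)
    if n_classes not in (2, 3):
        raise ParameterError("n_classes must be 2 or 3")
    layers: list[LayerSpec] = []
    for filters in hp["conv_filters"]:
        layers.append(_layer("conv", filters=filters, kernel=hp["kernel_size"],
                             activation="relu"))
        layers.append(_layer("pool", size=hp["pool_size"]))
        layers.append(_layer("dropout", rate=hp["conv_dropout"]))
    layers.append(_layer("flatten"))
    for units, rate in zip(hp["dense_units"], hp["dense_dropout"]):
        layers.append(_layer("dense", units=units, activation="relu"))
        layers.append(_layer("dropout", rate=rate))
    layers.append(_layer("dense", units=n_classes, activation="softmax"))
    return layers


def build_rnn(n_classes: int, **overrides) -> list[LayerSpec]:
    """Describe the RNN: stacked LSTM (tanh) layers with dropout after each,
    descending into dense ReLU layers and a softmax output.

    Unit counts far outside 32-512 degrade representation learning; a
    configuration warning is emitted for them.
    """
    hp = dict(_DEFAULT_HYPERPARAMETERS["rnn"])
    hp.update(overrides)
    if n_classes not in (2, 3):
        raise ParameterError("n_classes must be 2 or 3")
    for units in tuple(hp["lstm_units"]) + tuple(hp["dense_units"]):
        if not 32 <= units <= 512:
            warnings.warn(
                f"unit count {units} outside the effective 32-512 range",
                UserWarning,
                stacklevel=2,
            )
    layers: list[LayerSpec] = []
    for units in hp["lstm_units"]:
        layers.append(_layer("lstm", units=units, activation="tanh"))
        layers.append(_layer("dropout", rate=hp["lstm_dropout"]))
    for units in hp["dense_units"]:
        layers.append(_layer("dense", units=units, activation="relu"))
    layers.append(_layer("dense", units=n_classes, activation="softmax"))
    return layers


def dropout_rates(layers: Sequence[LayerSpec]) -> list[float]:
    """Dropout rates read off an architecture description, in order."""
    return [dict(l.params)["rate"] for l in layers if l.kind == "dropout"]


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    spec: ModelSpec
    scaler: StandardScaler
    estimator: object
    classes_: np.ndarray
    history: pd.DataFrame | None = None  # per-epoch loss/accuracy (neural)


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def _as_labels(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.values
    return np.asarray(y)


def train(spec: ModelSpec, X, y, guard=None, indices=None) -> TrainedModel:
    """Fit one classifier; standardisation is fitted on this X only."""
    X = _as_array(X)
    y = _as_labels(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ShapeError("X must be 2-D with one row per label")
    if np.isnan(X).any():
        raise TrainingError("feature matrix contains NaN")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training labels contain a single class")
    if len(classes) != spec.n_classes:
        raise TrainingError(
            f"spec expects {spec.n_classes} classes, labels have {len(classes)}"
        )
    if guard is not None:
        guard.check(indices if indices is not None else [])

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    y_int = np.searchsorted(classes, y)
    hp = spec.hyperparameters
    history = None

    if spec.family == "svm":
        kwargs = {}
        if hp.get("platt", False):  # Platt scaling; off by default (see predict)
            kwargs["probability"] = True
        est = SVC(
            kernel=hp["kernel"], C=hp["C"], gamma=hp["gamma"],
            random_state=spec.seed, **kwargs,
        ).fit(Xs, y_int)
    elif spec.family == "knn":
        est = KNeighborsClassifier(
            n_neighbors=hp["n_neighbors"], metric=hp["metric"]
        ).fit(Xs, y_int)
    elif spec.family == "rf":
        est = RandomForestClassifier(
            n_estimators=hp["n_estimators"], criterion=hp["criterion"],
            random_state=spec.seed,
        ).fit(Xs, y_int)
    elif spec.family == "cnn":
        est = CNN1DClassifier(
            conv_filters=hp["conv_filters"], kernel_size=hp["kernel_size"],
            pool_size=hp["pool_size"], conv_dropout=hp["conv_dropout"],
            dense_units=hp["dense_units"], dense_dropout=hp["dense_dropout"],
            lr=hp["lr"], epochs=hp["epochs"], batch_size=hp["batch_size"],
            seed=spec.seed,
        ).fit(Xs, y_int, spec.n_classes)
        history = pd.DataFrame(est.history)
    else:  # rnn
        est = LSTMClassifier(
            lstm_units=hp["lstm_units"], lstm_dropout=hp["lstm_dropout"],
            dense_units=hp["dense_units"], seq_shape=hp["seq_shape"],
            n_channels=hp["n_channels"],
            lr=hp["lr"], epochs=hp["epochs"], batch_size=hp["batch_size"],
            seed=spec.seed,
        ).fit(Xs, y_int, spec.n_classes)
        history = pd.DataFrame(est.history)
    return TrainedModel(spec, scaler, est, classes, history)


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class probabilities; labels are the probability
    argmax, rows sum to one.

    The default SVM configuration derives probabilities by a softmax over
    its decision values (Platt scaling is available via the ``platt``
    hyperparameter); this leaves accuracy/precision/recall/F1 untouched and
    only affects the probability-based RMSE metric.
    """
    X = _as_array(X)
    if X.shape[1] != model.scaler.n_features_in_:
        raise ShapeError(
            f"{X.shape[1]} features, model trained with {model.scaler.n_features_in_}"
        )
    Xs = model.scaler.transform(X)
    est = model.estimator
    if isinstance(est, SVC) and not model.spec.hyperparameters.get("platt", False):
        d = est.decision_function(Xs)
        if d.ndim == 1:  # binary: margins for (negative, positive)
            margins = np.c_[-d, d]
        else:
            margins = d
        proba = softmax(margins)
    elif isinstance(est, (CNN1DClassifier, LSTMClassifier)):
        proba = est.predict_proba(Xs)
    else:
        proba = est.predict_proba(Xs)
    labels = model.classes_[proba.argmax(axis=1)]
    return labels, proba


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchSpace:
    """Axes of the neural hyperparameter grid."""

    dropout_rates: tuple[float, ...] = (0.0, 0.25, 0.5)
    learning_rates: tuple[float, ...] = (0.2, 0.5, 0.05, 0.005, 0.009, 0.0009, 0.00009)
    epoch_counts: tuple[int, ...] = (50, 80, 100, 120, 200)

    def validate(self) -> None:
        if not (self.dropout_rates and self.learning_rates and self.epoch_counts):
            raise ParameterError("grid axes must be non-empty")
        if any(not 0.0 <= r <= 0.9 for r in self.dropout_rates):
            raise ParameterError("dropout rates must lie in [0.0, 0.9]")
        if any(lr <= 0 for lr in self.learning_rates):
            raise ParameterError("learning rates must be positive")
        if any(e < 1 for e in self.epoch_counts):
            raise ParameterError("epoch counts must be >= 1")

    def members(self):
        return itertools.product(self.dropout_rates, self.learning_rates,
                                 self.epoch_counts)


def _apply_grid_point(spec: ModelSpec, dropout: float, lr: float, epochs: int) -> ModelSpec:
    hp = dict(spec.hyperparameters)
    hp.update({"lr": lr, "epochs": epochs})
    if spec.family == "cnn":
        hp["conv_dropout"] = dropout
        hp["dense_dropout"] = (dropout, dropout)
    elif spec.family == "rnn":
        hp["lstm_dropout"] = dropout
    return replace(spec, hyperparameters=hp)


def grid_search(
    space: GridSearchSpace,
    X,
    y,
    folds: int | float = 3,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over dropout rate, learning rate and epoch count.

    ``folds`` is either an integer fold count (stratified k-fold validation
    accuracy) or a fraction in (0, 1) held out as a single validation split.
    Returns the best member (highest mean validation accuracy; ties resolve
    to the earlier grid member) and the full results table.
    """
    space.validate()
    X = _as_array(X)
    y = _as_labels(y)
    spec = spec or ModelSpec("cnn", n_classes=len(np.unique(y)))
    if isinstance(folds, float):
        if not 0 < folds < 1:
            raise ParameterError("a fractional validation split must lie in (0, 1)")
        tr, va = train_test_split(np.arange(len(y)), test_size=folds,
                                  stratify=y, random_state=seed)
        splits = [(tr, va)]
    else:
        if folds < 2:
            raise ParameterError("grid search needs >= 2 folds")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    records = []
    for dropout, lr, epochs in space.members():
        point = _apply_grid_point(spec, dropout, lr, epochs)
        scores = []
        for tr, va in splits:
            model = train(point, X[tr], y[tr])
            labels, _ = predict(model, X[va])
            scores.append(float((labels == y[va]).mean()))
        records.append(
            {"dropout": dropout, "lr": lr, "epochs": epochs,
             "mean_accuracy": float(np.mean(scores))}
        )
    results = pd.DataFrame(records)
    best_row = results.iloc[int(results["mean_accuracy"].to_numpy().argmax())]
    best = {"dropout": float(best_row["dropout"]), "lr": float(best_row["lr"]),
            "epochs": int(best_row["epochs"])}
    return best, results
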