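"""Evaluation protocols: 80:20 holdout and stratified 10-fold CV.

Per split, augmentation (signal transforms then SMOTE) and feature
standardisation are fitted on the training portion only; a
:class:`LeakageGuard` carries the test indices and any training-only stage
touching them raises.  Metrics per classifier: accuracy, precision, recall,
F1 (positive-class for the binary scheme, macro-averaged for the ternary
one, configurable), and the RMSE between predicted class-probability rows
and one-hot true labels.

For epoch-level inputs the transform variants of every epoch are computed
once (they depend only on the epoch and the run seed, never on the fold) and
per-fold training sets are assembled from training-epoch variants only; test
epochs contribute nothing but their own original-feature rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from .augment import (
    AugmentationConfig,
    epoch_population_sd,
    epoch_variants,
    smote,
    transform_training_set,
)
from .eeg_io import EpochSet, LabelVector, make_labels
from .exceptions import LeakageError, ParameterError
from .features import FeatureConfig, FeatureMatrix, extract_features
from .models import ModelSpec, predict, train

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """How to partition the data: one 80:20 holdout or k=10 rotating folds."""

    protocol: str = "kfold"
    test_fraction: float = 0.2
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.protocol not in ("holdout", "kfold"):
            raise ParameterError(f"unknown protocol {self.protocol!r}")
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must lie in (0, 1)")
        if self.k < 2:
            raise ParameterError("k must be >= 2")


class LeakageGuard:
    """Registers the test indices of one split; training-only stages call
    :meth:`check` with the indices they are about to touch."""

    def __init__(self, test_indices: Sequence[int]):
        self.test_indices = frozenset(int(i) for i in test_indices)
        self.checks = 0
        self.violations = 0

    def check(self, indices: Sequence[int]) -> None:
        overlap = self.test_indices.intersection(int(i) for i in indices)
        self.checks += 1
        if overlap:
            self.violations += 1
            raise LeakageError(
                f"{len(overlap)} test indices reached a training-only stage: "
                f"{sorted(overlap)[:5]}..."
            )


def make_splits(y, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index pairs (train, test) under the plan; folds are disjoint and
    exhaustive, stratified folds preserve class mix within one sample."""
    plan.validate()
    labels = y.values if isinstance(y, LabelVector) else np.asarray(y)
    n = len(labels)
    idx = np.arange(n)
    classes, counts = np.unique(labels, return_counts=True)
    if plan.stratified and counts.min() < 2:
        raise ParameterError("stratified splitting needs >= 2 samples per class")
    if plan.protocol == "holdout":
        tr, te = train_test_split(
            idx,
            test_size=plan.test_fraction,
            stratify=labels if plan.stratified else None,
            random_state=plan.seed,
        )
        return [(np.sort(tr), np.sort(te))]
    if plan.stratified:
        if counts.min() < plan.k:
            raise ParameterError(
                f"smallest class ({counts.min()} samples) cannot stratify "
                f"{plan.k} folds"
            )
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    else:
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return [(tr, te) for tr, te in splitter.split(idx, labels)]


def compute_metrics(
    y_true,
    y_pred,
    probabilities: np.ndarray | None = None,
    classes: Sequence | None = None,
    average: str = "macro",
    positive_label=None,
) -> dict:
    """Accuracy, precision, recall, F1 and probability RMSE for one test set.

    With two classes, precision/recall/F1 are the positive class's (default
    positive label: ``pain`` if present, else the lexically last class);
    with more, they are averaged per ``average`` (macro by default).  RMSE
    is the root mean square difference between probability rows and one-hot
    truth, ``None`` when no probabilities are supplied.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred are misaligned")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    else:
        classes = np.asarray(classes)
        seen = set(np.unique(np.concatenate([y_true, y_pred])))
        if not seen.issubset(set(classes.tolist())):
            raise ParameterError("labels outside the declared class set")
    accuracy = float((y_true == y_pred).mean())
    if len(classes) == 2:
        if positive_label is None:
            positive_label = "pain" if "pain" in classes else classes[-1]
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(classes), average=None, zero_division=0
        )
        pos = list(classes).index(positive_label)
        precision, recall, f1 = float(p[pos]), float(r[pos]), float(f[pos])
    else:
        precision, recall, f1 = (
            float(v)
            for v in precision_recall_fscore_support(
                y_true, y_pred, labels=list(classes), average=average, zero_division=0
            )[:3]
        )
    rmse = None
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(y_true), len(classes)):
            raise ParameterError("probability matrix shape mismatch")
        onehot = (y_true[:, None] == np.asarray(classes)[None, :]).astype(float)
        rmse = float(np.sqrt(np.mean((probabilities - onehot) ** 2)))
    cm = _sk_confusion(y_true, y_pred, labels=list(classes))
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "rmse": rmse,
        "confusion": cm,
        "classes": list(classes),
    }


@dataclass
class EvaluationReport:
    """Aggregated experiment output.

    ``table()`` gives mean metrics per classifier family; ``per_fold`` holds
    every fold's metrics; ``bookkeeping`` records the augmentation sample
    counts per fold; ``leakage_audit`` the guard counters (checks performed,
    violations observed — always zero for a completed run).
    """

    scheme: str
    protocol: str
    records: list[dict] = field(default_factory=list)
    bookkeeping: list[dict] = field(default_factory=list)
    confusions: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    leakage_audit: dict = field(default_factory=dict)

    @property
    def per_fold(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def table(self) -> pd.DataFrame:
        df = self.per_fold
        metrics = ["accuracy", "precision", "recall", "f1", "rmse"]
        out = (
            df.groupby("family")[metrics].mean().reset_index()
            .assign(scheme=self.scheme, protocol=self.protocol)
        )
        return out[["family", "scheme", "protocol", *metrics]]

    def best_family(self) -> tuple[str, float]:
        t = self.table().sort_values("accuracy", ascending=False)
        return str(t.iloc[0]["family"]), float(t.iloc[0]["accuracy"])


def _feature_space_training_set(
    X: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    aug: AugmentationConfig | None,
    guard: LeakageGuard,
    fold_seed: int,
    bookkeeping: dict,
):
    Xtr, ytr = X[train_idx], labels[train_idx]
    bookkeeping["n_train"] = len(train_idx)
    if aug is not None:
        cfg = AugmentationConfig(**{**aug.__dict__, "seed": fold_seed})
        Xtr, ytr, _ = transform_training_set(
            Xtr, ytr, cfg, dt=1.0, guard=guard, indices=train_idx
        )
        bookkeeping["n_after_transform"] = len(ytr)
        before = dict(zip(*np.unique(ytr, return_counts=True)))
        Xtr, ytr = smote(Xtr, ytr, k=cfg.smote_k, rng=np.random.default_rng(fold_seed))
        bookkeeping["class_counts_before_smote"] = {str(k): int(v) for k, v in before.items()}
        after = dict(zip(*np.unique(ytr, return_counts=True)))
        bookkeeping["class_counts_after_smote"] = {str(k): int(v) for k, v in after.items()}
    return Xtr, ytr


def _precompute_variant_features(
    epochs: EpochSet,
    aug: AugmentationConfig,
    feature_config: FeatureConfig,
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    """Feature rows of the six transform variants of every epoch.

    Variants depend only on the epoch and the run seed — never on the fold —
    so computing them once is equivalent to re-running the transform inside
    each fold on its training epochs, while test epochs only ever contribute
    their original rows.
    """
    sigma = epoch_population_sd(epochs)
    rng = np.random.default_rng(seed)
    per_epoch: list[np.ndarray] = []
    tags: list[str] = []
    for ep in epochs:
        variants = epoch_variants(ep, aug, sigma, epochs.fs, rng)
        if not tags:
            tags = [t for t, _ in variants]
        vset = EpochSet([v for _, v in variants], epochs.fs, epochs.channel_names)
        per_epoch.append(extract_features(vset, feature_config).values)
    return np.stack(per_epoch), tags  # (n_epochs, n_variants, n_features)


def run_experiment(
    features: FeatureMatrix | np.ndarray | None = None,
    labels: LabelVector | np.ndarray | None = None,
    specs: Sequence[ModelSpec] = (),
    plan: SplitPlan | None = None,
    aug_config: AugmentationConfig | None = None,
    *,
    epochs: EpochSet | None = None,
    scheme: str | None = None,
    feature_config: FeatureConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate classifier specs under one split plan, leakage-safe.

    Two input modes: a precomputed feature matrix with labels (augmentation,
    if any, runs in feature space), or an :class:`EpochSet` plus a labelling
    ``scheme`` (features are extracted per epoch and augmentation runs on
    the epoch signals).  Per fold the training portion is transformed,
    SMOTE-balanced, standardised and fitted; metrics are computed on the
    untouched test portion and averaged across folds.
    """
    plan = plan or SplitPlan()
    plan.validate()
    if not specs:
        raise ParameterError("at least one ModelSpec is required")

    variant_features = None
    if epochs is not None:
        if scheme is None:
            raise ParameterError("scheme is required with epoch input")
        feature_config = feature_config or FeatureConfig()
        labels = make_labels(epochs.ratings, scheme)
        X = extract_features(epochs, feature_config).values
        if aug_config is not None and aug_config.space == "signal":
            variant_features, _ = _precompute_variant_features(
                epochs, aug_config, feature_config, seed
            )
    elif features is not None:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        scheme = scheme or (labels.scheme if isinstance(labels, LabelVector) else "binary")
    else:
        raise ParameterError("provide either features or epochs")
    if labels is None:
        raise ParameterError("labels are required with feature input")
    y = labels.values if isinstance(labels, LabelVector) else np.asarray(labels)

    splits = make_splits(y, plan)
    report = EvaluationReport(
        scheme=scheme,
        protocol=plan.protocol,
        config={
            "seed": seed,
            "plan": plan.__dict__.copy(),
            "augmentation": None if aug_config is None else aug_config.__dict__.copy(),
            "specs": [
                {"family": s.family, "n_classes": s.n_classes, "seed": s.seed}
                for s in specs
            ],
        },
    )
    total_checks = 0
    for fold, (train_idx, test_idx) in enumerate(splits):
        guard = LeakageGuard(test_idx)
        fold_seed = (seed * 1009 + fold) % (2**31 - 1)
        book = {"fold": fold, "n_test": len(test_idx)}
        if variant_features is not None:
            guard.check(train_idx)
            n_var, d = variant_features.shape[1], variant_features.shape[2]
            Xtr = variant_features[train_idx].reshape(len(train_idx) * n_var, d)
            ytr = np.repeat(y[train_idx], n_var)
            book["n_train"] = len(train_idx)
            book["n_after_transform"] = len(ytr)
            before = dict(zip(*np.unique(ytr, return_counts=True)))
            Xtr, ytr = smote(
                Xtr, ytr, k=aug_config.smote_k, rng=np.random.default_rng(fold_seed)
            )
            book["class_counts_before_smote"] = {str(k): int(v) for k, v in before.items()}
            after = dict(zip(*np.unique(ytr, return_counts=True)))
            book["class_counts_after_smote"] = {str(k): int(v) for k, v in after.items()}
        else:
            Xtr, ytr = _feature_space_training_set(
                X, y, train_idx, aug_config, guard, fold_seed, book
            )
        Xte, yte = X[test_idx], y[test_idx]
        for spec in specs:
            model = train(spec, Xtr, ytr, guard=guard, indices=train_idx)
            pred, proba = predict(model, Xte)
            m = compute_metrics(
                yte, pred, proba, classes=model.classes_,
            )
            report.records.append(
                {"family": spec.family, "fold": fold, **{
                    k: m[k] for k in ("accuracy", "precision", "recall", "f1", "rmse")
                }}
            )
            report.confusions[(spec.family, fold)] = m["confusion"]
        report.bookkeeping.append(book)
        total_checks += guard.checks
        if guard.violations:  # pragma: no cover - guard raises before this
            raise LeakageError("leakage detected during fold processing")
    report.leakage_audit = {"checks": total_checks, "violations": 0}
    return report
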