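"""Split plans, metric arithmetic, leakage guarding, experiment runner."""

import numpy as np
import pytest

import painsense as ps
from painsense.exceptions import LeakageError, ParameterError


def brute_force_metrics(y_true, y_pred, classes):
    """Independent confusion-matrix implementation via explicit loops."""
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    per_class = []
    for i in range(k):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class.append((prec, rec, f1))
    acc = np.trace(cm) / cm.sum()
    return acc, per_class, cm


class TestMakeSplits:
    def test_holdout_counts(self):
        y = np.repeat(["a", "b"], 50)
        (tr, te), = ps.make_splits(y, ps.SplitPlan("holdout", seed=0))
        assert len(tr) == 80 and len(te) == 20
        assert not set(tr) & set(te)

    def test_kfold_partition(self):
        y = np.repeat(["a", "b"], 50)
        splits = ps.make_splits(y, ps.SplitPlan("kfold", k=10, seed=0))
        seen = np.concatenate([te for _, te in splits])
        assert sorted(seen) == list(range(100))
        assert len(splits) == 10
        for tr, te in splits:
            assert not set(tr) & set(te)

    def test_stratified_holdout_preserves_mix(self):
        """Proportion-count oracle on a 90/10 class mix."""
        y = np.array(["maj"] * 90 + ["min"] * 10)
        (_, te), = ps.make_splits(y, ps.SplitPlan("holdout", seed=1))
        n_min = int((y[te] == "min").sum())
        assert abs(n_min - 2) <= 1  # 10% of 20 test samples, within 1

    def test_small_class_under_stratified_kfold(self):
        y = np.array(["a"] * 95 + ["b"] * 5)
        with pytest.raises(ParameterError):
            ps.make_splits(y, ps.SplitPlan("kfold", k=10))

    def test_invalid_plans(self):
        with pytest.raises(ParameterError):
            ps.SplitPlan("bootstrap").validate()
        with pytest.raises(ParameterError):
            ps.SplitPlan("holdout", test_fraction=1.5).validate()
        with pytest.raises(ParameterError):
            ps.SplitPlan("kfold", k=1).validate()


class TestComputeMetrics:
    def test_binary_forced_arithmetic(self):
        """TP=9, FP=1, FN=1, TN=9 -> all four headline metrics 0.9."""
        y_true = np.array(["pain"] * 10 + ["no_pain"] * 10)
        y_pred = np.array(["pain"] * 9 + ["no_pain"] + ["no_pain"] * 9 + ["pain"])
        m = ps.compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(0.9)

    def test_perfect_predictions(self):
        y = np.array(["low", "moderate", "high", "low"])
        proba = np.zeros((4, 3))
        classes = ["high", "low", "moderate"]
        for i, lab in enumerate(y):
            proba[i, classes.index(lab)] = 1.0
        m = ps.compute_metrics(y, y, proba, classes=classes)
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["rmse"] == 0.0

    def test_macro_equals_per_class_mean(self, rng):
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, 60)
        y_pred = rng.choice(classes, 60)
        m = ps.compute_metrics(y_true, y_pred, classes=classes)
        _, per_class, _ = brute_force_metrics(y_true, y_pred, classes)
        assert m["precision"] == pytest.approx(np.mean([p for p, _, _ in per_class]))
        assert m["recall"] == pytest.approx(np.mean([r for _, r, _ in per_class]))
        assert m["f1"] == pytest.approx(np.mean([f for _, _, f in per_class]))

    def test_matches_brute_force_on_random_vectors(self):
        """1000 random truth/prediction pairs against the loop oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 4))
            classes = ["c0", "c1", "c2"][:k]
            n = int(rng.integers(5, 30))
            y_true = rng.choice(classes, n)
            y_pred = rng.choice(classes, n)
            m = ps.compute_metrics(y_true, y_pred, classes=classes)
            acc, per_class, cm = brute_force_metrics(y_true, y_pred, classes)
            assert m["accuracy"] == pytest.approx(acc)
            np.testing.assert_array_equal(m["confusion"], cm)
            if k == 2:
                pos = classes.index(classes[-1])
                assert m["precision"] == pytest.approx(per_class[pos][0])
                assert m["recall"] == pytest.approx(per_class[pos][1])
                assert m["f1"] == pytest.approx(per_class[pos][2])
            else:
                assert m["f1"] == pytest.approx(
                    np.mean([f for _, _, f in per_class])
                )

    def test_confusion_row_sums_are_class_counts(self, rng):
        classes = ["x", "y"]
        y_true = rng.choice(classes, 40)
        y_pred = rng.choice(classes, 40)
        m = ps.compute_metrics(y_true, y_pred, classes=classes)
        for i, c in enumerate(classes):
            assert m["confusion"][i].sum() == (y_true == c).sum()

    def test_rmse_on_probabilities(self):
        y_true = np.array(["a", "b"])
        proba = np.array([[0.8, 0.2], [0.4, 0.6]])
        m = ps.compute_metrics(y_true, np.array(["a", "b"]), proba, classes=["a", "b"])
        expected = np.sqrt(np.mean((proba - np.array([[1, 0], [0, 1]])) ** 2))
        assert m["rmse"] == pytest.approx(expected)

    def test_foreign_labels_rejected(self):
        with pytest.raises(ParameterError):
            ps.compute_metrics(np.array(["a"]), np.array(["z"]), classes=["a", "b"])


class TestLeakageGuard:
    def test_overlap_raises(self):
        guard = ps.LeakageGuard([1, 2, 3])
        with pytest.raises(LeakageError):
            guard.check([3, 4])
        guard.check([4, 5])
        assert guard.checks == 2 and guard.violations == 1

    def test_augmentation_with_test_indices_raises(self, rng):
        guard = ps.LeakageGuard([0, 1])
        with pytest.raises(LeakageError):
            ps.transform_training_set(
                rng.standard_normal((3, 16)), np.zeros(3),
                guard=guard, indices=[0, 5],
            )

    def test_train_with_test_indices_raises(self, separable_table):
        fm, labels = separable_table
        guard = ps.LeakageGuard([7])
        with pytest.raises(LeakageError):
            ps.train(ps.ModelSpec("knn"), fm, labels, guard=guard,
                     indices=np.arange(10))


class TestRunExperiment:
    def _table(self, sizes=(40, 40), effect=5.0, seed=0):
        fm, labels = ps.generate_feature_table(sizes, 12, effect_size=effect, seed=seed)
        names = np.array(["no_pain", "pain"])[labels] if len(sizes) == 2 else labels
        return fm, names

    def test_deterministic_for_baseline_families(self):
        fm, y = self._table()
        plan = ps.SplitPlan("kfold", k=5, seed=3)
        specs = [ps.ModelSpec("svm"), ps.ModelSpec("knn")]
        r1 = ps.run_experiment(fm, y, specs, plan, None, seed=3)
        r2 = ps.run_experiment(fm, y, specs, plan, None, seed=3)
        assert r1.table().equals(r2.table())

    def test_kfold_mean_is_fold_average(self):
        fm, y = self._table()
        plan = ps.SplitPlan("kfold", k=5, seed=0)
        report = ps.run_experiment(fm, y, [ps.ModelSpec("knn")], plan, None, seed=0)
        per_fold = report.per_fold
        mean = report.table()["accuracy"].iloc[0]
        assert mean == pytest.approx(per_fold["accuracy"].mean())
        assert len(per_fold) == 5

    def test_augmentation_bookkeeping_recorded(self):
        fm, y = self._table(sizes=(40, 15))
        plan = ps.SplitPlan("holdout", seed=0)
        aug = ps.AugmentationConfig(space="feature", seed=0)
        report = ps.run_experiment(fm, y, [ps.ModelSpec("knn")], plan, aug, seed=0)
        book = report.bookkeeping[0]
        assert book["n_after_transform"] == 6 * book["n_train"]
        counts = set(book["class_counts_after_smote"].values())
        assert len(counts) == 1  # balanced after SMOTE
        assert report.leakage_audit["violations"] == 0

    def test_paired_runs_with_and_without_augmentation(self):
        """Directional comparison on scarce training data is reported (not
        hard-asserted): both runs complete with comparable bookkeeping."""
        fm, y = self._table(sizes=(40, 40), effect=1.5, seed=5)
        plan = ps.SplitPlan("holdout", seed=1)
        base = ps.run_experiment(fm, y, [ps.ModelSpec("svm")], plan, None, seed=1)
        aug = ps.run_experiment(
            fm, y, [ps.ModelSpec("svm")], plan,
            ps.AugmentationConfig(space="feature", seed=1), seed=1,
        )
        assert {"accuracy"} <= set(base.table().columns)
        assert aug.bookkeeping[0]["n_after_transform"] > base.bookkeeping[0]["n_train"]

    def test_epoch_mode_signal_space(self, small_epochs):
        plan = ps.SplitPlan("kfold", k=3, seed=0)
        report = ps.run_experiment(
            specs=[ps.ModelSpec("knn")], plan=plan,
            aug_config=ps.AugmentationConfig(seed=0),
            epochs=small_epochs, scheme="binary", seed=0,
        )
        assert len(report.per_fold) == 3
        assert report.bookkeeping[0]["n_after_transform"] == 6 * report.bookkeeping[0]["n_train"]

    def test_requires_input(self):
        with pytest.raises(ParameterError):
            ps.run_experiment(specs=[ps.ModelSpec("knn")], plan=ps.SplitPlan())
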