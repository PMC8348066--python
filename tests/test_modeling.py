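"""k-fold splitting, confusion-matrix metrics and cross-validation."""

import numpy as np
import pytest

from stsfatigue.dataset_builder import ALL_FEATURE_IDS, FatigueDataset, Register
from stsfatigue.io_core import Participant
from stsfatigue.modeling import (
    ConfusionMatrix,
    ModelSpec,
    confusion_metrics,
    cross_validate,
    kfold_split,
    make_estimator,
    rf_feature_importance,
    stratified_eval,
)


def make_synthetic_dataset(rng, n_per_class=40, informative=("F1",),
                           effect=0.6):
    """Registers with gaussian features; the informative ones shift by class."""
    dataset = FatigueDataset()
    shifts = {"LF": 0.0, "MF": effect, "HF": 2 * effect}
    i = 0
    for label, shift in shifts.items():
        for _ in range(n_per_class):
            features = {
                fid: 1.0 + rng.normal(0, 0.1)
                + (shift if fid in informative else 0.0)
                for fid in ALL_FEATURE_IDS
            }
            pid = f"P{i % 10:03d}"
            dataset.registers.append(
                Register(
                    participant_id=pid, borg_time=10.0 * (i + 1) % 110 + 10,
                    borg_value=5.0, features=features, label=label,
                )
            )
            sex = "female" if (i % 10) % 2 == 0 else "male"
            dataset.participants[pid] = Participant(
                id=pid, age=22, sex=sex, weight=65, height=170
            )
            i += 1
    return dataset


class TestKFoldSplit:
    def test_660_into_6_folds_of_110(self):
        folds = kfold_split(660, k=6, seed=0)
        assert [len(f) for f in folds] == [110] * 6
        assert sorted(np.concatenate(folds)) == list(range(660))

    def test_remainder_spreads_by_at_most_one(self):
        sizes = sorted((len(f) for f in kfold_split(7, k=6, seed=1)),
                       reverse=True)
        assert sizes == [2, 1, 1, 1, 1, 1]

    def test_same_seed_reproduces_groups(self):
        a = kfold_split(100, k=6, seed=42)
        b = kfold_split(100, k=6, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=6)


class TestConfusionMetrics:
    def test_perfect_diagonal_gives_ones(self):
        m = ConfusionMatrix(np.diag([110, 110, 110]))
        metrics = confusion_metrics(m)
        assert metrics["accuracy"] == 1.0
        assert metrics["precision"] == metrics["recall"] == 1.0
        assert metrics["f_score"] == 1.0

    def test_accuracy_is_trace_over_total(self):
        m = ConfusionMatrix(np.array([[5, 0, 0], [0, 0, 5], [0, 5, 0]]))
        assert confusion_metrics(m)["accuracy"] == pytest.approx(5 / 15)

    def test_f_score_at_symmetric_point(self):
        # P = R = 0.5 for every class -> macro F = 0.5
        m = ConfusionMatrix(np.array([[5, 5, 0], [0, 5, 5], [5, 0, 5]]))
        metrics = confusion_metrics(m)
        assert metrics["precision"] == pytest.approx(0.5)
        assert metrics["recall"] == pytest.approx(0.5)
        assert metrics["f_score"] == pytest.approx(0.5)

    def test_never_predicted_class_gets_zero_precision(self):
        m = ConfusionMatrix(np.array([[10, 5, 5], [0, 0, 0], [0, 0, 0]]))
        metrics = confusion_metrics(m)
        assert metrics["precision_MF"] == 0.0
        assert metrics["precision_HF"] == 0.0

    def test_predictions_on_rows_true_on_columns(self):
        y_true = np.array(["LF", "LF", "MF"])
        y_pred = np.array(["LF", "MF", "MF"])
        m = ConfusionMatrix.from_predictions(y_true, y_pred)
        # one LF predicted as MF: row MF (pred), column LF (true)
        assert m.counts[1, 0] == 1
        assert m.counts[0, 0] == 1 and m.counts[1, 1] == 1


class TestCrossValidate:
    def test_identical_seed_gives_identical_fold_matrices(self):
        dataset = make_synthetic_dataset(np.random.default_rng(0))
        spec = ModelSpec(family="RF", seed=5)
        a = cross_validate(dataset, spec, k=6, seed=9)
        b = cross_validate(dataset, spec, k=6, seed=9)
        for ma, mb in zip(a.fold_matrices, b.fold_matrices):
            np.testing.assert_array_equal(ma.counts, mb.counts)

    def test_accuracy_equals_pooled_trace_over_total(self):
        dataset = make_synthetic_dataset(np.random.default_rng(1))
        result = cross_validate(dataset, ModelSpec(family="RF", seed=2),
                                k=6, seed=2)
        pooled = result.pooled_matrix()
        assert confusion_metrics(pooled)["accuracy"] == pytest.approx(
            np.trace(pooled.counts) / pooled.total
        )

    def test_informative_dataset_beats_chance_strongly(self):
        dataset = make_synthetic_dataset(np.random.default_rng(3))
        result = cross_validate(dataset, ModelSpec(family="LR", seed=0),
                                k=6, seed=4)
        assert result.mean_accuracy > 0.8

    def test_shuffled_labels_sit_at_chance(self):
        rng = np.random.default_rng(6)
        dataset = make_synthetic_dataset(rng, informative=(), effect=0.0)
        accs = []
        for seed in range(4):
            result = cross_validate(
                dataset, ModelSpec(family="RF", seed=seed), k=6, seed=seed
            )
            accs.append(result.mean_accuracy)
        assert abs(np.mean(accs) - 1 / 3) < 0.12

    def test_every_family_instantiates_and_fits(self):
        dataset = make_synthetic_dataset(np.random.default_rng(8),
                                         n_per_class=15)
        X, y = dataset.design_matrix()
        for family in ("RF", "SVM", "LR", "KNN"):
            est = make_estimator(ModelSpec(family=family, seed=0))
            est.fit(X, y)
            assert set(est.predict(X)) <= {"LF", "MF", "HF"}

    def test_ann_spec_carries_study_hyperparameters(self):
        est = make_estimator(ModelSpec(family="ANN", seed=0))
        assert est.hidden_layer_sizes == (100, 20, 100)
        assert est.alpha == 0.05
        assert est.learning_rate == "adaptive"


class TestFeatureImportance:
    def test_single_informative_feature_ranks_first(self):
        dataset = make_synthetic_dataset(
            np.random.default_rng(10), informative=("F1",), effect=1.0
        )
        result = cross_validate(dataset, ModelSpec(family="RF", seed=1),
                                k=6, seed=1)
        ranked = rf_feature_importance(result)
        assert ranked[0][0] == "F1"
        assert ranked[0][1] > ranked[1][1]
        total = sum(w for _, w in ranked)
        assert total == pytest.approx(1.0)
        assert all(w >= 0 for _, w in ranked)

    def test_null_importances_stay_diffuse(self):
        # labels independent of features: no weight should dominate
        maxima = []
        for seed in range(5):
            dataset = make_synthetic_dataset(
                np.random.default_rng(seed), informative=(), effect=0.0,
                n_per_class=30,
            )
            result = cross_validate(
                dataset, ModelSpec(family="RF", seed=seed), k=6, seed=seed
            )
            weights = np.array(
                [w for _, w in rf_feature_importance(result)]
            )
            maxima.append(weights.max() / weights.mean())
        assert max(maxima) < 3.0

    def test_non_rf_family_has_no_importances(self):
        dataset = make_synthetic_dataset(np.random.default_rng(11),
                                         n_per_class=15)
        result = cross_validate(dataset, ModelSpec(family="KNN"), k=6, seed=0)
        with pytest.raises(ValueError, match="random-forest"):
            rf_feature_importance(result)


class TestStratifiedEval:
    def test_sex_strata_cover_the_dataset(self):
        dataset = make_synthetic_dataset(np.random.default_rng(12))
        results = stratified_eval(dataset, ModelSpec(family="RF", seed=0),
                                  by="sex", k=6, seed=0)
        assert set(results) == {"female", "male"}
        total = sum(r.pooled_matrix().total for r in results.values())
        assert total == len(dataset)

    def test_sex_balanced_cohort_splits_into_two_330_register_strata(
        self, default_dataset
    ):
        results = stratified_eval(
            default_dataset, ModelSpec(family="RF", seed=0), by="sex",
            k=6, seed=0,
        )
        assert set(results) == {"female", "male"}
        for result in results.values():
            assert result.pooled_matrix().total == 330

    def test_unknown_field_rejected(self):
        dataset = make_synthetic_dataset(np.random.default_rng(13),
                                         n_per_class=15)
        with pytest.raises(ValueError, match="unknown participant field"):
            stratified_eval(dataset, ModelSpec(family="RF"), by="shoe_size")
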