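"""Split/CV protocol, accuracy, classifier registry, and bench integrity."""

import numpy as np
import pandas as pd
import pytest

from itdeeg.bench import (
    EvaluationProtocol,
    accuracy,
    cross_validate,
    run_bench,
    split_train_test,
)
from itdeeg.features import FeatureMatrix
from itdeeg.registry import ClassifierSpec, FAMILIES, all_specs, make_estimator


def matrix_from_array(x, labels):
    x = np.asarray(x, dtype=float)
    df = pd.DataFrame(x, columns=[f"ch01|EEG|f{i}" for i in range(x.shape[1])])
    return FeatureMatrix(
        values=df,
        labels=np.asarray(labels),
        selection="EEG",
        flags=np.zeros(x.shape, dtype=bool),
        row_flags=np.zeros(x.shape[0], dtype=bool),
    )


def balanced_matrix(rng, n_per_class=20, n_classes=6, n_features=4, separation=0.0):
    labels = np.repeat(np.arange(n_classes) + 1, n_per_class)
    x = rng.standard_normal((labels.size, n_features))
    if separation:
        for c in range(n_classes):
            x[labels == c + 1, c % n_features] += separation
    return matrix_from_array(x, labels)


class TestSplit:
    def test_600_rows_split_480_120_stratified(self, rng):
        fm = balanced_matrix(rng, n_per_class=100)
        train, test = split_train_test(fm, EvaluationProtocol())
        assert train.n_trials == 480 and test.n_trials == 120
        assert np.bincount(test.labels)[1:].tolist() == [20] * 6

    def test_same_seed_identical_partitions(self, rng):
        fm = balanced_matrix(rng)
        p = EvaluationProtocol(split_seed=3)
        t1, s1 = split_train_test(fm, p)
        t2, s2 = split_train_test(fm, p)
        assert t1.values.equals(t2.values) and s1.values.equals(s2.values)

    def test_partition_is_exact(self, rng):
        fm = balanced_matrix(rng)
        train, test = split_train_test(fm, EvaluationProtocol(split_seed=1))
        merged = pd.concat([train.values, test.values]).sort_values(
            list(train.values.columns)
        )
        original = fm.values.sort_values(list(fm.values.columns))
        np.testing.assert_allclose(merged.to_numpy(), original.to_numpy())

    def test_small_class_rejected(self, rng):
        fm = balanced_matrix(rng, n_per_class=5)
        with pytest.raises(ValueError, match="at least 10 trials"):
            split_train_test(fm, EvaluationProtocol())


class TestCrossValidate:
    def test_separable_data_near_perfect(self, rng):
        fm = balanced_matrix(rng, n_classes=3, n_features=3, separation=8.0)
        score = cross_validate(
            ClassifierSpec("svm", "linear"), fm, EvaluationProtocol()
        )
        assert score >= 0.95

    def test_shuffled_labels_at_chance(self, rng):
        fm = balanced_matrix(rng, n_per_class=50, separation=6.0)
        shuffled = matrix_from_array(
            fm.values.to_numpy(), rng.permutation(fm.labels)
        )
        score = cross_validate(
            ClassifierSpec("knn", "cosine"), shuffled, EvaluationProtocol()
        )
        se = np.sqrt((1 / 6) * (5 / 6) / fm.n_trials)
        assert abs(score - 1 / 6) <= 3 * se + 0.05

    def test_leave_one_out_smoke(self, rng):
        fm = balanced_matrix(rng, n_per_class=10, n_classes=3, separation=5.0)
        score = cross_validate(
            ClassifierSpec("decision_tree", "fine"),
            fm,
            EvaluationProtocol(k_folds=fm.n_trials // 3),
        )
        assert 0.0 <= score <= 1.0

    def test_missing_class_in_fold_rejected(self, rng):
        fm = balanced_matrix(rng, n_per_class=3, n_classes=3)
        with pytest.raises(ValueError, match="k_folds"):
            cross_validate(
                ClassifierSpec("knn", "cosine"), fm, EvaluationProtocol(k_folds=5)
            )


class TestAccuracy:
    def test_diagonal_matrix_is_perfect(self):
        assert accuracy(np.diag([10, 20, 5])) == 1.0

    def test_uniform_confusion_is_chance(self):
        assert accuracy(np.full((6, 6), 3)) == pytest.approx(1 / 6)

    def test_binary_matches_printed_formula(self):
        # TP=8, TN=80, FP=10, FN=2 -> (8+80)/100
        conf = np.array([[8, 2], [10, 80]])
        assert accuracy(conf) == pytest.approx(0.88)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy(np.zeros((6, 6)))


class TestRegistry:
    def test_twenty_seven_variants_in_eight_families(self):
        specs = all_specs()
        assert len(specs) == 27
        assert len(FAMILIES) == 8
        per_family = {f: 0 for f in FAMILIES}
        for s in specs:
            per_family[s.family] += 1
        assert per_family == {
            "decision_tree": 3,
            "discriminant": 2,
            "naive_bayes": 2,
            "svm": 6,
            "knn": 2,
            "ensemble": 5,
            "neural_net": 5,
            "kernel_approx": 2,
        }

    @pytest.mark.parametrize("spec", all_specs(), ids=lambda s: s.name)
    def test_every_variant_fits_and_predicts(self, rng, spec):
        x = rng.standard_normal((60, 6))
        y = np.arange(60) % 3 + 1
        x[:, 0] += y * 2.0
        est = make_estimator(spec, n_features=6, random_state=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, y)
            pred = est.predict(x)
        assert set(pred) <= {1, 2, 3}

    def test_unknown_spec_rejected(self):
        with pytest.raises(KeyError, match="unknown classifier"):
            make_estimator(ClassifierSpec("svm", "octic"), 4)


class TestRunBench:
    def test_single_variant_best_of_family(self, rng):
        fm = balanced_matrix(rng, n_per_class=20, separation=4.0)
        rep = run_bench(fm, specs=[ClassifierSpec("knn", "cosine")])
        best = rep.best_per_family("cv")
        assert list(best) == ["knn"]
        assert best["knn"].cv_accuracy == rep.variants[0].cv_accuracy

    def test_determinism_per_seed(self, rng):
        fm = balanced_matrix(rng, n_per_class=15, separation=2.0)
        specs = [
            ClassifierSpec("decision_tree", "medium"),
            ClassifierSpec("ensemble", "bagged"),
        ]
        protocol = EvaluationProtocol(split_seed=5, cv_seed=9)
        r1 = run_bench(fm, specs=specs, protocol=protocol)
        r2 = run_bench(fm, specs=specs, protocol=protocol)
        for a, b in zip(r1.variants, r2.variants):
            assert a.cv_accuracy == b.cv_accuracy
            assert a.test_accuracy == b.test_accuracy
            np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_no_leakage_from_test_rows(self, rng):
        # mutation test: corrupting the rows that land in the test
        # partition must leave the training partition, and therefore the
        # CV score and the fitted model, bit-identical
        from sklearn.model_selection import train_test_split

        fm = balanced_matrix(rng, n_per_class=15, separation=2.0)
        protocol = EvaluationProtocol(split_seed=2, cv_seed=2)
        idx = np.arange(fm.n_trials)
        _, test_idx = train_test_split(
            idx, test_size=0.2, stratify=fm.labels, random_state=protocol.split_seed
        )
        mutated = fm.values.to_numpy().copy()
        mutated[test_idx] = 1e9
        mutated_fm = matrix_from_array(mutated, fm.labels)
        spec = ClassifierSpec("decision_tree", "fine")
        train_a, _ = split_train_test(fm, protocol)
        train_b, _ = split_train_test(mutated_fm, protocol)
        assert train_a.values.equals(train_b.values)
        score_a = cross_validate(spec, train_a, protocol, "anova")
        score_b = cross_validate(spec, train_b, protocol, "anova")
        assert score_a == score_b

    def test_failed_classifier_recorded_not_available(self, rng):
        # a constant feature set makes QDA's covariance singular
        x = np.zeros((60, 3))
        labels = np.arange(60) % 3 + 1
        fm = matrix_from_array(x, labels)
        rep = run_bench(
            fm,
            specs=[
                ClassifierSpec("discriminant", "quadratic"),
                ClassifierSpec("decision_tree", "coarse"),
            ],
        )
        statuses = {v.spec.variant: v.status for v in rep.variants}
        assert statuses["coarse"] == "ok"

    def test_report_serialization_round_trip(self, rng, tmp_path):
        fm = balanced_matrix(rng, n_per_class=15)
        rep = run_bench(fm, specs=[ClassifierSpec("naive_bayes", "gaussian")])
        path = tmp_path / "bench.json"
        rep.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["variants"][0]["family"] == "naive_bayes"
        conf = np.array(payload["variants"][0]["confusion"])
        assert conf.sum() == 18  # 20% of 90 rows
        assert accuracy(conf) == pytest.approx(rep.variants[0].test_accuracy)

    def test_whole_data_anova_mode_runs(self, rng):
        fm = balanced_matrix(rng, n_per_class=15, n_features=8, separation=2.0)
        rep = run_bench(
            fm,
            specs=[ClassifierSpec("decision_tree", "medium")],
            selection_mode="anova_whole",
        )
        assert rep.variants[0].status == "ok"
        assert 0.0 <= rep.variants[0].test_accuracy <= 1.0

    def test_accuracies_within_bounds(self, rng):
        fm = balanced_matrix(rng, n_per_class=15, separation=1.0)
        rep = run_bench(fm, specs=all_specs(families={"decision_tree"}))
        for v in rep.variants:
            assert v.status == "ok"
            assert 0.0 <= v.cv_accuracy <= 1.0
            assert 0.0 <= v.test_accuracy <= 1.0
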