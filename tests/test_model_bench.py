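"""Classifier benchmarking: metrics, ROC, leave-one-out, suites."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from toxfunnel.model_bench import (
    ALGORITHMS,
    ClassifierSpec,
    LabeledDataset,
    build_classifier,
    confusion_metrics,
    external_evaluate,
    loo_evaluate,
    roc_auc,
    train_endpoint_suite,
)
from toxfunnel.synthetic import generate_labeled_library, null_spec, strong_logp_spec


def concordance_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(10, 0, 10, 0)
        assert (rep.sensitivity, rep.specificity, rep.overall_accuracy, rep.precision) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_computed_panel(self):
        rep = confusion_metrics(8, 3, 7, 2)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.7)
        assert rep.overall_accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(8 / 11)
        assert rep.n == 20

    def test_zero_denominator_is_undefined_not_zero(self):
        rep = confusion_metrics(0, 0, 5, 5)
        assert math.isnan(rep.precision)
        assert rep.specificity == 1.0
        assert rep.sensitivity == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_pure_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == pytest.approx(0.5)

    def test_interleaved_pairs(self):
        # 4 pos-neg pairs, 2 concordant: AUC 0.5 by direct pair count
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 0, 1]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_invariants(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        curve = roc_auc(s, y)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr), abs=1e-9)

    def test_equals_concordance_oracle_on_100_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestLooEvaluate:
    def test_linearly_separated_data_perfect_accuracy(self):
        # two-unit gap around the decision boundary (2 SD of the noise axis)
        rng = np.random.default_rng(7)
        x1 = np.concatenate([rng.uniform(-3, -1, 20), rng.uniform(1, 3, 20)])
        X = pd.DataFrame({"d1": x1, "noise": rng.normal(size=40)})
        y = (x1 > 0).astype(int)
        data = LabeledDataset("e", X, y, [f"c{i}" for i in range(40)])
        rep = loo_evaluate(data, ClassifierSpec("random_forest", seed=7))
        assert rep.overall_accuracy == 1.0

    def test_permuted_labels_near_chance(self):
        lib = generate_labeled_library(null_spec(n=100, seed=7))
        data = LabeledDataset(
            "e", lib.X, lib.labels["cardiotoxicity"], lib.ids
        )
        rep = loo_evaluate(data, ClassifierSpec("random_forest", seed=7))
        assert 0.35 <= rep.auc <= 0.65

    def test_minimal_dataset_has_n_heldout_predictions(self):
        # the lone-negative fold trains on positives only; naive Bayes can
        # still fit it and scores the held-out sample with certainty
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        data = LabeledDataset("e", X, np.array([0, 1, 1]), ["a", "b", "c"])
        rep = loo_evaluate(data, ClassifierSpec("naive_bayes"))
        assert len(rep.per_sample_scores) == 3
        assert rep.per_sample_scores["a"] == 1.0  # degenerate single-class fold

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_matches_retrain_per_sample_oracle(self, algo, small_labeled_dataset):
        """Held-out scores equal sklearn's independent LOO implementation."""
        spec = ClassifierSpec(algo, seed=11)
        rep = loo_evaluate(small_labeled_dataset, spec)
        oracle = cross_val_predict(
            build_classifier(spec),
            small_labeled_dataset.X.to_numpy(float),
            small_labeled_dataset.y,
            cv=LeaveOneOut(),
            method="predict_proba",
        )[:, 1]
        mine = np.array([rep.per_sample_scores[i] for i in small_labeled_dataset.ids])
        assert np.array_equal(mine, oracle)

    def test_deterministic_given_seed(self, small_labeled_dataset, rf_spec):
        a = loo_evaluate(small_labeled_dataset, rf_spec)
        b = loo_evaluate(small_labeled_dataset, rf_spec)
        assert a.per_sample_scores == b.per_sample_scores

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        data = LabeledDataset("e", X, np.array([1, 1, 1]), ["a", "b", "c"])
        with pytest.raises(ValueError, match="both classes"):
            loo_evaluate(data, ClassifierSpec("knn"))

    def test_untrainable_fold_skipped_with_warning(self):
        # the SVM cannot fit a single-class training fold
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        data = LabeledDataset("e", X, np.array([1, 0, 0, 0]), list("abcd"))
        with pytest.warns(UserWarning, match="skipped"):
            rep = loo_evaluate(data, ClassifierSpec("svm"))
        assert rep.skipped_ids == ["a"]
        assert len(rep.per_sample_scores) == 3


class TestExternalEvaluate:
    def test_memorizing_tree_on_training_copy(self, small_labeled_dataset):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        model = Pipeline(
            [("scale", StandardScaler()), ("clf", DecisionTreeClassifier(random_state=0))]
        )
        model.fit(small_labeled_dataset.X.to_numpy(float), small_labeled_dataset.y)
        rep = external_evaluate(
            model, list(small_labeled_dataset.X.columns), small_labeled_dataset
        )
        assert rep.overall_accuracy == 1.0
        assert rep.scheme == "external"

    def test_validation_from_training_distribution_tracks_loo_auc(self):
        spec = strong_logp_spec(n=200, seed=11)
        train = generate_labeled_library(spec)
        tdata = LabeledDataset("e", train.X, train.labels["cardiotoxicity"], train.ids)
        cspec = ClassifierSpec("random_forest", seed=11)
        loo = loo_evaluate(tdata, cspec)
        model = build_classifier(cspec)
        model.fit(train.X.to_numpy(float), tdata.y)
        val_spec = strong_logp_spec(n=200, seed=211)
        val = generate_labeled_library(val_spec)
        vdata = LabeledDataset("e", val.X, val.labels["cardiotoxicity"], val.ids)
        ext = external_evaluate(model, list(train.X.columns), vdata, spec=cspec)
        assert abs(ext.auc - loo.auc) <= 0.1

    def test_column_mismatch_lists_missing(self, small_labeled_dataset, rf_spec):
        model = build_classifier(rf_spec)
        model.fit(small_labeled_dataset.X.to_numpy(float), small_labeled_dataset.y)
        bad = LabeledDataset(
            "e",
            small_labeled_dataset.X.drop(columns=["logp"]),
            small_labeled_dataset.y,
            small_labeled_dataset.ids,
        )
        with pytest.raises(ValueError, match="logp"):
            external_evaluate(model, list(small_labeled_dataset.X.columns), bad)

    def test_empty_validation_rejected(self, small_labeled_dataset, rf_spec):
        model = build_classifier(rf_spec)
        model.fit(small_labeled_dataset.X.to_numpy(float), small_labeled_dataset.y)
        empty = LabeledDataset("e", small_labeled_dataset.X.iloc[:0],
                               np.array([], dtype=int), [])
        with pytest.raises(ValueError, match="empty"):
            external_evaluate(model, list(small_labeled_dataset.X.columns), empty)


class TestEndpointSuite:
    @pytest.fixture()
    def five_datasets(self):
        lib = generate_labeled_library(
            strong_logp_spec(
                n=60,
                seed=9,
                endpoints=(
                    "arrhythmia",
                    "cardiac_failure",
                    "heart_block",
                    "hypertension",
                    "myocardial_infarction",
                ),
            )
        )
        return {
            ep: LabeledDataset(ep, lib.X, y, lib.ids) for ep, y in lib.labels.items()
        }, lib

    def test_identical_data_gives_identical_scores(self, small_labeled_dataset):
        datasets = {
            ep: small_labeled_dataset
            for ep in ("a", "b", "c", "d", "e")
        }
        suite = train_endpoint_suite(
            datasets, ClassifierSpec("random_forest", seed=1), endpoints=list(datasets)
        )
        probs = suite.predict_proba(small_labeled_dataset.X)
        for ep in "bcde":
            assert np.array_equal(probs["a"], probs[ep])

    def test_save_load_round_trip_bit_stable(self, tmp_path, five_datasets):
        datasets, lib = five_datasets
        suite = train_endpoint_suite(datasets, ClassifierSpec("random_forest", seed=2))
        before = suite.predict_proba(lib.X.iloc[:50])
        suite.save(tmp_path / "suite")
        from toxfunnel.model_bench import EndpointModelSuite

        reloaded = EndpointModelSuite.load(tmp_path / "suite")
        after = reloaded.predict_proba(lib.X.iloc[:50])
        assert np.array_equal(before.to_numpy(), after.to_numpy())
        assert reloaded.spec.algorithm == suite.spec.algorithm
        assert reloaded.spec.seed == suite.spec.seed
        assert (
            reloaded.spec.resolved_hyperparameters()
            == suite.spec.resolved_hyperparameters()
        )

    def test_missing_endpoint_rejected(self, small_labeled_dataset):
        with pytest.raises(ValueError, match="missing datasets"):
            train_endpoint_suite(
                {"arrhythmia": small_labeled_dataset}, ClassifierSpec("knn")
            )

    def test_seed_sensitivity_labels_stable_on_high_margin_data(self, five_datasets):
        datasets, lib = five_datasets
        s1 = train_endpoint_suite(datasets, ClassifierSpec("random_forest", seed=1))
        s2 = train_endpoint_suite(datasets, ClassifierSpec("random_forest", seed=99))
        p1 = s1.predict_proba(lib.X)["arrhythmia"]
        p2 = s2.predict_proba(lib.X)["arrhythmia"]
        # probabilities shift with the seed but hard calls mostly agree
        agree = np.mean((p1 >= 0.5) == (p2 >= 0.5))
        assert agree >= 0.8
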