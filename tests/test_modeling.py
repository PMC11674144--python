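"""Cross-validated classification/regression, ROC, and the FNN regressor."""

import numpy as np
import pandas as pd
import pytest

import echoedema as ee
from echoedema.modeling import fnn_train, make_regressor
from echoedema.simulate import EARLY_LABEL, LATE_LABEL
from oracles import auc_concordance_oracle


def _toy_classification_table(rng, n=200, separation=8.0):
    half = n // 2
    X = np.vstack(
        [rng.normal(0, 1, (half, 3)), rng.normal(separation, 1, (n - half, 3))]
    )
    df = pd.DataFrame(X, columns=["maximum", "variance", "kurtosis"])
    df["class_label"] = [EARLY_LABEL] * half + [LATE_LABEL] * (n - half)
    df["subject_id"] = [f"S{i % 10}" for i in range(n)]
    return df


def _toy_regression_table(rng, n=300, noise=0.0):
    X = rng.normal(size=(n, 3))
    y = 0.5 * X[:, 0] - 0.2 * X[:, 1] + 0.1 * X[:, 2]
    df = pd.DataFrame(X, columns=["maximum", "variance", "kurtosis"])
    df["target_ratio"] = y + noise * rng.normal(size=n)
    df["subject_id"] = [f"S{i % 10}" for i in range(n)]
    return df


FEATS = ["maximum", "variance", "kurtosis"]


class TestCrossvalClassify:
    @pytest.mark.parametrize("kind", ["svm", "logistic_regression", "decision_tree", "random_forest"])
    def test_separable_clusters_are_perfect(self, rng, kind):
        table = _toy_classification_table(rng)
        res = ee.crossval_classify(table, FEATS, ee.ClassifierSpec(kind, seed=0), k=10, seed=0)
        assert res.mean["ACC"] == 1.0
        assert res.mean["AUC"] == 1.0
        assert res.mean["F1"] == 1.0

    def test_shuffled_labels_give_chance_auc(self, rng):
        table = _toy_classification_table(rng, separation=0.0)
        res = ee.crossval_classify(
            table, FEATS, ee.ClassifierSpec("logistic_regression", seed=0), k=10, seed=0
        )
        assert 0.4 <= res.mean["AUC"] <= 0.6

    def test_fold_partition_covers_all_rows_once(self, rng):
        table = _toy_classification_table(rng, n=173)
        res = ee.crossval_classify(table, FEATS, ee.ClassifierSpec("random_forest", seed=1), k=10, seed=1)
        rows = res.predictions["row"].to_numpy()
        assert sorted(rows) == list(range(len(table)))

    def test_metrics_invariant_to_feature_rescaling(self, rng):
        table = _toy_classification_table(rng, separation=1.5)
        res1 = ee.crossval_classify(table, FEATS, ee.ClassifierSpec("svm", seed=0), k=5, seed=0)
        scaled = table.copy()
        scaled[FEATS] = scaled[FEATS] * [1000.0, 0.001, 42.0]
        res2 = ee.crossval_classify(scaled, FEATS, ee.ClassifierSpec("svm", seed=0), k=5, seed=0)
        for m in ("ACC", "AUC", "F1"):
            assert res2.mean[m] == pytest.approx(res1.mean[m], abs=1e-9)

    def test_group_cv_keeps_subjects_out_of_train(self, rng):
        table = _toy_classification_table(rng)
        res = ee.crossval_classify(
            table, FEATS, ee.ClassifierSpec("random_forest", seed=0), k=5, seed=0,
            group_by_subject=True,
        )
        merged = res.predictions.merge(
            table.reset_index().rename(columns={"index": "row"})[["row", "subject_id"]], on="row"
        )
        folds_per_subject = merged.groupby("subject_id")["fold"].nunique()
        assert (folds_per_subject == 1).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ee.ClassifierSpec("boosted_stump")

    def test_single_class_rejected(self, rng):
        table = _toy_classification_table(rng)
        table["class_label"] = EARLY_LABEL
        with pytest.raises(ValueError):
            ee.crossval_classify(table, FEATS, ee.ClassifierSpec("svm"), k=5, seed=0)


class TestCrossvalRegress:
    def test_noiseless_linear_recovered_exactly(self, rng):
        table = _toy_regression_table(rng)
        res = ee.crossval_regress(table, FEATS, ee.RegressorSpec("linear"), k=10, seed=0)
        assert res.mean["MSE"] < 1e-6
        assert res.mean["R2"] > 1 - 1e-6

    def test_rmse_is_sqrt_mse_per_fold(self, rng):
        table = _toy_regression_table(rng, noise=0.3)
        res = ee.crossval_regress(
            table, FEATS, ee.RegressorSpec("random_forest", seed=0), k=10, seed=0
        )
        assert res.fold_metrics["RMSE"].to_numpy() == pytest.approx(
            np.sqrt(res.fold_metrics["MSE"].to_numpy()), rel=1e-12
        )

    def test_mean_predictor_has_nonpositive_r2(self, rng):
        # a regressor that always outputs (approximately) the training mean
        table = _toy_regression_table(rng, noise=0.1)
        spec = ee.RegressorSpec("random_forest", hyperparameters={"max_depth": 1, "n_estimators": 1, "min_samples_leaf": 10_000}, seed=0)
        res = ee.crossval_regress(table, FEATS, spec, k=5, seed=0)
        assert res.mean["R2"] <= 0.01

    def test_constant_target_fold_reports_missing_r2(self, rng):
        table = _toy_regression_table(rng, n=60)
        table["target_ratio"] = 0.5
        with pytest.warns(UserWarning, match="constant target"):
            res = ee.crossval_regress(table, FEATS, ee.RegressorSpec("linear"), k=5, seed=0)
        assert res.fold_metrics["R2"].isna().all()

    def test_regressor_defaults_match_stated_hyperparameters(self):
        rf = make_regressor(ee.RegressorSpec("random_forest"))
        assert (rf.n_estimators, rf.max_depth, rf.min_samples_split, rf.min_samples_leaf) == (100, 20, 5, 1)
        svr = make_regressor(ee.RegressorSpec("svm"))
        assert svr.kernel == "linear" and svr.C == 1.0
        fnn = make_regressor(ee.RegressorSpec("fnn"))
        assert fnn.hidden_layer_sizes == (64, 32)
        assert fnn.activation == "relu" and fnn.solver == "adam"
        assert fnn.learning_rate_init == 0.001
        assert fnn.max_iter == 50 and fnn.batch_size == 64


class TestRocCurve:
    def test_perfect_scores(self):
        fpr, tpr, auc = ee.roc_curve([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, _, auc = ee.roc_curve([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_textbook_example(self):
        _, _, auc = ee.roc_curve([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_staircase_shape(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        fpr, tpr, _ = ee.roc_curve(labels, rng.uniform(size=40))
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_matches_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=n), 1)  # force ties
            _, _, auc = ee.roc_curve(labels, scores)
            assert auc == pytest.approx(auc_concordance_oracle(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ee.roc_curve([1, 1, 1], [0.1, 0.2, 0.3])


class TestFNN:
    def test_identity_mapping_learned(self, rng):
        X = rng.normal(size=(2000, 1))
        y = X[:, 0]
        model = fnn_train(X[:1600], y[:1600], ee.RegressorSpec("fnn", seed=0))
        mse = np.mean((model.predict(X[1600:]) - y[1600:]) ** 2)
        assert mse < 0.01

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(300, 2))
        y = X[:, 0] - X[:, 1]
        p1 = fnn_train(X, y, ee.RegressorSpec("fnn", seed=7)).predict(X)
        p2 = fnn_train(X, y, ee.RegressorSpec("fnn", seed=7)).predict(X)
        assert np.array_equal(p1, p2)

    def test_non_fnn_spec_rejected(self):
        with pytest.raises(ValueError):
            fnn_train(np.zeros((4, 1)), np.zeros(4), ee.RegressorSpec("linear"))
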