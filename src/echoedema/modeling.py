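"""Cross-validated classification and regression on the feature table.

Four classifiers (SVM, logistic regression, decision tree, random forest)
separate early cytotoxic from late vasogenic edema; four regressors (linear
SVM, random forest, ordinary least squares, and a small feedforward network)
predict the interpolated infarct volume ratio. Both run under seeded 10-fold
cross-validation with fold-wise standardization fit on training rows only
(normalizing before the split is available via ``standardize_per_fold=False``
for parity with pipelines that pre-normalize the whole table, at the cost of
mild information leakage).

Reported metrics: ACC / AUC / F1 (positive class = late vasogenic) for
classification; MSE / RMSE / MAE / R^2 for regression; each as mean +/- SD
over folds plus the per-fold values and out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .simulate import LATE_LABEL

__all__ = [
    "ClassifierSpec",
    "RegressorSpec",
    "CVResult",
    "make_classifier",
    "make_regressor",
    "crossval_classify",
    "crossval_regress",
    "roc_curve",
    "fnn_train",
    "CLASSIFIER_KINDS",
    "REGRESSOR_KINDS",
]

CLASSIFIER_KINDS = ("svm", "logistic_regression", "decision_tree", "random_forest")
REGRESSOR_KINDS = ("svm", "random_forest", "linear", "fnn")

# aliases accepted on the CLI
_KIND_ALIASES = {
    "logr": "logistic_regression",
    "dt": "decision_tree",
    "rf": "random_forest",
    "lr": "linear",
}


def _canonical(kind: str) -> str:
    return _KIND_ALIASES.get(kind, kind)


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and with what hyperparameter overrides."""

    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", _canonical(self.kind))
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class RegressorSpec:
    """Which regressor to build and with what hyperparameter overrides.

    Defaults: linear-kernel SVR with C=1; random forest with 100 trees,
    max depth 20, min samples split 5, min samples leaf 1; ordinary least
    squares; FNN with hidden layers (64, 32), ReLU, adam, learning rate 1e-3,
    50 epochs, batch size 64, squared-error loss.
    """

    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", _canonical(self.kind))
        if self.kind not in REGRESSOR_KINDS:
            raise ValueError(f"unknown regressor kind {self.kind!r}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn classifier for a spec (library defaults)."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        return SVC(random_state=spec.seed, **hp)
    if spec.kind == "logistic_regression":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    return RandomForestClassifier(random_state=spec.seed, **hp)


def make_regressor(spec: RegressorSpec):
    """Instantiate the sklearn regressor for a spec with the stated defaults."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "svm":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        return SVR(**hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_depth", 20)
        hp.setdefault("min_samples_split", 5)
        hp.setdefault("min_samples_leaf", 1)
        return RandomForestRegressor(random_state=spec.seed, **hp)
    if spec.kind == "linear":
        return LinearRegression(**hp)
    hp.setdefault("hidden_layer_sizes", (64, 32))
    hp.setdefault("activation", "relu")
    hp.setdefault("solver", "adam")
    hp.setdefault("learning_rate_init", 0.001)
    hp.setdefault("max_iter", 50)
    hp.setdefault("batch_size", 64)
    hp.setdefault("n_iter_no_change", 50)  # always run the full epoch budget
    return MLPRegressor(random_state=spec.seed, **hp)


@dataclass
class CVResult:
    """Per-fold and aggregated cross-validation metrics."""

    task: str
    model_kind: str
    fold_metrics: pd.DataFrame
    mean: Dict[str, float]
    sd: Dict[str, float]
    predictions: pd.DataFrame
    roc_points: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def _folds_classify(y, groups, k, seed):
    if groups is not None:
        return GroupKFold(n_splits=k).split(np.zeros(len(y)), y, groups)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
        np.zeros(len(y)), y
    )


def _positive_scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        idx = list(model.classes_).index(LATE_LABEL)
        return model.predict_proba(X)[:, idx]
    scores = model.decision_function(X)
    # decision_function is signed toward classes_[1]
    return scores if model.classes_[1] == LATE_LABEL else -scores


def crossval_classify(
    table: pd.DataFrame,
    feature_set: Sequence[str],
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    standardize_per_fold: bool = True,
    group_by_subject: bool = False,
) -> CVResult:
    """Stratified k-fold evaluation of an edema-type classifier.

    Per fold: standardize on training rows, fit, score held-out rows with
    ACC, AUC (from the late-vasogenic score) and F1 (late-vasogenic positive).
    """
    X_all = table[list(feature_set)].to_numpy(dtype=float)
    y_all = table["class_label"].to_numpy()
    if len(np.unique(y_all)) < 2:
        raise ValueError("need at least 2 classes")
    groups = table["subject_id"].to_numpy() if group_by_subject else None
    if not standardize_per_fold:
        X_all = StandardScaler().fit_transform(X_all)

    rows, preds = [], []
    oof_fpr_tpr = None
    all_scores = np.empty(len(y_all))
    for fold, (tr, te) in enumerate(_folds_classify(y_all, groups, k, seed), start=1):
        Xtr, Xte = X_all[tr], X_all[te]
        if standardize_per_fold:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        model = make_classifier(spec).fit(Xtr, y_all[tr])
        y_pred = model.predict(Xte)
        scores = _positive_scores(model, Xte)
        all_scores[te] = scores
        y_true_bin = (y_all[te] == LATE_LABEL).astype(int)
        rows.append(
            {
                "fold": fold,
                "ACC": skm.accuracy_score(y_all[te], y_pred),
                "AUC": skm.roc_auc_score(y_true_bin, scores),
                "F1": skm.f1_score(y_all[te], y_pred, pos_label=LATE_LABEL),
            }
        )
        preds.append(
            pd.DataFrame(
                {
                    "row": te,
                    "fold": fold,
                    "y_true": y_all[te],
                    "y_pred": y_pred,
                    "score": scores,
                }
            )
        )
    fold_df = pd.DataFrame(rows)
    pred_df = pd.concat(preds, ignore_index=True).sort_values("row").reset_index(drop=True)
    fpr, tpr, auc = roc_curve((y_all == LATE_LABEL).astype(int), all_scores)
    roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    metric_cols = ["ACC", "AUC", "F1"]
    return CVResult(
        task="classification",
        model_kind=spec.kind,
        fold_metrics=fold_df,
        mean={m: float(fold_df[m].mean()) for m in metric_cols},
        sd={m: float(fold_df[m].std(ddof=1)) for m in metric_cols},
        predictions=pred_df,
        roc_points=roc_df,
    )


def crossval_regress(
    table: pd.DataFrame,
    feature_set: Sequence[str],
    spec: RegressorSpec,
    k: int = 10,
    seed: int = 0,
    standardize_per_fold: bool = True,
    group_by_subject: bool = False,
) -> CVResult:
    """Seeded k-fold evaluation of an infarct-ratio regressor.

    A held-out fold with constant target leaves R^2 undefined: that fold's
    R^2 is reported as NaN and excluded from the aggregate with a warning.
    """
    X_all = table[list(feature_set)].to_numpy(dtype=float)
    y_all = table["target_ratio"].to_numpy(dtype=float)
    if np.any(~np.isfinite(y_all)):
        raise ValueError("target_ratio must be present and finite for all rows")
    if not standardize_per_fold:
        X_all = StandardScaler().fit_transform(X_all)
    if group_by_subject:
        splitter = GroupKFold(n_splits=k).split(X_all, y_all, table["subject_id"].to_numpy())
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed).split(X_all)

    rows, preds = [], []
    for fold, (tr, te) in enumerate(splitter, start=1):
        Xtr, Xte = X_all[tr], X_all[te]
        if standardize_per_fold:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        model = make_regressor(spec).fit(Xtr, y_all[tr])
        y_pred = model.predict(Xte)
        mse = skm.mean_squared_error(y_all[te], y_pred)
        if np.ptp(y_all[te]) == 0:
            warnings.warn(
                f"fold {fold}: constant target in test fold; R^2 undefined",
                stacklevel=2,
            )
            r2 = np.nan
        else:
            r2 = skm.r2_score(y_all[te], y_pred)
        rows.append(
            {
                "fold": fold,
                "MSE": mse,
                "RMSE": float(np.sqrt(mse)),
                "MAE": skm.mean_absolute_error(y_all[te], y_pred),
                "R2": r2,
            }
        )
        preds.append(
            pd.DataFrame({"row": te, "fold": fold, "y_true": y_all[te], "y_pred": y_pred})
        )
    fold_df = pd.DataFrame(rows)
    pred_df = pd.concat(preds, ignore_index=True).sort_values("row").reset_index(drop=True)
    metric_cols = ["MSE", "RMSE", "MAE", "R2"]
    return CVResult(
        task="regression",
        model_kind=spec.kind,
        fold_metrics=fold_df,
        mean={m: float(fold_df[m].mean(skipna=True)) for m in metric_cols},
        sd={m: float(fold_df[m].std(ddof=1, skipna=True)) for m in metric_cols},
        predictions=pred_df,
    )


def roc_curve(labels, scores) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC staircase from (0,0) to (1,1) with trapezoidal AUC; ties grouped.

    ``labels`` are 0/1 (1 = positive class); returns (fpr, tpr, auc).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = skm.roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, float(skm.auc(fpr, tpr))


def fnn_train(
    features: np.ndarray,
    targets: np.ndarray,
    spec: RegressorSpec | None = None,
) -> MLPRegressor:
    """Train the feedforward regression network on standardized inputs.

    Deterministic given the spec seed (fixed weight init and batch order).
    A non-finite training loss aborts with diagnostics.
    """
    spec = spec or RegressorSpec(kind="fnn")
    if spec.kind != "fnn":
        raise ValueError("fnn_train requires an fnn spec")
    model = make_regressor(spec)
    model.fit(np.asarray(features, dtype=float), np.asarray(targets, dtype=float))
    if not np.isfinite(model.loss_):
        raise RuntimeError(
            f"FNN training diverged: loss={model.loss_} after {model.n_iter_} epochs"
        )
    return model
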