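"""Behavioral-state decoding from whole-brain timescale features.

Multiclass classification (RBF-kernel SVM or multinomial logistic
regression) with nested cross-validation: hyperparameters are tuned with an
inner stratified k-fold on each outer training split only, so the outer
test folds never leak into tuning. The outer folds partition the samples
without replacement, so the aggregated confusion matrix covers the whole
dataset exactly once. Per-class one-vs-rest ROC curves are computed per
outer fold and averaged on a fixed false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ClassifierReport", "build_feature_table", "nested_cv_classify",
           "average_roc"]

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ClassifierReport:
    """Aggregated nested-CV results."""

    classes: list[str]
    confusion: pd.DataFrame  # rows = true class, cols = predicted, counts
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    roc: dict[str, dict]  # class -> {fpr, tpr_mean, tpr_sd, auc, n_folds}
    fold_params: list[dict] = field(default_factory=list)


def build_feature_table(
    int_table: pd.DataFrame, measure: str = "tau_s"
) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a long-format INT table into (features, labels).

    Rows are time windows, columns are channels; windows with any
    non-converged or missing estimate are dropped (complete-case policy).
    """
    t = int_table.copy()
    t.loc[~t["converged"], measure] = np.nan
    wide = t.pivot_table(index=["window", "state"], columns="channel",
                         values=measure, dropna=False)
    wide = wide.dropna(axis=0)
    y = wide.index.get_level_values("state").to_numpy()
    return wide.to_numpy(), y


def _make_search(model: str, inner: int, n_iter: int, seed: int):
    if model == "svm":
        est = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(kernel="rbf"))])
        space = {"clf__C": loguniform(1e-2, 1e3),
                 "clf__gamma": loguniform(1e-4, 1e1)}
    elif model == "logistic":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, tol=1e-4)),
        ])
        space = {"clf__C": loguniform(1e-3, 1e3)}
    else:
        raise ValueError(f"unknown model {model!r}")
    return RandomizedSearchCV(
        est,
        space,
        n_iter=n_iter,
        cv=StratifiedKFold(inner, shuffle=True, random_state=seed + 1),
        random_state=seed + 2,
        n_jobs=None,
    )


def nested_cv_classify(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "svm",
    inner: int = 10,
    outer: int = 10,
    n_iter: int = 30,
    seed: int = 0,
) -> ClassifierReport:
    """Nested cross-validated multiclass classification.

    ``X`` is windows x features, ``y`` the state label per window. The
    outer ``StratifiedKFold`` partitions the samples; on each training
    split a randomized search (``n_iter`` draws of log-uniform
    regularization and, for the SVM, kernel scale) is scored with the inner
    stratified k-fold. Feature standardization is fit on training folds
    only (inside the pipeline). Fully seeded and reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < outer:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples; "
            f"stratified {outer}-fold CV needs at least {outer} per class"
        )

    okf = StratifiedKFold(outer, shuffle=True, random_state=seed)
    y_pred = np.empty(y.shape, dtype=object)
    fold_params: list[dict] = []
    fold_curves: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        c: [] for c in classes
    }
    for k, (tr, te) in enumerate(okf.split(X, y)):
        search = _make_search(model, inner, n_iter, seed + 1000 * (k + 1))
        search.fit(X[tr], y[tr])
        best = search.best_estimator_
        fold_params.append(dict(search.best_params_))
        y_pred[te] = best.predict(X[te])
        scores = _class_scores(best, X[te])  # (n_te, n_classes) per best.classes_
        for ci, c in enumerate(best.classes_):
            y_bin = (y[te] == c).astype(int)
            if y_bin.min() == y_bin.max():
                continue  # fold test set misses the class or its complement
            fpr, tpr, _ = roc_curve(y_bin, scores[:, ci])
            fold_curves[c].append((fpr, tpr))

    conf = confusion_matrix(y, y_pred, labels=classes)
    conf_df = pd.DataFrame(conf, index=classes, columns=classes)
    per_class = {
        c: conf[i, i] / conf[i].sum() if conf[i].sum() else np.nan
        for i, c in enumerate(classes)
    }
    roc = {c: average_roc(curves) for c, curves in fold_curves.items() if curves}
    return ClassifierReport(
        classes=classes,
        confusion=conf_df,
        overall_accuracy=float(np.trace(conf) / conf.sum()),
        per_class_accuracy=per_class,
        roc=roc,
        fold_params=fold_params,
    )


def _class_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba") and hasattr(est[-1], "predict_proba"):
        return est.predict_proba(X)
    s = est.decision_function(X)
    # binary decision_function is 1-D: score for the positive (second) class
    return np.column_stack([-s, s]) if s.ndim == 1 else s


def average_roc(curves: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Average fold ROC curves on a common 101-point FPR grid.

    Each fold's curve is linearly interpolated onto the grid; the mean and
    across-fold SD of the true-positive rate are returned together with the
    AUC of the mean curve.
    """
    if len(curves) < 1:
        raise ValueError("no fold curves to average")
    tprs = []
    for fpr, tpr in curves:
        # ROC curves are right-continuous steps; at each grid point take
        # the highest TPR attained at or below that FPR
        idx = np.searchsorted(fpr, FPR_GRID, side="right") - 1
        tprs.append(np.maximum.accumulate(tpr)[np.clip(idx, 0, None)])
    T = np.vstack(tprs)
    mean = T.mean(axis=0)
    sd = T.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return {
        "fpr": FPR_GRID.copy(),
        "tpr_mean": mean,
        "tpr_sd": sd,
        "auc": float(auc(FPR_GRID, mean)),
        "n_folds": len(curves),
    }
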