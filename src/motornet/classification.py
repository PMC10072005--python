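"""Nested cross-validated SVM classification of dyskinesia degree.

The eight network AUC features feed one-versus-rest (OVR) linear support
vector machines.  Feature selection uses recursive feature elimination
(RFE): at each round the feature with the smallest aggregate |weight| across
the OVR classifiers is dropped.  Generalization is estimated with a nested
scheme — leave-one-out outer loop; inside every outer training fold a
stratified 10-fold grid search picks the regularization strength and the
retained-feature count, with scaling, ranking and selection all fitted on
training data only (no information from the held-out subject leaks into any
training artifact).  Pooled out-of-fold predictions give the confusion
matrix, accuracy, per-class sensitivity/specificity, and OVR ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics
from sklearn.feature_selection import RFE
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "ClassificationResult",
    "standardize_features",
    "rfe_rank",
    "nested_cv",
    "ovr_rates",
    "roc_curve",
]


@dataclass
class ClassifierConfig:
    """Hyperparameter search space and CV layout."""

    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 10
    n_features: int | str = "auto"  # "auto" → searched over 1…n_features_total
    scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")
        if not self.c_grid:
            raise ValueError("c_grid must be non-empty")


@dataclass
class ClassificationResult:
    classes: list[str]
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    accuracy: float
    predictions: pd.Series  # index: subject order, value: predicted class
    decision_values: pd.DataFrame  # pooled OVR decision scores, one col/class
    fold_log: list[dict]
    rates: pd.DataFrame  # per-class sensitivity/specificity
    roc: dict  # class → {"fpr": …, "tpr": …, "auc": float}
    rfe_full: pd.DataFrame  # full-data ranking + normalized weights


def _ovr_importance(est: OneVsRestClassifier) -> np.ndarray:
    """Aggregate |weight| of each feature across the OVR binary classifiers."""
    coefs = np.vstack([e.coef_ for e in est.estimators_])
    return np.abs(coefs).sum(axis=0)


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feat_cols = [c for c in features.columns if c != "subject_id"]
    X = features[feat_cols].to_numpy(dtype=float)
    y = np.asarray(labels)
    return X, y, feat_cols


def standardize_features(
    train: pd.DataFrame, apply_to: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale estimated on ``train`` only, applied to both tables.

    A zero-variance feature is centered but not scaled (warning issued).
    """
    feat_cols = [c for c in train.columns if c != "subject_id"]
    mean = train[feat_cols].mean()
    sd = train[feat_cols].std(ddof=0)
    zero = sd <= 1e-12 * mean.abs().clip(lower=1.0)
    if zero.any():
        warnings.warn(
            f"zero-variance feature(s) {list(sd.index[zero])}: centered only"
        )
        sd = sd.mask(zero, 1.0)
    out = []
    for tbl in (train, apply_to):
        scaled = tbl.copy()
        scaled[feat_cols] = (tbl[feat_cols] - mean) / sd
        out.append(scaled)
    return out[0], out[1]


def rfe_rank(
    features: pd.DataFrame, labels, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Full-data RFE elimination order plus normalized importance weights.

    Weights are the aggregate |coefficient| of each feature in the
    full-feature OVR linear SVM fit (after scaling), normalized to sum to 1;
    rank 1 is the last-surviving (most discriminative) feature.
    """
    cfg = config if config is not None else ClassifierConfig()
    X, y, feat_cols = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    if cfg.scale:
        X = StandardScaler().fit_transform(X)
    est = OneVsRestClassifier(SVC(kernel="linear", C=1.0))
    selector = RFE(est, n_features_to_select=1, importance_getter=_ovr_importance)
    selector.fit(X, y)
    weights = _ovr_importance(est.fit(X, y))
    weights = weights / weights.sum()
    frame = pd.DataFrame(
        {"feature": feat_cols, "rank": selector.ranking_, "weight": weights}
    )
    return frame.sort_values("rank", ignore_index=True)


def _make_pipeline(cfg: ClassifierConfig, n_total: int) -> tuple[Pipeline, dict]:
    steps = []
    if cfg.scale:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "rfe",
            RFE(
                OneVsRestClassifier(SVC(kernel="linear", C=1.0)),
                n_features_to_select=n_total,
                importance_getter=_ovr_importance,
            ),
        )
    )
    steps.append(("svm", OneVsRestClassifier(SVC(kernel="linear", C=1.0))))
    if cfg.n_features == "auto":
        nf_grid = list(range(1, n_total + 1))
    else:
        nf_grid = [int(cfg.n_features)]
    grid = {
        "rfe__n_features_to_select": nf_grid,
        "svm__estimator__C": list(cfg.c_grid),
    }
    return Pipeline(steps), grid


def nested_cv(
    features: pd.DataFrame, labels, config: ClassifierConfig | None = None
) -> ClassificationResult:
    """Leave-one-out outer loop around a stratified inner grid search.

    Every training-fold artifact — scaler, RFE ranking, hyperparameters —
    is fitted on the outer-training subjects only; the single held-out
    subject is scored with the refit best inner model.  Pooled predictions
    give the confusion matrix, accuracy and per-class rates; pooled OVR
    decision values give per-class ROC curves.
    """
    cfg = config if config is not None else ClassifierConfig()
    X, y, feat_cols = _as_xy(features, labels)
    classes = sorted(np.unique(y).tolist())
    n = len(y)
    if n < cfg.inner_folds + 1:
        raise ValueError("too few subjects for the inner fold count")

    preds = np.empty(n, dtype=object)
    decisions = np.zeros((n, len(classes)))
    fold_log: list[dict] = []
    for fold, (train_idx, test_idx) in enumerate(LeaveOneOut().split(X)):
        y_tr = y[train_idx]
        missing = set(classes) - set(y_tr)
        if missing:
            raise ValueError(f"class {missing.pop()!r} absent from a training fold")
        pipe, grid = _make_pipeline(cfg, X.shape[1])
        inner = StratifiedKFold(
            n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed + fold
        )
        gs = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", n_jobs=1)
        gs.fit(X[train_idx], y_tr)
        best = gs.best_estimator_
        i = test_idx[0]
        preds[i] = best.predict(X[test_idx])[0]
        dec = best.decision_function(X[test_idx])
        order = [list(best.classes_).index(c) for c in classes]
        decisions[i] = np.atleast_2d(dec)[0, order]
        rfe_step = best.named_steps["rfe"]
        fold_log.append(
            {
                "held_out": int(i),
                "best_C": float(gs.best_params_["svm__estimator__C"]),
                "best_n_features": int(gs.best_params_["rfe__n_features_to_select"]),
                "selected_features": [
                    f for f, s in zip(feat_cols, rfe_step.support_) if s
                ],
                "ranking": rfe_step.ranking_.tolist(),
            }
        )

    conf = sklearn.metrics.confusion_matrix(y, preds.astype(str), labels=classes)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    accuracy = float(np.trace(conf) / conf.sum())
    decision_frame = pd.DataFrame(decisions, columns=classes)

    roc = {}
    for k, cls in enumerate(classes):
        binary = (y == cls).astype(int)
        fpr, tpr, auc = roc_curve(decisions[:, k], binary)
        roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": auc}

    result = ClassificationResult(
        classes=classes,
        confusion=confusion,
        accuracy=accuracy,
        predictions=pd.Series(preds.astype(str)),
        decision_values=decision_frame,
        fold_log=fold_log,
        rates=pd.DataFrame(),
        roc=roc,
        rfe_full=rfe_rank(features, labels, cfg),
    )
    result.rates = ovr_rates(result)
    return result


def ovr_rates(result: ClassificationResult) -> pd.DataFrame:
    """Per-class sensitivity and specificity from the pooled confusion matrix.

    For class k the rest classes are pooled: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).  An empty class yields NaN rates.
    """
    conf = result.confusion.to_numpy(dtype=float)
    total = conf.sum()
    rows = []
    for k, cls in enumerate(result.classes):
        tp = conf[k, k]
        fn = conf[k].sum() - tp
        fp = conf[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        rows.append({"class": cls, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def roc_curve(decision_values, binary_labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal area for one binary problem.

    Thin wrapper over scikit-learn's curve (which steps simultaneously on
    tied scores); raises if only one label value is present.
    """
    scores = np.asarray(decision_values, dtype=float)
    labels = np.asarray(binary_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both label values must be present")
    fpr, tpr, _ = sklearn.metrics.roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))
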