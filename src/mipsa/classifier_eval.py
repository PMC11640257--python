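"""Wrapped SVM classification, cross-validated error, metrics and curves.

The soft-margin SVM itself is delegated to scikit-learn's solver; this
module owns the contract around it: gene-subset restriction, fold hygiene
(standardization statistics are always fitted on the training portion of a
fold only), leave-one-out and k-fold error estimation, the confusion-matrix
metrics, and ROC / precision-recall point sets. The positive class is
label 1 ("Cancer") everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expression_io import ExpressionDataset, GeneSubset

_KERNEL_MAP = {"linear": "linear", "polynomial": "poly", "rbf": "rbf"}


@dataclass
class ClassifierConfig:
    """SVM configuration.

    kernel : {"linear", "polynomial", "rbf"}; linear by default.
    C : soft-margin penalty (default 1.0).
    gamma : kernel coefficient for polynomial/rbf; None uses the
        1/(n_features * Var(X)) convention ("scale").
    degree, coef0 : polynomial-kernel degree d and offset r.
    standardize : fit a per-gene standard scaler on each training fold.
    """

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in _KERNEL_MAP:
            raise ValueError(f"kernel must be one of {sorted(_KERNEL_MAP)}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def build(self):
        svc = SVC(
            kernel=_KERNEL_MAP[self.kernel],
            C=self.C,
            gamma=self.gamma if self.gamma is not None else "scale",
            degree=self.degree,
            coef0=self.coef0,
        )
        if self.standardize:
            return make_pipeline(StandardScaler(), svc)
        return make_pipeline(svc)


@dataclass
class ConfusionMatrix:
    """Counts of true/false positives/negatives (positive class = 1)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class Metrics:
    """ACC, precision (P), recall/sensitivity (Sn) and F-score.

    Any metric whose denominator is zero is reported as 0.0 and its name
    recorded in ``undefined``.
    """

    accuracy: float
    precision: float
    recall: float
    f_score: float
    undefined: set[str] = field(default_factory=set)

    def __iter__(self):
        return iter((self.accuracy, self.precision, self.recall, self.f_score))


@dataclass
class EvaluationReport:
    """Everything the final report emits for one selected gene subset."""

    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f_score: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc_roc: float
    per_run_accuracies: list[float]
    best: float
    average: float
    worst: float


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, sensitivity and F-score from a confusion matrix.

    ACC = (TP+TN)/(TP+TN+FP+FN); P = TP/(TP+FP); Sn = TP/(TP+FN);
    F = 2*P*Sn/(P+Sn). Zero-denominator metrics are 0 and flagged.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: set[str] = set()
    acc = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp > 0:
        p = cm.tp / (cm.tp + cm.fp)
    else:
        p, undefined = 0.0, undefined | {"precision"}
    if cm.tp + cm.fn > 0:
        sn = cm.tp / (cm.tp + cm.fn)
    else:
        sn = 0.0
        undefined.add("recall")
    if p + sn > 0:
        f = 2 * p * sn / (p + sn)
    else:
        f = 0.0
        undefined.add("f_score")
    return Metrics(acc, p, sn, f, undefined)


def train_and_score(
    train: ExpressionDataset,
    test: ExpressionDataset,
    subset: GeneSubset,
    cfg: ClassifierConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training set, predict the test set; returns (labels, scores).

    Columns are restricted to the subset; when standardizing, the scaler is
    fitted on the training values only and applied to both sides, so no
    test-set statistics leak into the fit. Scores are signed decision-function
    values (positive favours class 1), suitable for ROC/PR construction.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    X_tr = train.subset_values(subset)
    X_te = test.subset_values(subset)
    model = cfg.build()
    model.fit(X_tr, train.labels)
    return model.predict(X_te), model.decision_function(X_te)


def _cv_predictions(
    X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, splitter
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Held-out predictions and scores over a CV splitter.

    Single-class training folds are skipped with a warning; the returned
    evaluated-mask marks samples that received a prediction.
    """
    preds = np.zeros_like(y)
    scores = np.zeros(len(y), dtype=float)
    evaluated = np.zeros(len(y), dtype=bool)
    for train_idx, test_idx in splitter.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            warnings.warn("skipping single-class training fold", stacklevel=2)
            continue
        model = cfg.build()
        model.fit(X[train_idx], y[train_idx])
        preds[test_idx] = model.predict(X[test_idx])
        scores[test_idx] = model.decision_function(X[test_idx])
        evaluated[test_idx] = True
    if not evaluated.any():
        raise ValueError("no fold could be evaluated (degenerate dataset)")
    return preds, scores, evaluated


def loocv_predictions(
    dataset: ExpressionDataset, subset: GeneSubset, cfg: ClassifierConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out held-out predictions, decision scores and evaluated mask."""
    if dataset.n_samples < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    X = dataset.subset_values(subset)
    return _cv_predictions(X, dataset.labels, cfg, LeaveOneOut())


def loocv_accuracy(
    dataset: ExpressionDataset, subset: GeneSubset, cfg: ClassifierConfig
) -> tuple[float, ConfusionMatrix]:
    """Leave-one-out accuracy and the aggregated confusion matrix."""
    preds, _, mask = loocv_predictions(dataset, subset, cfg)
    cm = ConfusionMatrix.from_labels(dataset.labels[mask], preds[mask])
    return (cm.tp + cm.tn) / cm.total, cm


def kfold_error(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold misclassification rate on a raw matrix."""
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds, _, mask = _cv_predictions(X, y, cfg, splitter)
    return float((preds[mask] != y[mask]).mean())


def holdout_error(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
    test_size: float = 0.2,
    seed: int = 42,
) -> float:
    """Stratified single-split misclassification rate (default 80/20)."""
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    model = cfg.build()
    model.fit(X_tr, y_tr)
    return float((model.predict(X_te) != y_te).mean())


def curves(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float]:
    """ROC and PR point sets from a threshold sweep, plus trapezoid AUC.

    ROC points run from (0, 0) to (1, 1); AUC is the trapezoid-rule area
    under them, which for tie-free scores equals the Mann-Whitney
    concordance probability. PR points are (recall, precision) in
    ascending recall.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("curves need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(labels, scores, pos_label=1)
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    pr_points = sorted(zip(recall.tolist(), precision.tolist()))
    return roc_points, pr_points, auc


def summarize_runs(per_run_accuracies: list[float]) -> tuple[float, float, float]:
    """(best, average, worst) accuracy over repeated runs."""
    if not per_run_accuracies:
        raise ValueError("no runs to summarize")
    arr = np.asarray(per_run_accuracies, dtype=float)
    return float(arr.max()), float(arr.mean()), float(arr.min())


def build_report(
    dataset: ExpressionDataset,
    subset: GeneSubset,
    cfg: ClassifierConfig,
    per_run_accuracies: list[float],
) -> EvaluationReport:
    """LOOCV-based evaluation report for one subset plus run summary."""
    preds, scores, mask = loocv_predictions(dataset, subset, cfg)
    cm = ConfusionMatrix.from_labels(dataset.labels[mask], preds[mask])
    m = metrics(cm)
    roc_points, pr_points, auc = curves(dataset.labels[mask], scores[mask])
    best, average, worst = summarize_runs(per_run_accuracies)
    return EvaluationReport(
        confusion=cm,
        accuracy=m.accuracy,
        precision=m.precision,
        recall=m.recall,
        f_score=m.f_score,
        roc_points=roc_points,
        pr_points=pr_points,
        auc_roc=auc,
        per_run_accuracies=list(per_run_accuracies),
        best=best,
        average=average,
        worst=worst,
    )
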