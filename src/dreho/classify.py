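"""Leave-one-out cross-validated linear SVM on cluster-mean features.

Each fold trains a soft-margin linear SVM (squared hinge, C=1, the library
defaults) on n-1 subjects and predicts the held-out one; features are
standardized with training-fold statistics only. Pooled predictions give
accuracy/precision/sensitivity/specificity (patient = positive class) and the
pooled signed decision scores give the ROC curve and AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC


@dataclass
class FeatureMatrix:
    """Subjects x features with binary labels (patient = positive)."""

    values: np.ndarray
    labels: np.ndarray              # 1 = patient, 0 = control
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels).astype(int)
        if self.values.ndim != 2 or self.values.shape[0] != self.labels.size:
            raise ValueError("values must be (n_subjects, n_features) matching labels")
        if np.isnan(self.values).any():
            raise ValueError("missing feature values")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]


@dataclass
class ClassifierReport:
    accuracy: float      # percent
    precision: float     # percent
    sensitivity: float   # percent
    specificity: float   # percent
    auc: float
    predictions: np.ndarray
    decision_scores: np.ndarray
    roc_points: np.ndarray  # (n_points, 2) of (FPR, TPR)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def confusion_metrics(true_labels, predicted_labels) -> dict[str, float]:
    """Accuracy/precision/sensitivity/specificity in percent, patient positive."""
    y = np.asarray(true_labels).astype(int)
    yhat = np.asarray(predicted_labels).astype(int)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("labels must be nonempty and equal length")
    tp = int(((y == 1) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    return {
        "accuracy": pct(tp + tn, y.size),
        "precision": pct(tp, tp + fp),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def roc_auc(decision_scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over a threshold sweep and the trapezoid AUC.

    Ties in the scores are handled by grouping, making the AUC equal to the
    Mann-Whitney U statistic divided by n1*n0.
    """
    scores = np.asarray(decision_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    scores_s, y_s = scores[order], y[order]
    # group tied scores so the curve is a proper step/diagonal through ties
    distinct = np.where(np.diff(scores_s))[0]
    idx = np.r_[distinct, y_s.size - 1]
    tps = np.cumsum(y_s)[idx]
    fps = np.cumsum(1 - y_s)[idx]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def loocv_linear_svm(
    fm: FeatureMatrix, C: float = 1.0, standardize: bool = True
) -> ClassifierReport:
    """Leave-one-out cross-validated linear SVM (squared hinge, default C=1)."""
    x, y = fm.values, fm.labels
    n = y.size
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    keep = x.std(axis=0) > 0
    if not keep.all():
        import warnings

        warnings.warn("dropping constant feature(s)", stacklevel=2)
        x = x[:, keep]
    if x.shape[1] == 0:
        raise ValueError("no informative features")

    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        xtr, xte = x[tr], x[i : i + 1]
        if standardize:
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            xtr, xte = (xtr - mu) / sd, (xte - mu) / sd
        clf = LinearSVC(C=C).fit(xtr, y[tr])
        preds[i] = int(clf.predict(xte)[0])
        scores[i] = float(clf.decision_function(xte)[0])

    metrics = confusion_metrics(y, preds)
    roc_points, auc = roc_auc(scores, y)
    return ClassifierReport(
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=auc,
        predictions=preds,
        decision_scores=scores,
        roc_points=roc_points,
    )
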