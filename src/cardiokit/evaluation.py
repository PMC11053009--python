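"""Classifier harness, confusion-matrix metric suite, table arithmetic, and
the binary-entropy uncertainty score.

Five standard classifiers (k-nearest neighbours, a small tanh multilayer
perceptron, an RBF-kernel SVM, a random forest, Gaussian naive Bayes) are
delegated to scikit-learn and evaluated with a stratified 80/20 split plus
10-fold cross-validation. From the held-out confusion counts the ten-metric
suite is computed exactly as conventionally printed for this problem:

    AUC    = (Se + Sp) / 2            (balanced accuracy; kept under the
                                       name the source tables use — a
                                       conventional ROC AUC is available
                                       separately as ``roc_auc``)
    ACC    = (TP + TN) / total
    Prec   = TP / (TP + FP)
    Se     = TP / (TP + FN)
    F1     = harmonic mean of Prec and Se
    MCC    = Matthews correlation coefficient
    FPR    = FP / (FP + TN)
    Sp     = TN / (TN + FP)
    G-mean = sqrt(Prec * Se)          (precision-recall convention)
    DER    = (FP + FN) / total

Classifier uncertainty is scored with the binary information entropy of a
performance fraction p: H(p) = -p*log2(p) - (1-p)*log2(1-p) bits, maximal
(1 bit) at p = 0.5 and zero at certainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ConfusionCounts

__all__ = [
    "ClassifierSpec",
    "make_classifier",
    "split_and_cv",
    "confusion_metrics",
    "roc_auc",
    "average_performance",
    "difference_ratio",
    "performance_entropy",
    "entropy_report",
    "EvalResult",
]

ALL_METRICS = ["AUC", "ACC", "F1", "Prec", "MCC", "FPR", "Se", "Sp", "G-mean", "DER"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and its fixed hyperparameters.

    kind: one of knn, nn, svm, rf, nb. The MLP uses three tanh hidden
    layers of seven neurons (a five-layer network counting input and
    output); the SVM uses an RBF kernel; defaults elsewhere are knn k=5
    and rf with 100 trees.
    """

    kind: str
    k: int = 5
    hidden_neurons: int = 7
    hidden_layers: int = 3
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "nn", "svm", "rf", "nb"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec.

    The distance- and gradient-based learners (knn, svm, nn) are wrapped in
    a standardization pipeline: clinical attributes span wildly different
    ranges (serum cholesterol in the hundreds next to 0/1 flags), and those
    learners are not scale-invariant. Tree and count-based learners (rf,
    nb) are left on the raw features.
    """
    if spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.k)
    elif spec.kind == "nn":
        est = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_neurons,) * spec.hidden_layers,
            activation="tanh",
            max_iter=3000,
            random_state=spec.seed,
        )
    elif spec.kind == "svm":
        est = SVC(kernel="rbf")
    elif spec.kind == "rf":
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=spec.seed)
    else:
        return GaussianNB()
    return make_pipeline(StandardScaler(), est)


def _pooled_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts; multi-class labels are pooled one-vs-rest."""
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if classes.size == 2:
        pos = classes[-1]
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        tn = int(np.sum((y_true != pos) & (y_pred != pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        return ConfusionCounts(tp, tn, fp, fn)
    tp = tn = fp = fn = 0
    for pos in classes:
        tp += int(np.sum((y_true == pos) & (y_pred == pos)))
        tn += int(np.sum((y_true != pos) & (y_pred != pos)))
        fp += int(np.sum((y_true != pos) & (y_pred == pos)))
        fn += int(np.sum((y_true == pos) & (y_pred != pos)))
    return ConfusionCounts(tp, tn, fp, fn)


@dataclass(frozen=True)
class EvalResult:
    counts: ConfusionCounts
    metrics: pd.Series
    cv_accuracy: np.ndarray  # per-fold accuracies

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracy))


def split_and_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: ClassifierSpec,
    ratio: float = 0.8,
    folds: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Stratified train/test evaluation with k-fold CV reported alongside.

    ``ratio`` is the training fraction; all randomness (split, folds,
    stochastic learners) derives from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("single-class data cannot be evaluated")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows; need >= {folds} for {folds}-fold CV"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=ratio, stratify=y, random_state=seed
    )
    model = make_classifier(spec)
    model.fit(X_tr, y_tr)
    y_pred = model.predict(X_te)
    cnt = _pooled_counts(y_te, y_pred)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(make_classifier(spec), X, y, cv=cv, scoring="accuracy")
    return EvalResult(cnt, confusion_metrics(cnt), scores)


def confusion_metrics(c: ConfusionCounts) -> pd.Series:
    """The ten-metric suite from confusion counts; undefined entries are NaN."""
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    total = tp + tn + fp + fn

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else np.nan

    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    fpr = _ratio(fp, fp + tn)
    acc = (tp + tn) / total
    f1 = _ratio(2 * prec * se, prec + se) if np.isfinite(prec) and np.isfinite(se) else np.nan
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else np.nan
    auc = (se + sp) / 2 if np.isfinite(se) and np.isfinite(sp) else np.nan
    gmean = math.sqrt(prec * se) if np.isfinite(prec) and np.isfinite(se) else np.nan
    der = (fp + fn) / total
    return pd.Series(
        [auc, acc, f1, prec, mcc, fpr, se, sp, gmean, der], index=ALL_METRICS
    )


def roc_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Conventional ROC area (distinct from the tables' balanced-accuracy AUC)."""
    return float(roc_auc_score(y_true, y_score))


def average_performance(a: pd.Series, b: pd.Series) -> pd.Series:
    """Element-wise mean of two metric vectors over their shared metric set."""
    if not a.index.equals(b.index):
        raise ValueError("metric vectors must share the same metric set")
    return (a + b) / 2.0


def difference_ratio(avg: pd.Series) -> pd.Series:
    """Element-wise 1 - value: each metric's shortfall from a perfect score."""
    vals = avg.astype(float)
    bad = vals[(vals < 0) | (vals > 1)].dropna()
    if len(bad):
        raise ValueError(f"entries outside [0, 1]: {sorted(bad.index)}")
    return 1.0 - vals


def performance_entropy(p_perf: float) -> float:
    """Binary information entropy of a performance fraction, in bits."""
    if not 0.0 <= p_perf <= 1.0:
        raise ValueError("performance fraction must lie in [0, 1]")
    h = 0.0
    for p in (p_perf, 1.0 - p_perf):
        if p > 0.0:
            h -= p * math.log2(p)
    return h


def entropy_report(metrics: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Per-metric uncertainty: P_perf, P_diff = 1 - P_perf, and H in bits."""
    if isinstance(metrics, pd.Series):
        metrics = metrics.to_frame().T
    flat = metrics.stack()
    rows = [
        (idx if isinstance(idx, tuple) else (0, idx), float(v))
        for idx, v in flat.items()
    ]
    out = pd.DataFrame(
        [
            {
                "classifier": key[0],
                "metric": key[1],
                "P_perf": v,
                "P_diff": 1.0 - v,
                "H_bits": performance_entropy(v)
                if np.isfinite(v) and 0.0 <= v <= 1.0
                else np.nan,
            }
            for key, v in rows
        ]
    )
    return out
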