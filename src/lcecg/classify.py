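"""Classifier training, stratified cross-validation and evaluation metrics.

Five classifiers are trained on the 45-feature sub-band matrix with the
study's hyperparameters: k-NN (k = 3, Euclidean), a one-vs-all SVM with a
3rd-order polynomial kernel and C = 50, a random forest of 60 trees,
bagged trees (50 learners) and a multilayer perceptron (one hidden layer
of 5 units, gradient descent with momentum and adaptive learning rate,
at most 1000 epochs).  Classifier internals are delegated to scikit-learn;
this module owns fold sharing and the evaluation arithmetic.

Metrics (all on the pooled held-out predictions of a shared stratified
K-fold): overall accuracy, NMI (mutual information over the arithmetic
mean of label entropies), macro F-measure, multi-class Cohen's kappa and
macro one-vs-all specificity, plus the compression/sample-reduction ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierConfig",
    "ConfusionSummary",
    "MetricReport",
    "CVResult",
    "make_classifiers",
    "train_classifiers",
    "cross_validate",
    "confusion_summary",
    "evaluate",
    "compression_ratio",
    "sample_reduction",
]

CLASSIFIER_NAMES = ("knn", "ann", "svm", "rf", "bag")


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the five classifiers."""

    knn_k: int = 3
    svm_degree: int = 3
    svm_c: float = 50.0
    rf_trees: int = 60
    bag_trees: int = 50
    ann_hidden: tuple[int, ...] = (5,)
    ann_max_epochs: int = 1000


@dataclass
class ConfusionSummary:
    """Per-class TP/FP/FN/TN counts of a multi-class prediction."""

    labels: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_total: int

    @property
    def n_classes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MetricReport:
    """Unit-interval evaluation scores of one classifier."""

    acc: float
    nmi: float
    f1: float
    kappa: float
    sp: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "nmi": self.nmi, "f1": self.f1,
                "kappa": self.kappa, "sp": self.sp}


@dataclass
class CVResult:
    """Shared-fold cross-validation outcome."""

    reports: dict[str, MetricReport]
    predictions: dict[str, np.ndarray]
    confusions: dict[str, ConfusionSummary]
    y_true: np.ndarray
    fold_of: np.ndarray


def make_classifiers(config: ClassifierConfig | None = None, seed: int = 0) -> dict:
    """Unfitted estimators keyed by short name, seeded deterministically."""
    cfg = config if config is not None else ClassifierConfig()
    return {
        "knn": KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="euclidean"),
        "ann": MLPClassifier(
            hidden_layer_sizes=cfg.ann_hidden,
            solver="sgd",
            momentum=0.9,
            learning_rate="adaptive",
            max_iter=cfg.ann_max_epochs,
            random_state=seed,
        ),
        "svm": OneVsRestClassifier(
            SVC(kernel="poly", degree=cfg.svm_degree, C=cfg.svm_c)
        ),
        "rf": RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed),
        "bag": BaggingClassifier(n_estimators=cfg.bag_trees, random_state=seed),
    }


def train_classifiers(
    features: np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> dict:
    """Fit the selected classifiers on the full matrix."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    models = make_classifiers(config, seed)
    if names is not None:
        models = {k: models[k] for k in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for model in models.values():
            model.fit(features, labels)
    return models


def confusion_summary(y_true: np.ndarray, y_pred: np.ndarray,
                      labels: list | None = None) -> ConfusionSummary:
    """Per-class one-vs-all TP/FP/FN/TN from a multi-class prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty predictions")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    n = y_true.size
    tp = np.array([np.sum((y_true == c) & (y_pred == c)) for c in labels])
    fp = np.array([np.sum((y_true != c) & (y_pred == c)) for c in labels])
    fn = np.array([np.sum((y_true == c) & (y_pred != c)) for c in labels])
    tn = n - tp - fp - fn
    return ConfusionSummary(labels=list(labels), tp=tp, fp=fp, fn=fn, tn=tn, n_total=n)


def _mutual_information(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(MI, H(true), H(pred)) in nats from the label contingency table."""
    n = y_true.size
    t_labels, t_idx = np.unique(y_true, return_inverse=True)
    p_labels, p_idx = np.unique(y_pred, return_inverse=True)
    cont = np.zeros((t_labels.size, p_labels.size))
    np.add.at(cont, (t_idx, p_idx), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / outer[nz])))
    h_t = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h_p = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    return mi, h_t, h_p


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """All five metrics from pooled predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty predictions")
    cs = confusion_summary(y_true, y_pred)
    n = cs.n_total

    acc = float(np.sum(y_true == y_pred)) / n

    mi, h_t, h_p = _mutual_information(y_true, y_pred)
    denom = 0.5 * (h_t + h_p)
    nmi = mi / denom if denom > 0 else 0.0
    nmi = float(min(max(nmi, 0.0), 1.0))

    # macro F-measure (classes are balanced in the study design)
    f1s = []
    for tp, fp, fn in zip(cs.tp, cs.fp, cs.fn):
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    f1 = float(np.mean(f1s))

    # multi-class Cohen's kappa from the confusion-matrix margins
    row = cs.tp + cs.fn  # true counts per class
    col = cs.tp + cs.fp  # predicted counts per class
    pe = float(np.sum(row * col)) / n**2
    kappa = 1.0 if pe >= 1.0 and acc >= 1.0 else (acc - pe) / (1.0 - pe) if pe < 1.0 else 0.0

    sp = float(np.mean(cs.tn / (cs.tn + cs.fp)))
    return MetricReport(acc=acc, nmi=nmi, f1=f1, kappa=float(kappa), sp=sp)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    classifiers: tuple[str, ...] | None = None,
    config: ClassifierConfig | None = None,
) -> CVResult:
    """Stratified K-fold CV with folds shared across all classifiers.

    Every instance is held out exactly once; metrics are computed on the
    pooled held-out predictions.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    names = classifiers if classifiers is not None else CLASSIFIER_NAMES
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        warnings.warn("some class has fewer instances than folds", RuntimeWarning)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, labels))
    fold_of = np.empty(labels.size, dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = f

    templates = make_classifiers(config, seed)
    predictions: dict[str, np.ndarray] = {}
    reports: dict[str, MetricReport] = {}
    confusions: dict[str, ConfusionSummary] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for name in names:
            pred = np.empty(labels.size, dtype=labels.dtype)
            for train_idx, test_idx in splits:
                model = clone(templates[name])
                model.fit(features[train_idx], labels[train_idx])
                pred[test_idx] = model.predict(features[test_idx])
            predictions[name] = pred
            reports[name] = evaluate(labels, pred)
            confusions[name] = confusion_summary(labels, pred)
    return CVResult(reports=reports, predictions=predictions, confusions=confusions,
                    y_true=labels.copy(), fold_of=fold_of)


def compression_ratio(n_classical: int, n_proposed: int) -> float:
    """R_comp = data points in the conventional chain / proposed chain."""
    if n_proposed <= 0:
        raise ValueError("n_proposed must be positive")
    return n_classical / n_proposed


def sample_reduction(classical_samples: int, lc_samples: int) -> float:
    """Ratio of fixed-rate sample count to level-crossing event count."""
    if lc_samples <= 0:
        raise ValueError("lc_samples must be positive")
    return classical_samples / lc_samples
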