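"""Classifiers and confusion-matrix diagnostics.

Covers the final stage of the pipeline: an 85/15 stratified split, linear
SVM / KNN / decision-tree classification on selected features, and the four
confusion-matrix metrics (accuracy, sensitivity, specificity, precision)
with the blast class (label 1) as positive — sensitivity is the blast
detection rate. Percentages are rounded to one decimal only at reporting
time; exact fractions are kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateTrainingError, SplitError

__all__ = [
    "SplitSpec",
    "ClassifierSpec",
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_split",
    "build_classifier",
    "train_and_predict",
    "confusion",
    "metrics",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("svm_linear", "knn", "dtree")


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/test partition recipe, with indices once resolved."""

    train_fraction: float = 0.85
    stratified: bool = True
    seed: int = 0
    train_indices: tuple[int, ...] | None = None
    test_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise SplitError("train_fraction must lie strictly between 0 and 1")
        if (self.train_indices is None) != (self.test_indices is None):
            raise ValueError("train and test indices must be set together")
        if self.train_indices is not None:
            tr, te = set(self.train_indices), set(self.test_indices)
            if tr & te:
                raise ValueError("train and test indices overlap")


def stratified_split(labels, spec: SplitSpec | None = None) -> SplitSpec:
    """Per-class floor(train_fraction * n_c) training samples by seeded shuffle.

    The remainder of each class forms the test set; a class with fewer than
    2 samples, or a fraction leaving any class without test samples, raises
    :class:`SplitError`.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train: list[int] = []
    test: list[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise SplitError(f"class {c} has {len(idx)} samples; need at least 2 to split")
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise SplitError(
                f"train_fraction {spec.train_fraction} leaves class {c} with an empty train or test set"
            )
        perm = rng.permutation(idx)
        train.extend(int(i) for i in perm[:n_train])
        test.extend(int(i) for i in perm[n_train:])
    return SplitSpec(
        train_fraction=spec.train_fraction,
        stratified=spec.stratified,
        seed=spec.seed,
        train_indices=tuple(sorted(train)),
        test_indices=tuple(sorted(test)),
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three classifiers; linear kernel mandated for the SVM."""

    kind: str = "svm_linear"
    knn_k: int = 3
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be odd (tie avoidance)")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be > 0")

    @property
    def display_name(self) -> str:
        return {"svm_linear": "SVM", "knn": "K-NN", "dtree": "DT"}[self.kind]


def build_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator for a classifier spec."""
    if spec.kind == "svm_linear":
        return SVC(kernel="linear", C=spec.svm_c)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    return DecisionTreeClassifier(criterion="gini", random_state=spec.seed)


def train_and_predict(train_X, train_y, test_X, spec: ClassifierSpec | None = None) -> np.ndarray:
    """Fit the requested classifier on the training rows and predict the test rows."""
    spec = spec or ClassifierSpec()
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test feature widths differ")
    if len(np.unique(train_y)) < 2:
        raise DegenerateTrainingError("training set contains a single class")
    model = build_classifier(spec)
    model.fit(train_X, train_y)
    return np.asarray(model.predict(test_X))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with positive class = blast (label 1)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FN/TN/FP over {0,1} label vectors of equal length."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors differ in length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must lie in {0, 1}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/sensitivity/specificity/precision as exact fractions.

    Undefined ratios (zero denominators) are ``None`` — reported as
    not-available, never as 0. Percentages round to one decimal only in
    :meth:`as_percentages`.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    cm: ConfusionMatrix = field(repr=False, default=None)  # type: ignore[assignment]

    def as_percentages(self, ndigits: int = 1) -> dict[str, float | None]:
        return {
            name: (None if v is None else round(100.0 * v, ndigits))
            for name, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("precision", self.precision),
            )
        }


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four confusion-matrix metrics as exact fractions."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.n,
        sensitivity=cm.tp / cm.positives if cm.positives > 0 else None,
        specificity=cm.tn / cm.negatives if cm.negatives > 0 else None,
        precision=cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None,
        cm=cm,
    )
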