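"""Classifier training, confusion-matrix metrics and the multi-run protocol.

The positive class is OSCC (label 1).  Metrics are the three percentage
formulas

    sensitivity = TP / (TP + FN) * 100
    precision   = TP / (TP + FP) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

reported to one decimal in summaries, full precision in machine output.
The evaluation protocol is a stratified 80/20 outer holdout (seeded); 10-fold
cross-validation within the training partition is available for sanity
checks.  Across-condition comparisons use per-run accuracies and a Welch
two-sample t-test at the 95% confidence level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier

from .datasets import FeatureDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "SplitPlan",
    "split_data",
    "train_classifier",
    "evaluate",
    "compute_metrics",
    "compare_runs",
    "cross_validate_train",
]

CLASSIFIER_KINDS = ("xgboost", "random_forest", "ann")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts with OSCC (1) as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, precision and accuracy as percentages in [0, 100].

    A metric whose denominator is zero is NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    sensitivity: float
    precision: float
    accuracy: float
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def rounded(self) -> dict[str, float]:
        """One-decimal report values (NaN preserved for undefined metrics)."""
        return {
            "sensitivity": round(self.sensitivity, 1),
            "precision": round(self.precision, 1),
            "accuracy": round(self.accuracy, 1),
        }


@dataclass(frozen=True)
class SplitPlan:
    """Stratified outer-holdout plan: train fraction, CV folds, seed."""

    train_fraction: float = 0.8
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def split_data(
    data: FeatureDataset, plan: SplitPlan
) -> tuple[FeatureDataset, FeatureDataset]:
    """Stratified train/test split: disjoint, exhaustive, seeded.

    Per class, the test allocation is round(n_class * (1 - train_fraction)),
    clamped so both partitions keep at least one member of each class.
    """
    rng = np.random.default_rng(plan.seed)
    classes = np.unique(data.y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    test_fraction = 1.0 - plan.train_fraction
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(data.y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        if plan.stratified:
            idx = rng.permutation(idx)
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (
        data.subset_rows(np.sort(np.concatenate(train_idx))),
        data.subset_rows(np.sort(np.concatenate(test_idx))),
    )


def train_classifier(
    train: FeatureDataset,
    kind: str,
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit a binary classifier of the given kind on the training partition.

    ``kind`` is one of ``xgboost``, ``random_forest`` or ``ann`` (a
    multilayer perceptron).  Hyperparameters default to the library defaults
    with fixed seeds and are fully overridable via ``hyperparams``.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("training data must contain both classes")
    params = dict(hyperparams or {})
    if kind == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("random_state", seed)
        params.setdefault("n_jobs", 1)
        model = XGBClassifier(**params)
    elif kind == "random_forest":
        params.setdefault("random_state", seed)
        params.setdefault("n_jobs", 1)
        model = RandomForestClassifier(**params)
    elif kind == "ann":
        params.setdefault("random_state", seed)
        params.setdefault("max_iter", 500)
        model = MLPClassifier(**params)
    else:
        raise ValueError(
            f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}"
        )
    model.fit(train.X, train.y)
    return model


def evaluate(model, test: FeatureDataset) -> ConfusionCounts:
    """Confusion counts on a test partition (OSCC = positive)."""
    pred = np.asarray(model.predict(test.X)).astype(int)
    y = test.y
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, precision and accuracy (percent) from confusion counts."""
    undefined = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    prec = _ratio(c.TP, c.TP + c.FP, "precision")
    acc = _ratio(c.TP + c.TN, c.total, "accuracy")
    return MetricsReport(sens, prec, acc, undefined=tuple(undefined))


def compare_runs(acc_a, acc_b) -> tuple[float, float]:
    """Welch two-sample t-test on per-run accuracies; returns (t, p).

    Significant difference at p < 0.05 (95% confidence).  Two degenerate
    zero-variance samples with equal means give (0.0, 1.0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each accuracy vector needs at least 2 runs")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cross_validate_train(
    train: FeatureDataset,
    kind: str,
    plan: SplitPlan,
    hyperparams: dict | None = None,
) -> np.ndarray:
    """k-fold CV accuracies within the training partition (sanity check)."""
    model = train_classifier(train, kind, hyperparams, seed=plan.seed)
    cv = StratifiedKFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
    return cross_val_score(model, train.X, train.y, cv=cv, scoring="accuracy")
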