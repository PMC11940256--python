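"""Random-forest pair classification: grid search, threshold tuning, metrics.

The forest itself is scikit-learn's bagged-tree ensemble; the substance
here is the protocol around it: hyperparameter selection on a validation
set (number of trees x per-split feature rule, accuracy argmax, ties to
the first listed configuration), decision-threshold (DT) tuning as an
exhaustive scan over the distinct predicted probabilities, and a retrain
on train+validation that never re-tunes on test.

Evaluation metrics are the standard confusion-matrix family:

    ACC = (TP + TN) / total        PREC = TP / (TP + FP)
    REC = TP / (TP + FN)           F1   = 2 * PREC * REC / (PREC + REC)

with ROC/AUC computed over all score thresholds (TPR = TP/(TP+FN) vs
FPR = FP/(FP+TN), trapezoidal area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "EvalReport",
    "fit_forest",
    "grid_search",
    "tune_threshold",
    "compute_metrics",
    "roc_auc",
    "evaluate_predictions",
    "retrain_and_test",
]

FEATURE_RULES = ("sqrt", "log2")


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int
    max_features_rule: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_rule not in FEATURE_RULES:
            raise ValueError(f"max_features_rule must be one of {FEATURE_RULES}")


@dataclass
class TrainedClassifier:
    """A fitted forest plus its configuration and decision threshold."""

    model: RandomForestClassifier
    config: ClassifierConfig
    decision_threshold: float = 0.5

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row."""
        return self.model.predict_proba(np.asarray(X))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.decision_threshold).astype(int)


def fit_forest(X: np.ndarray, y: np.ndarray, config: ClassifierConfig) -> RandomForestClassifier:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features_rule,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(np.asarray(X), y)
    return model


def grid_search(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    tree_grid: list[int],
    feature_rules: list[str],
    seed: int = 0,
) -> ClassifierConfig:
    """Pick the configuration with the best validation accuracy.

    Configurations are visited in listed order (trees outer, feature rule
    inner); exact ties keep the first visited — so the grid order is part
    of the contract.
    """
    if not tree_grid or not feature_rules:
        raise ValueError("grids must be nonempty")
    X_tr, y_tr = train
    X_val, y_val = np.asarray(val[0]), np.asarray(val[1])
    best: tuple[float, ClassifierConfig] | None = None
    for n_trees in tree_grid:
        for rule in feature_rules:
            config = ClassifierConfig(n_trees=n_trees, max_features_rule=rule, seed=seed)
            model = fit_forest(X_tr, y_tr, config)
            acc = float(np.mean(model.predict(X_val) == y_val))
            if best is None or acc > best[0]:
                best = (acc, config)
    assert best is not None
    return best[1]


def _threshold_objective(metric: str):
    def f1_of(tp, tn, fp, fn):
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    if metric == "f1":
        return f1_of
    if metric == "accuracy":
        return lambda tp, tn, fp, fn: (tp + tn) / (tp + tn + fp + fn)
    if metric == "youden":
        return lambda tp, tn, fp, fn: (
            (tp / (tp + fn) if tp + fn else 0.0)
            + (tn / (tn + fp) if tn + fp else 0.0) - 1.0
        )
    raise ValueError(f"unknown threshold metric {metric!r}")


def tune_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    metric: str = "f1",
) -> float:
    """Scan the distinct predicted probabilities for the best cutoff.

    A sample is called positive when ``score >= threshold``. Among
    thresholds achieving the maximal objective the smallest is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold tuning requires both classes in validation")
    objective = _threshold_objective(metric)
    best_t, best_v = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        v = objective(tp, tn, fp, fn)
        if v > best_v:  # strict: ties keep the smallest threshold
            best_t, best_v = float(t), v
    assert best_t is not None
    return best_t


def compute_metrics(TP: int, TN: int, FP: int, FN: int) -> tuple[float, float, float, float]:
    """(ACC, PREC, REC, F1) from confusion-matrix counts.

    Undefined ratios (zero denominators) return 0 with a warning rather
    than raising, so degenerate evaluations stay reportable.
    """
    counts = (TP, TN, FP, FN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion-matrix counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no evaluated records")
    acc = (TP + TN) / total
    if TP + FP == 0:
        warnings.warn("no predicted positives; PREC set to 0")
        prec = 0.0
    else:
        prec = TP / (TP + FP)
    if TP + FN == 0:
        warnings.warn("no actual positives; REC set to 0")
        rec = 0.0
    else:
        rec = TP / (TP + FN)
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC vertices (FPR, TPR) at each distinct score, and trapezoidal AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvalReport:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    PREC: float
    REC: float
    F1: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "ACC": self.ACC, "PREC": self.PREC, "REC": self.REC, "F1": self.F1,
            "AUC": self.auc,
        }


def evaluate_predictions(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> EvalReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc, prec, rec, f1 = compute_metrics(tp, tn, fp, fn)
    roc_points, auc_value = roc_auc(scores, labels)
    p, r, _ = precision_recall_curve(labels, scores)
    return EvalReport(
        TP=tp, TN=tn, FP=fp, FN=fn, ACC=acc, PREC=prec, REC=rec, F1=f1,
        roc_points=roc_points, auc=auc_value,
        pr_points=list(zip(r.tolist(), p.tolist())),
    )


def retrain_and_test(
    merged: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    config: ClassifierConfig,
    threshold: float,
    merged_keys: list | None = None,
    test_keys: list | None = None,
) -> tuple[TrainedClassifier, EvalReport]:
    """Refit on train+validation, evaluate on test at the fixed threshold.

    The threshold is never re-tuned here. If pair keys are supplied for
    both sides, any overlap trips a leakage guard.
    """
    X_test, y_test = np.asarray(test[0]), np.asarray(test[1])
    if X_test.size == 0:
        raise ValueError("empty test set")
    if merged_keys is not None and test_keys is not None:
        canon = lambda keys: {tuple(sorted(k)) for k in keys}
        overlap = canon(merged_keys) & canon(test_keys)
        if overlap:
            raise ValueError(f"leakage: {len(overlap)} pairs shared between "
                             f"training and test (e.g. {sorted(overlap)[:3]})")
    model = fit_forest(merged[0], merged[1], config)
    clf = TrainedClassifier(model=model, config=config, decision_threshold=threshold)
    report = evaluate_predictions(clf.predict_proba(X_test), y_test, threshold)
    return clf, report
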