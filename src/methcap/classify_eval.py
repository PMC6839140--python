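"""Tree-ensemble TN/non-TN classification and confusion-matrix evaluation.

The ensemble is bagged decision trees with per-split feature subsampling;
the per-tree complexity cap ("number of nodes", implemented as the maximum
leaf-node count) is tuned by scanning 1..n-1 and keeping the value with the
minimum out-of-bag error (ties to the smallest cap).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from methcap.methio import TN, ValidationError

NONTN = "nonTN"


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals for display/reporting."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix2x2:
    """Counts with the TN class as positive: rows truth, columns prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValidationError("empty confusion matrix")

    def swapped(self) -> "ConfusionMatrix2x2":
        """Relabel with the non-TN class as positive."""
        return ConfusionMatrix2x2(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass
class ClassifierReport:
    confusion: ConfusionMatrix2x2
    f1_tn: float
    f1_nontn: float
    mcc: float
    n_correct: int
    auc: float | None = None
    degenerate: bool = False


def _f1(tp: int, fp: int, fn: int) -> tuple[float, bool]:
    denom_p, denom_r = tp + fp, tp + fn
    if denom_p == 0 or denom_r == 0:
        return 0.0, True
    precision = tp / denom_p
    recall = tp / denom_r
    if precision + recall == 0:
        return 0.0, True
    return 2.0 * recall * precision / (recall + precision), False


def confusion_metrics(cm: ConfusionMatrix2x2) -> ClassifierReport:
    """F1 per class, MCC and the diagonal sum from a 2x2 confusion matrix.

    Any zero denominator factor yields 0 for the affected metric with the
    report flagged degenerate.
    """
    f1_tn, deg1 = _f1(cm.tp, cm.fp, cm.fn)
    sw = cm.swapped()
    f1_nontn, deg2 = _f1(sw.tp, sw.fp, sw.fn)
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        mcc, deg3 = 0.0, True
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)
        deg3 = False
    return ClassifierReport(
        confusion=cm,
        f1_tn=float(f1_tn),
        f1_nontn=float(f1_nontn),
        mcc=float(mcc),
        n_correct=cm.tp + cm.tn,
        degenerate=deg1 or deg2 or deg3,
    )


@dataclass
class TreeEnsemble:
    model: RandomForestClassifier | None  # None for the degenerate 1-node cap
    majority_class: str
    feature_names: list[str]
    node_count: int
    oob_errors: dict[int, float]
    n_trees: int


def _oob_error_majority(y: np.ndarray) -> float:
    vals, counts = np.unique(y, return_counts=True)
    return 1.0 - counts.max() / y.size


def train_tree_ensemble(
    features: pd.DataFrame,
    labels: dict[str, str],
    seed: int = 0,
    n_trees: int = 500,
    scan_trees: int | None = None,
    node_counts=None,
) -> TreeEnsemble:
    """Fit the bagged-tree classifier with OOB-tuned leaf-node cap.

    *features* is samples x features; *labels* maps sample -> TN/nonTN.
    The cap is scanned over ``node_counts`` (default 1..n-1); a cap of 1 is
    the degenerate majority-class tree.  ``scan_trees`` lets the scan run
    with a smaller forest than the final fit.
    """
    samples = list(features.index)
    y = np.array([labels[s] for s in samples])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("need >= 2 samples per class")
    x = features.to_numpy(float)
    n = len(samples)
    if node_counts is None:
        node_counts = range(1, n)
    scan_n = scan_trees or n_trees

    oob_errors: dict[int, float] = {}
    for k in node_counts:
        if k < 1:
            raise ValidationError(f"node count must be >= 1, got {k}")
        if k == 1:
            oob_errors[1] = _oob_error_majority(y)
            continue
        rf = RandomForestClassifier(
            n_estimators=scan_n,
            max_leaf_nodes=int(k),
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        rf.fit(x, y)
        oob_errors[int(k)] = 1.0 - float(rf.oob_score_)
    best = min(oob_errors, key=lambda k: (oob_errors[k], k))

    majority = classes[int(np.argmax(counts))]
    if best == 1:
        model = None
    else:
        model = RandomForestClassifier(
            n_estimators=n_trees,
            max_leaf_nodes=int(best),
            max_features="sqrt",
            bootstrap=True,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        model.fit(x, y)
    return TreeEnsemble(
        model=model,
        majority_class=str(majority),
        feature_names=list(features.columns),
        node_count=int(best),
        oob_errors=oob_errors,
        n_trees=n_trees,
    )


def predict_scores(ensemble: TreeEnsemble, features: pd.DataFrame) -> pd.Series:
    """Per-sample TN vote fraction (trees voting TN / total trees)."""
    missing = [f for f in ensemble.feature_names if f not in features.columns]
    if missing:
        raise ValidationError(f"missing features: {missing[:5]}")
    x = features[ensemble.feature_names].to_numpy(float)
    if ensemble.model is None:
        frac = 1.0 if ensemble.majority_class == TN else 0.0
        return pd.Series(frac, index=features.index, name="tn_vote_fraction")
    votes = np.zeros(x.shape[0])
    for tree in ensemble.model.estimators_:
        pred = ensemble.model.classes_[
            np.argmax(tree.predict_proba(x), axis=1)
        ]
        votes += pred == TN
    return pd.Series(
        votes / len(ensemble.model.estimators_),
        index=features.index,
        name="tn_vote_fraction",
    )


def predict_classes(
    ensemble: TreeEnsemble, features: pd.DataFrame, threshold: float = 0.5
) -> pd.Series:
    scores = predict_scores(ensemble, features)
    return pd.Series(
        np.where(scores >= threshold, TN, NONTN), index=scores.index, name="predicted"
    )


def confusion_from_predictions(
    predicted: pd.Series, labels: dict[str, str]
) -> ConfusionMatrix2x2:
    truth = np.array([labels[s] for s in predicted.index])
    pred = predicted.to_numpy()
    return ConfusionMatrix2x2(
        tp=int(((truth == TN) & (pred == TN)).sum()),
        fn=int(((truth == TN) & (pred != TN)).sum()),
        fp=int(((truth != TN) & (pred == TN)).sum()),
        tn=int(((truth != TN) & (pred != TN)).sum()),
    )


def roc_auc(
    scores: pd.Series, labels: dict[str, str]
) -> tuple[pd.DataFrame, float]:
    """ROC points over all score thresholds and the trapezoid AUC.

    The AUC equals the Mann-Whitney probability of concordance with ties
    counted half (TN as positive class).
    """
    y = np.array([labels[s] for s in scores.index])
    if np.unique(y).size != 2:
        raise ValidationError("both classes must be present")
    fpr, tpr, thresh = _roc_curve(y == TN, scores.to_numpy(), drop_intermediate=False)
    points = pd.DataFrame({"threshold": thresh, "fpr": fpr, "tpr": tpr})
    return points, float(_trapezoid_auc(fpr, tpr))
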