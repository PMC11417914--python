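"""Metrics, ROC/AUC, stratified cross-validation and the window-size sweep.

The six confusion-matrix metrics are computed from first principles (the
test suite cross-checks them against scikit-learn); any metric whose
denominator is zero is 0 by convention so aggregation stays total. AUC is
the tie-aware rank statistic: the probability that a random active site
outscores a random inactive one, ties counting one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .chimeric_model import FeatureSet, build_model, predict, train
from .errors import ValidationError
from .io_formats import RunConfig

# ---------------------------------------------------------------------------
# Confusion matrix & metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionMatrix":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise ValidationError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """The six confusion-matrix metrics; zero denominators give 0."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return MetricsReport(
        accuracy=_ratio(tp + tn, cm.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * precision * recall, precision + recall),
        mcc=_ratio(tp * tn - fp * fn, mcc_den),
        auc=auc,
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Tie-aware rank AUC (Mann-Whitney formulation).

    ``labels`` may be 0/1 ints or "active"/"inactive" strings.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if l in (1, "active", True) else 0 for l in labels])
    if scores.shape[0] != y.shape[0]:
        raise ValidationError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes to be present")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for CSV export/plotting."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if l in (1, "active", True) else 0 for l in labels])
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    rows = [{"fpr": 0.0, "tpr": 0.0, "threshold": np.inf}]
    tp = fp = 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and scores[j] == scores[i]:
            tp += int(y[j])
            fp += int(1 - y[j])
            j += 1
        rows.append({"fpr": fp / n_neg, "tpr": tp / n_pos, "threshold": scores[i]})
        i = j
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(y: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition into k folds of index arrays."""
    y = np.asarray(y).astype(int)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValidationError(
                f"class {cls} has {int(np.sum(y == cls))} members, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros_like(y), y)]


@dataclass
class CVResult:
    per_fold: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    variant: str = ""
    k: int = 0

    def table(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.per_fold]
        df = pd.DataFrame(rows)
        df.insert(0, "fold", range(len(rows)))
        return df


def _aggregate(reports: list[MetricsReport]) -> tuple[dict, dict]:
    df = pd.DataFrame([r.as_dict() for r in reports])
    mean = df.mean().to_dict()
    # sample (n-1) standard deviation, matching "x.xxx +/- y.yyy" reporting
    sd = df.std(ddof=1).fillna(0.0).to_dict()
    return mean, sd


def cross_validate(
    features: FeatureSet,
    variant: str,
    config: RunConfig,
    k: int = 5,
) -> CVResult:
    """Stratified k-fold CV with an inner stratified early-stopping split.

    For each fold the model trains on the other k-1 folds (10% of which,
    stratified, is held out for early stopping) and is evaluated on the
    held-out fold.
    """
    if features.y is None:
        raise ValidationError("cross_validate requires labeled features")
    folds = stratified_kfold(features.y, k, config.seed)
    reports: list[MetricsReport] = []
    for fold_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(features)), test_idx)
        tr_idx, val_idx = train_test_split(
            train_idx,
            test_size=config.val_fraction,
            stratify=features.y[train_idx],
            random_state=config.seed + fold_idx,
        )
        model = build_model(variant, "classification", config, features.dim)
        trained = train(model, features.subset(tr_idx), features.subset(val_idx), config)
        test = features.subset(test_idx)
        probs = trained.predict_proba(test)
        y_pred = (probs > config.decision_threshold).astype(int)
        cm = ConfusionMatrix.from_labels(test.y, y_pred)
        auc = roc_auc(probs, test.y) if 0 < test.y.sum() < len(test) else None
        reports.append(compute_metrics(cm, auc=auc))
    mean, sd = _aggregate(reports)
    return CVResult(per_fold=reports, mean=mean, sd=sd, variant=variant, k=k)


# ---------------------------------------------------------------------------
# Window-size sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: window_size, mean_mcc, sd_mcc
    best_size: int


def window_sweep(
    window_features: dict[int, FeatureSet],
    config: RunConfig,
    k: int = 5,
) -> SweepResult:
    """Cross-validate the local_only variant once per window size.

    ``window_features`` maps each odd size in [3, 61] to a FeatureSet whose
    windows were extracted at that size (see
    :func:`deamipred.chimeric_model.featurize_labeled`).
    """
    rows = []
    for size in sorted(window_features):
        if size % 2 == 0 or not (3 <= size <= 61):
            raise ValidationError(f"window size {size} must be odd and in [3, 61]")
        cfg = RunConfig.from_dict({**config.to_dict(), "window_size": size})
        result = cross_validate(window_features[size], "local_only", cfg, k=k)
        rows.append(
            {"window_size": size, "mean_mcc": result.mean["mcc"], "sd_mcc": result.sd["mcc"]}
        )
    table = pd.DataFrame(rows)
    best_size = int(table.loc[table["mean_mcc"].idxmax(), "window_size"])
    return SweepResult(table=table, best_size=best_size)
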