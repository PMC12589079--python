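"""Classifier evaluation from first principles.

Confusion counts, the four scalar metrics, ROC and precision-recall curves
with their areas, the calibration curve, and learning curves.  Stroke is the
positive class everywhere, and a sample is called positive when its score is
greater than or equal to the threshold.

AUC-ROC uses trapezoidal integration over the threshold sweep (equivalent to
the Mann-Whitney pair-counting statistic with half-credit for ties).  AUC-PR
uses the step-wise, right-continuous rule (the "average precision" estimator);
trapezoidal interpolation in PR space is optimistic and is deliberately not
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "MetricsReport",
    "confusion",
    "scalar_metrics",
    "roc_curve",
    "pr_curve",
    "calibration_curve",
    "learning_curve",
    "evaluate_predictions",
]


def confusion(labels, preds) -> tuple[int, int, int, int]:
    """2x2 confusion counts (tp, fp, fn, tn); stroke (1) is positive."""
    y = np.asarray(labels, dtype=int).reshape(-1)
    p = np.asarray(preds, dtype=int).reshape(-1)
    if y.shape != p.shape:
        raise ValueError("labels and preds lengths differ")
    if y.size == 0:
        raise ValueError("need at least one sample")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    return tp, fp, fn, tn


def scalar_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1); 0-by-convention on empty denominators."""
    total = tp + fp + fn + tn
    if total < 1:
        raise DataError("confusion counts are all zero")
    import warnings

    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int).reshape(-1)
    s = np.asarray(scores, dtype=float).reshape(-1)
    if y.shape != s.shape:
        raise ValueError("labels and scores lengths differ")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present for a threshold sweep")
    return y, s


def _threshold_sweep(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (tp, fp) after each group of tied scores, descending."""
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # indices where a tie group ends
    ends = np.nonzero(np.diff(s_sorted) != 0)[0]
    ends = np.append(ends, len(s_sorted) - 1)
    cum_tp = np.cumsum(y_sorted == 1)[ends]
    cum_fp = np.cumsum(y_sorted == 0)[ends]
    return cum_tp, cum_fp


def roc_curve(labels, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over descending thresholds, plus trapezoid AUC.

    Tied scores are grouped at one threshold; the point list starts at (0, 0)
    and ends at (1, 1).
    """
    y, s = _check_scores(labels, scores)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    cum_tp, cum_fp = _threshold_sweep(y, s)
    tpr = np.concatenate([[0.0], cum_tp / n_pos])
    fpr = np.concatenate([[0.0], cum_fp / n_neg])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def pr_curve(labels, scores) -> tuple[np.ndarray, float]:
    """PR points (recall, precision) over descending thresholds, step-wise AUC.

    AUC-PR = sum over thresholds of (R_t - R_{t-1}) * P_t (the average-
    precision estimator); for an all-tied scorer this equals the positive-class
    prevalence.
    """
    y, s = _check_scores(labels, scores)
    n_pos = int(np.sum(y == 1))
    cum_tp, cum_fp = _threshold_sweep(y, s)
    recall = cum_tp / n_pos
    precision = cum_tp / (cum_tp + cum_fp)
    points = np.column_stack([recall, precision])
    auc_pr = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return points, auc_pr


def calibration_curve(labels, probabilities, n_bins: int = 10) -> np.ndarray:
    """Reliability diagram points over equal-width probability bins.

    For each non-empty bin of [0, 1] the point is (mean predicted probability,
    empirical positive fraction); empty bins are omitted.  The final bin is
    closed at 1.0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    y = np.asarray(labels, dtype=int).reshape(-1)
    p = np.asarray(probabilities, dtype=float).reshape(-1)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities lengths differ")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    points = []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        points.append((float(p[sel].mean()), float(y[sel].mean())))
    return np.array(points)


@dataclass
class MetricsReport:
    """Full evaluation of one set of scored predictions."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_points: np.ndarray
    auc_roc: float
    pr_points: np.ndarray
    auc_pr: float
    calibration_points: np.ndarray
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_samples = self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "roc_points": self.roc_points.tolist(),
            "pr_points": self.pr_points.tolist(),
            "calibration_points": self.calibration_points.tolist(),
        }


def evaluate_predictions(labels, p_stroke, pred_labels, n_bins: int = 10) -> MetricsReport:
    """Assemble the full metrics report from labels, probabilities and votes."""
    tp, fp, fn, tn = confusion(labels, pred_labels)
    accuracy, precision, recall, f1 = scalar_metrics(tp, fp, fn, tn)
    roc_pts, auc = roc_curve(labels, p_stroke)
    pr_pts, auc_pr = pr_curve(labels, p_stroke)
    cal_pts = calibration_curve(labels, p_stroke, n_bins=n_bins)
    return MetricsReport(
        tp, fp, fn, tn, accuracy, precision, recall, f1,
        roc_pts, auc, pr_pts, auc_pr, cal_pts,
    )


def learning_curve(
    features: pd.DataFrame,
    fractions,
    config=None,
) -> pd.DataFrame:
    """Test accuracy as a function of training-set size.

    For each fraction, a stratified per-class subsample of the train split
    (``round(fraction * n_class)`` rows per class, drawn with a fraction-
    independent base seed so the subsets are nested-comparable) is used to fit
    one classifier, which is then evaluated on the fixed test split.  Returns
    a DataFrame with columns ``fraction, n_train, test_accuracy``.
    """
    from .features import FEATURE_NAMES
    from .model import StrokeVQC, TrainConfig, predict as model_predict

    cfg = config or TrainConfig()
    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    train_tab = features[features["split"] == "train"]
    test_tab = features[features["split"] == "test"]
    if train_tab.empty or test_tab.empty:
        raise DataError("need non-empty train and test splits")
    rng = np.random.default_rng(cfg.seed)
    perms = {
        lbl: rng.permutation(np.flatnonzero((train_tab["label"] == lbl).to_numpy()))
        for lbl in (0, 1)
    }
    rows = []
    for frac in fractions:
        take = []
        for lbl, perm in perms.items():
            k = int(round(frac * len(perm)))
            if k < 1:
                raise DataError(f"fraction {frac} leaves class {lbl} empty")
            take.append(perm[:k])
        sub = train_tab.iloc[np.sort(np.concatenate(take))]
        res = StrokeVQC(sub["label"].to_numpy(), sub[FEATURE_NAMES].to_numpy()).fit(cfg)
        preds = model_predict(test_tab, res)
        acc = float(np.mean(preds["label"].to_numpy() == test_tab["label"].to_numpy()))
        rows.append({"fraction": frac, "n_train": len(sub), "test_accuracy": acc})
    return pd.DataFrame(rows)
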