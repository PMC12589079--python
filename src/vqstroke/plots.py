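"""Thin plotting layer over the evaluation point sets (optional)."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_roc(points: np.ndarray, auc: float, ax=None):
    ax = _ax(ax)
    ax.plot(points[:, 0], points[:, 1], marker=".", label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=1)
    ax.set(xlabel="False positive rate", ylabel="True positive rate", title="ROC")
    ax.legend()
    return ax


def plot_pr(points: np.ndarray, auc_pr: float, ax=None):
    ax = _ax(ax)
    ax.plot(points[:, 0], points[:, 1], marker=".", drawstyle="steps-post",
            label=f"AUC-PR = {auc_pr:.3f}")
    ax.set(xlabel="Recall", ylabel="Precision", title="Precision-Recall")
    ax.legend()
    return ax


def plot_calibration(points: np.ndarray, ax=None):
    ax = _ax(ax)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=1, label="ideal")
    if len(points):
        ax.plot(points[:, 0], points[:, 1], marker="o")
    ax.set(xlabel="Mean predicted probability", ylabel="Empirical positive fraction",
           title="Calibration")
    ax.legend()
    return ax


def plot_learning_curves(loss: np.ndarray, accuracy: np.ndarray, ax=None):
    ax = _ax(ax)
    epochs = np.arange(1, len(loss) + 1)
    ax.plot(epochs, loss, label="train loss")
    ax.plot(epochs, accuracy, label="train accuracy")
    ax.set(xlabel="Epoch", title="Training history")
    ax.legend()
    return ax
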