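"""Weighted multiclass evaluation.

Sleep-stage data are strongly imbalanced (roughly half of all epochs are
light sleep), so precision, recall and F1 are support-weighted, and the
chance-corrected statistics — Cohen's kappa and the multiclass Matthews
correlation — carry the ranking.  Support-weighted recall is identically
the overall accuracy, which is why reported ACC and Recall columns in this
kind of study coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    matthews_corrcoef,
    precision_recall_fscore_support,
)


@dataclass
class EvalReport:
    """The weighted multiclass metric bundle for one evaluation."""

    accuracy: float
    precision: float          # support-weighted
    recall: float             # support-weighted (≡ accuracy)
    f1: float                 # support-weighted
    cohen_kappa: float
    matthews: float
    rmse: float | None        # one-hot residual RMSE, probabilistic outputs
    confusion: pd.DataFrame   # predicted (rows) × true (columns) counts
    n_test: int
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Metric row in the conventional ACC/PRC/Recall/Kappa/F/MC order."""
        return {
            "ACC": self.accuracy,
            "PRC": self.precision,
            "Recall": self.recall,
            "Kappa": self.cohen_kappa,
            "F-score": self.f1,
            "MC": self.matthews,
        }


def score(
    y_true: np.ndarray, y_pred: np.ndarray, probabilities: np.ndarray | None = None
) -> EvalReport:
    """Compute the weighted metric bundle.

    ``probabilities`` (n, C) in the sorted-label column order enables the
    one-hot residual RMSE used to track sequence-model loss.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation inputs")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0
    )
    rmse = None
    if probabilities is not None:
        probs = np.atleast_2d(probabilities)
        onehot = (y_true[:, None] == labels[None, :]).astype(float)
        if probs.shape != onehot.shape:
            raise ValueError("probabilities shape mismatch")
        rmse = float(np.sqrt(np.mean((probs - onehot) ** 2)))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    confusion = pd.DataFrame(cm.T, index=labels, columns=labels)
    confusion.index.name = "predicted"
    confusion.columns.name = "true"
    return EvalReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        cohen_kappa=float(cohen_kappa_score(y_true, y_pred)),
        matthews=float(matthews_corrcoef(y_true, y_pred)),
        rmse=rmse,
        confusion=confusion,
        n_test=len(y_true),
    )


def imbalance_report(labels: np.ndarray | pd.Series) -> pd.Series:
    """Per-class epoch fractions (the class-distribution table)."""
    s = pd.Series(np.asarray(labels))
    if s.empty:
        raise ValueError("empty label input")
    return s.value_counts(normalize=True).sort_index()


def sweep_summary(reports: list["EvalReport"]) -> dict:
    """Summarize a memory-step sweep.

    Returns the first ns attaining the maximum accuracy, the top-3 (ns,
    accuracy) pairs, and plot-ready boxplot data.  Invariant to report
    order; ties resolve to the smallest ns.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    rows = sorted(
        ((r.metadata.get("ns", i), r.accuracy) for i, r in enumerate(reports)),
        key=lambda t: t[0],
    )
    ns_arr = np.array([t[0] for t in rows])
    acc_arr = np.array([t[1] for t in rows])
    best_idx = int(np.argmax(acc_arr))  # argmax takes the first maximum
    n_tied = int(np.sum(acc_arr == acc_arr[best_idx]))
    top3_order = np.lexsort((ns_arr, -acc_arr))[:3]
    return {
        "best_ns": int(ns_arr[best_idx]),
        "best_accuracy": float(acc_arr[best_idx]),
        "ties": n_tied,
        "top3": [(int(ns_arr[i]), float(acc_arr[i])) for i in top3_order],
        "boxplot_data": {"ns": ns_arr.tolist(), "accuracy": acc_arr.tolist()},
    }


def hypnogram_compare(true, predicted) -> dict:
    """Align a predicted hypnogram with the truth for step-plot display.

    Returns the aligned series, overall agreement, and a per-stage recall
    table.  Both tables must share the epoch grid.
    """
    if len(true) != len(predicted) or true.interval != predicted.interval:
        raise ValueError("hypnograms are on different grids")
    if not (true.timestamps == predicted.timestamps).all():
        raise ValueError("hypnograms are on different grids")
    yt = true.frame["stage"].to_numpy()
    yp = predicted.frame["stage"].to_numpy()
    agree = yt == yp
    stages = np.unique(yt)
    per_stage = pd.Series(
        {s: float(agree[yt == s].mean()) for s in stages}, name="recall"
    )
    return {
        "timestamps": true.timestamps,
        "true": yt,
        "predicted": yp,
        "agreement": float(agree.mean()),
        "per_stage_recall": per_stage,
    }


def plot_hypnogram_comparison(comparison: dict, extras: pd.DataFrame | None = None):
    """Render the truth-vs-prediction step plot (plus optional signal
    panels: circadian, heart rate, steps).  Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_extra = 0 if extras is None else extras.shape[1]
    fig, axes = plt.subplots(1 + n_extra, 1, figsize=(10, 2.5 * (1 + n_extra)), sharex=True)
    axes = np.atleast_1d(axes)
    stages = list(dict.fromkeys(comparison["true"]))
    codes = {s: i for i, s in enumerate(stages)}
    t = comparison["timestamps"]
    axes[0].step(t, [codes[s] for s in comparison["true"]], where="post", label="actual")
    axes[0].step(
        t, [codes.get(s, -1) for s in comparison["predicted"]],
        where="post", label="predicted", alpha=0.7,
    )
    axes[0].set_yticks(range(len(stages)), stages)
    axes[0].legend(loc="upper right")
    if extras is not None:
        for ax, col in zip(axes[1:], extras.columns):
            ax.plot(extras.index, extras[col])
            ax.set_ylabel(col)
    fig.tight_layout()
    return fig
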