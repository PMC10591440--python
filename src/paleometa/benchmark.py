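"""Detection and authentication benchmarking against ground truth.

Jaccard/IoU and F1 between predicted and true taxon sets, swept over
assigned-read thresholds, and ROC curves over authentication scores with
ancient/modern truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "DetectionSets",
    "SweepResult",
    "jaccard",
    "f1",
    "threshold_sweep",
    "roc_curve",
    "plot_sweep",
    "plot_roc",
]


@dataclass
class DetectionSets:
    """Predicted and true taxon sets per sample (same taxonomy namespace)."""

    predicted: dict[str, set]
    truth: dict[str, set]


@dataclass
class SweepResult:
    """Mean ± sd of Jaccard and F1 across samples per read-count threshold."""

    table: pd.DataFrame  # columns: threshold, jaccard_mean/sd, f1_mean/sd

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def jaccard(predicted: set, truth: set) -> float:
    """|intersection| / |union|; two empty sets agree perfectly (1.0)."""
    union = predicted | truth
    if not union:
        return 1.0
    return len(predicted & truth) / len(union)


def f1(predicted: set, truth: set) -> float:
    """Harmonic mean of precision and recall; 1.0 when both sets are empty,
    0.0 when precision and recall are both zero."""
    if not predicted and not truth:
        return 1.0
    tp = len(predicted & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


def threshold_sweep(abundance: pd.DataFrame, truth: Mapping[str, set],
                    thresholds: Sequence[float]) -> SweepResult:
    """Sweep inclusive read-count thresholds over a samples × taxa count
    table; at each threshold the predicted set per sample is the taxa with
    count ≥ t, compared to that sample's truth set. Metrics are aggregated
    as the unweighted mean across samples with sample sd."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        jac, f1s = [], []
        for sample in abundance.index:
            counts = abundance.loc[sample]
            predicted = set(counts.index[counts >= t])
            tset = set(truth.get(sample, set()))
            jac.append(jaccard(predicted, tset))
            f1s.append(f1(predicted, tset))
        rows.append({
            "threshold": t,
            "jaccard_mean": float(np.mean(jac)),
            "jaccard_sd": float(np.std(jac, ddof=1)) if len(jac) > 1 else 0.0,
            "f1_mean": float(np.mean(f1s)),
            "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
        })
    return SweepResult(pd.DataFrame(rows))


def roc_curve(scores: Iterable[tuple[float, bool]]):
    """ROC over score thresholds (ties grouped) and trapezoid AUC.

    ``scores`` holds (score, is_ancient_truth) pairs; returns
    (fpr, tpr, thresholds, auc). Raises on single-class input.
    """
    pairs = list(scores)
    if not pairs:
        raise ValueError("no scores supplied")
    y_score = np.array([s for s, _ in pairs], dtype=float)
    y_true = np.array([bool(t) for _, t in pairs])
    if y_true.all() or not y_true.any():
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, thr = _skm.roc_curve(y_true, y_score)
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def plot_sweep(result: SweepResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, metric, label in ((axes[0], "jaccard", "Jaccard / IoU"),
                              (axes[1], "f1", "F1 score")):
        ax.errorbar(t["threshold"], t[f"{metric}_mean"], yerr=t[f"{metric}_sd"],
                    marker="o", capsize=3)
        ax.set_xlabel("assigned-read threshold")
        ax.set_ylabel(label)
        ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def plot_roc(fpr, tpr, auc_value: float, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, lw=2, label=f"AUC = {auc_value:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
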