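"""Staging metrics: confusion matrix, ACC, per-class PR/RE/F1, WF1, kappa, SEN-N1.

Definitions (rows of the confusion matrix are the expert stage, columns the
prediction):

* ACC = sum_i TP_i / M (trace over total),
* per-class precision TP/(TP+FP), recall TP/(TP+FN),
  F1 = 2 PR RE / (PR + RE), each one-vs-rest,
* WF1 = support-weighted mean of the per-class F1,
* Cohen's kappa = (Po - Pe) / (1 - Pe) with Pe = sum_i a_i b_i / n^2 from the
  row and column marginals,
* SEN-N1 = recall of stage N1.

Zero denominators map to 0 by convention. Cross-validated results pool the
per-fold confusion matrices by summation before computing metrics. The
paired Wilcoxon signed-rank test compares per-fold metric lists between two
configurations (exact null distribution for n <= 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .io import Hypnogram
from .stages import N_STAGES, STAGES

__all__ = [
    "confusion",
    "accuracy",
    "per_class_prf",
    "weighted_f1",
    "cohen_kappa",
    "sen_n1",
    "MetricsReport",
    "metrics_report",
    "paired_signed_rank",
    "export_hypnogram_comparison",
]


def confusion(y_true, y_pred) -> np.ndarray:
    """5x5 count matrix, rows = expert stage, columns = predicted stage."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= N_STAGES):
            raise ValueError("stage indices must lie in 0-4")
    cm = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (N_STAGES, N_STAGES) or np.any(cm < 0):
        raise ValueError("confusion matrix must be 5x5 with non-negative counts")
    return cm.astype(float)


def accuracy(cm) -> float:
    cm = _check_cm(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def per_class_prf(cm) -> dict[str, dict[str, float]]:
    """One-vs-rest precision/recall/F1 per stage; 0 on empty denominators."""
    cm = _check_cm(cm)
    out = {}
    for i, stage in enumerate(STAGES):
        tp = cm[i, i]
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        precision = tp / col if col > 0 else 0.0
        recall = tp / row if row > 0 else 0.0
        denom = precision + recall
        f1 = 2 * precision * recall / denom if denom > 0 else 0.0
        out[stage] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }
    return out


def weighted_f1(cm) -> float:
    """Support-weighted mean of the per-class F1 scores."""
    cm = _check_cm(cm)
    support = cm.sum(axis=1)
    total = support.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    prf = per_class_prf(cm)
    return float(
        sum(support[i] * prf[s]["f1"] for i, s in enumerate(STAGES)) / total
    )


def cohen_kappa(cm) -> float:
    cm = _check_cm(cm)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def sen_n1(cm) -> float:
    """Sensitivity (recall) of the N1 stage."""
    return per_class_prf(cm)["N1"]["recall"]


@dataclass
class MetricsReport:
    """Pooled confusion matrix with derived metrics and per-fold breakdown."""

    confusion: np.ndarray
    per_fold: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return accuracy(self.confusion)

    @property
    def per_class(self) -> dict:
        return per_class_prf(self.confusion)

    @property
    def wf1(self) -> float:
        return weighted_f1(self.confusion)

    @property
    def kappa(self) -> float:
        return cohen_kappa(self.confusion)

    @property
    def sen_n1(self) -> float:
        return sen_n1(self.confusion)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "wf1": self.wf1,
            "kappa": self.kappa,
            "sen_n1": self.sen_n1,
            "per_class": self.per_class,
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "per_fold": self.per_fold,
        }


def metrics_report(y_true, y_pred) -> MetricsReport:
    return MetricsReport(confusion=confusion(y_true, y_pred))


def paired_signed_rank(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs, the normal approximation above. Identical lists give 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D metric lists")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = spstats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def export_hypnogram_comparison(
    expert: Hypnogram, predicted: Hypnogram, path, plot_path=None
) -> pd.DataFrame:
    """Write an epoch-by-epoch expert-vs-predicted table (CSV), optional plot."""
    if len(expert) != len(predicted):
        raise ValueError(
            f"hypnogram lengths differ: {len(expert)} vs {len(predicted)}"
        )
    times = pd.date_range(
        start=expert.start_time, periods=len(expert), freq="30s"
    )
    df = pd.DataFrame(
        {
            "epoch": np.arange(len(expert)),
            "time": times,
            "expert": expert.labels,
            "predicted": predicted.labels,
            "match": expert.stages == predicted.stages,
        }
    )
    df.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(12, 5), sharex=True)
        for ax, (name, stages) in zip(
            axes, [("expert", expert.stages), ("predicted", predicted.stages)]
        ):
            ax.step(np.arange(len(expert)), stages, where="post")
            ax.set_yticks(range(N_STAGES))
            ax.set_yticklabels(STAGES)
            ax.invert_yaxis()
            ax.set_ylabel(name)
        axes[-1].set_xlabel("epoch (30 s)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return df
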