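"""Benchmark evaluation: confusion metrics and ROC sweeps over the R^2 gate.

A gene is called DE when it passes the significance screen *and* its final
model explains at least the threshold fraction of deviance (boundary-equal
R^2 is kept).  ROC curves sweep the R^2 threshold from 0.10 to 0.95 in steps
of 0.05 (18 points).  For ranking-based comparisons, genes failing either
gate are exported with p-value 1, flattening their contribution beyond the
nominal FPR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "classify",
    "confusion_metrics",
    "roc_over_rsq",
    "export_ranking",
    "RSQ_GRID",
]

RSQ_GRID = np.round(np.arange(0.10, 0.951, 0.05), 2)


def classify(
    results: pd.DataFrame, alpha: float = 0.05, rsq_threshold: float = 0.6
) -> np.ndarray:
    """Binary DE call per gene: screen-significant and R^2 >= threshold.

    Genes with NA screening p (non-convergent) or NA R^2 are never called.
    """
    p = results["adjusted_p"].to_numpy(dtype=float)
    r2 = results["r_squared"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return (p <= alpha) & (r2 >= rsq_threshold) & np.isfinite(p) & np.isfinite(r2)


def confusion_metrics(calls: np.ndarray, truth: np.ndarray) -> dict:
    """TPR, FPR, accuracy and F1 from binary calls against binary truth.

    TPR is NA when the truth has no positives; F1 is 0 when precision and
    recall are both 0.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    n = tp + fp + fn + tn
    tpr = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    fpr = fp / (fp + tn) if (fp + tn) > 0 else np.nan
    acc = (tp + tn) / n if n else np.nan
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tpr if np.isfinite(tpr) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "TPR": tpr, "FPR": fpr, "accuracy": acc, "F1": f1,
    }


def roc_over_rsq(
    results: pd.DataFrame, truth: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Confusion metrics at each R^2 threshold of the standard 18-point grid.

    Stricter thresholds can only remove calls, so TPR and FPR are
    non-increasing along the grid.
    """
    rows = []
    for thr in RSQ_GRID:
        calls = classify(results, alpha=alpha, rsq_threshold=float(thr))
        row = {"rsq_threshold": float(thr)}
        row.update(confusion_metrics(calls, truth))
        rows.append(row)
    return pd.DataFrame(rows)


def export_ranking(
    results: pd.DataFrame, rsq_threshold: float = 0.6, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene ranking p-values under the filtered-gene convention.

    Genes failing the screen or the R^2 gate (R^2 < threshold; boundary-equal
    genes pass) are assigned p = 1; passing genes keep their screening
    p-value.  This makes filtered results comparable to purely p-value-ranked
    methods.
    """
    calls = classify(results, alpha=alpha, rsq_threshold=rsq_threshold)
    p = results["p_value"].to_numpy(dtype=float)
    exported = np.where(calls, p, 1.0)
    return pd.DataFrame({"gene": results["gene"], "p_value": exported})
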