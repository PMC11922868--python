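"""Multi-label decision rule, subset accuracy, and the per-label clinical
metric panel (sensitivity, specificity, accuracy, AUC, F1, PPV, NPV, PLR, NLR).

Metrics whose denominator is zero are reported as NaN with an explicit flag
rather than coerced to 0 — on small synthetic sets a silent 0 would distort
summaries.  AUC uses the Mann–Whitney rank statistic (ties count ½), which
equals the trapezoidal ROC area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["predict_labels", "subset_accuracy", "auc_score", "clinical_panel",
           "MetricsReport"]

_METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "auc", "nlr",
                 "npv", "plr", "ppv", "f1")


@dataclass
class MetricsReport:
    """Per-label clinical metrics plus overall subset accuracy.

    ``per_label[name][metric]`` is a float (NaN when undefined);
    ``undefined[name]`` lists the metrics whose denominator vanished;
    ``confusion[name]`` holds integer (TP, FP, TN, FN).
    """

    subset_accuracy: float
    label_names: tuple[str, ...]
    per_label: dict[str, dict[str, float]]
    confusion: dict[str, dict[str, int]]
    undefined: dict[str, list[str]] = field(default_factory=dict)
    roc_points: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per label plus a macro-mean summary row."""
        rows = {name: self.per_label[name] for name in self.label_names}
        df = pd.DataFrame.from_dict(rows, orient="index")[list(_METRIC_NAMES)]
        summary = df.mean(axis=0, skipna=True)
        df.loc["macro_mean"] = summary
        df.insert(0, "subset_accuracy", np.nan)
        df.loc["macro_mean", "subset_accuracy"] = self.subset_accuracy
        return df

    def to_dict(self) -> dict:
        return {
            "subset_accuracy": self.subset_accuracy,
            "per_label": self.per_label,
            "confusion": self.confusion,
            "undefined": self.undefined,
        }


def predict_labels(y_prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize probabilities per label: ŷ = 1 where p ≥ threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"decision threshold must lie in [0, 1], got {threshold}")
    return (np.asarray(y_prob, dtype=np.float64) >= threshold).astype(np.int64)


def subset_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of samples whose whole predicted label vector matches exactly."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return float(np.all(y_true == y_pred, axis=-1).mean())


def auc_score(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """ROC AUC by the Mann–Whitney rank formulation; ties contribute ½.

    Returns NaN when only one class is present.
    """
    y_true = np.asarray(y_true).ravel()
    y_score = np.asarray(y_score, dtype=np.float64).ravel()
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(y_score)  # average ranks handle ties as ½
    rank_sum_pos = ranks[y_true == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def clinical_panel(y_true: np.ndarray, y_pred: np.ndarray,
                   y_prob: np.ndarray | None = None,
                   label_names: tuple[str, ...] | None = None,
                   roc_points: bool = False) -> MetricsReport:
    """Per-label confusion counts and the nine-metric clinical panel.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/B; PPV = TP/(TP+FP); NPV = TN/(TN+FN);
    PLR = sens/(1−spec); NLR = (1−sens)/spec;
    F1 = 2·PPV·sens/(PPV+sens); AUC from y_prob by rank statistic.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.ndim == 1:
        y_true, y_pred = y_true[:, None], y_pred[:, None]
        if y_prob is not None:
            y_prob = np.asarray(y_prob)[:, None]
    b, k = y_true.shape
    if label_names is None:
        label_names = tuple(f"label_{j}" for j in range(k))

    per_label: dict[str, dict[str, float]] = {}
    confusion: dict[str, dict[str, int]] = {}
    undefined: dict[str, list[str]] = {}
    rocs: dict[str, np.ndarray] = {}
    for j, name in enumerate(label_names):
        t, p = y_true[:, j], y_pred[:, j]
        tp = int(np.sum((t == 1) & (p == 1)))
        fp = int(np.sum((t == 0) & (p == 1)))
        tn = int(np.sum((t == 0) & (p == 0)))
        fn = int(np.sum((t == 1) & (p == 0)))
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        ppv = _safe_div(tp, tp + fp)
        npv = _safe_div(tn, tn + fn)
        plr = _safe_div(sens, 1.0 - spec) if np.isfinite(spec) else float("nan")
        nlr = _safe_div(1.0 - sens, spec) if np.isfinite(sens) else float("nan")
        f1 = _safe_div(2.0 * ppv * sens, ppv + sens) \
            if np.isfinite(ppv) and np.isfinite(sens) else float("nan")
        auc = auc_score(t, y_prob[:, j]) if y_prob is not None else float("nan")
        metrics = {"sensitivity": sens, "specificity": spec,
                   "accuracy": (tp + tn) / b, "auc": auc, "nlr": nlr,
                   "npv": npv, "plr": plr, "ppv": ppv, "f1": f1}
        per_label[name] = metrics
        confusion[name] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        flagged = [m for m, v in metrics.items() if not np.isfinite(v)]
        if flagged:
            undefined[name] = flagged
        if roc_points and y_prob is not None:
            rocs[name] = _roc_curve(t, y_prob[:, j])

    return MetricsReport(subset_accuracy=subset_accuracy(y_true, y_pred),
                         label_names=tuple(label_names), per_label=per_label,
                         confusion=confusion, undefined=undefined,
                         roc_points=rocs)


def _roc_curve(y_true: np.ndarray, y_score: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points at every distinct score threshold, for plotting."""
    order = np.argsort(-y_score, kind="stable")
    t = y_true[order]
    s = y_score[order]
    tps = np.cumsum(t)
    fps = np.cumsum(1 - t)
    keep = np.r_[np.diff(s) != 0, True]
    n_pos, n_neg = max(int(t.sum()), 1), max(int((1 - t).sum()), 1)
    fpr = np.r_[0.0, fps[keep] / n_neg]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    return np.column_stack([fpr, tpr])
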