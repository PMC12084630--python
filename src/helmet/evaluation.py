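"""Multiclass evaluation: threshold-averaged weighted one-vs-rest curves,
argmax accuracy, worsening-reformulated sensitivity/specificity, and
split-level summaries with 95% confidence intervals.

AUROC/AUPRC are binary notions; for the 4-class task each metric is computed
one-vs-rest per class at every probability threshold in [0, 1], then averaged
across classes weighted by the number of true observations in each class.
Curve areas come from trapezoidal integration over the swept curve.  For
sensitivity/specificity the task is reformulated as *worsening*: an event is
"future class exceeds current class", applied identically to the truth and to
the argmax prediction.

A uniform-random predictor on a class-balanced set scores AUROC ≈ 0.5,
AUPRC ≈ 0.25 and accuracy ≈ 0.25 under these definitions.

Metrics that cannot be computed (single-class subsets, empty filtered sets)
are reported as explicit NaN-with-flag entries, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import N_CLASSES

METRIC_NAMES = ("auroc", "auprc", "accuracy", "sensitivity", "specificity")
MODES = ("overall", "filtered")

#: threshold grid: 1001 equally spaced points plus all observed unique scores,
#: so that areas are insensitive to further grid refinement
N_GRID = 1001

UNDEFINED = float("nan")


def _threshold_grid(p: np.ndarray) -> np.ndarray:
    base = np.linspace(0.0, 1.0, N_GRID)
    thr = np.unique(np.concatenate([base, np.unique(p)]))
    return thr


@dataclass
class Curves:
    """Threshold-indexed weighted one-vs-rest ROC and PR curves."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auroc: float
    auprc: float


def weighted_ovr_curves(p: np.ndarray, targets: np.ndarray) -> Curves:
    """Weighted one-vs-rest ROC/PR curves swept over probability thresholds.

    Parameters
    ----------
    p : (n, 4) array
        Predicted class probabilities (rows on the simplex).
    targets : (n,) int array
        True class codes in {0..3}; at least two distinct classes required.

    At each threshold ``t`` the per-class one-vs-rest confusion (prediction
    ``p[:, c] >= t``) yields TPR/FPR/precision/recall, which are averaged
    across classes with weights equal to the true-class observation counts.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(targets, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("one-vs-rest curves need at least two target classes")

    thr = _threshold_grid(p)
    n = y.size
    weights = np.zeros(N_CLASSES)
    weights[classes] = counts
    wsum = weights.sum()

    tpr_acc = np.zeros(thr.size)
    fpr_acc = np.zeros(thr.size)
    prec_acc = np.zeros(thr.size)
    rec_acc = np.zeros(thr.size)
    for c in range(N_CLASSES):
        if weights[c] == 0:
            continue
        pos = y == c
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        s_pos = np.sort(p[pos, c])
        s_neg = np.sort(p[~pos, c])
        # of positives, how many score >= t  (searchsorted on sorted scores)
        tp = n_pos - np.searchsorted(s_pos, thr, side="left")
        fp = n_neg - np.searchsorted(s_neg, thr, side="left")
        tpr = tp / n_pos
        fpr = fp / n_neg if n_neg else np.zeros_like(thr, dtype=float)
        predicted_pos = tp + fp
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(predicted_pos > 0, tp / np.maximum(predicted_pos, 1), 1.0)
        w = weights[c] / wsum
        tpr_acc += w * tpr
        fpr_acc += w * fpr
        prec_acc += w * prec
        rec_acc += w * tpr

    # sweep from the highest threshold (0,0) to the lowest (1,1)
    order = np.argsort(thr)[::-1]
    fpr_s, tpr_s = fpr_acc[order], tpr_acc[order]
    rec_s, prec_s = rec_acc[order], prec_acc[order]
    auroc = float(np.trapezoid(tpr_s, fpr_s))
    auprc = float(np.trapezoid(prec_s, rec_s))
    return Curves(
        thresholds=thr[order],
        fpr=fpr_s,
        tpr=tpr_s,
        precision=prec_s,
        recall=rec_s,
        auroc=auroc,
        auprc=auprc,
    )


def accuracy_argmax(p: np.ndarray, targets: np.ndarray) -> float:
    """Share of observations whose highest predicted probability is the true
    class; probability ties break to the lowest class code."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(targets, dtype=int)
    if y.size == 0:
        return UNDEFINED
    return float(np.mean(np.argmax(p, axis=1) == y))


def worsening_metrics(
    p: np.ndarray, targets: np.ndarray, current: np.ndarray
) -> tuple[float, float]:
    """Sensitivity and specificity for the worsening reformulation.

    True label 1 iff ``target > current``; predicted label 1 iff
    ``argmax(p) > current``.  Returns NaN for a side with no eligible truth.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(targets, dtype=int)
    cur = np.asarray(current, dtype=int)
    true_pos = y > cur
    pred_pos = np.argmax(p, axis=1) > cur
    sens = float(np.mean(pred_pos[true_pos])) if true_pos.any() else UNDEFINED
    neg = ~true_pos
    spec = float(np.mean(~pred_pos[neg])) if neg.any() else UNDEFINED
    return sens, spec


def evaluate(
    p: np.ndarray,
    targets: np.ndarray,
    current: np.ndarray,
    mode: str = "overall",
) -> dict[str, float]:
    """All five metrics on the requested subset.

    ``mode="filtered"`` keeps only transition observations (target class
    differs from the current class) before computing anything.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    p = np.asarray(p, dtype=float)
    y = np.asarray(targets, dtype=int)
    cur = np.asarray(current, dtype=int)
    if mode == "filtered":
        keep = y != cur
        p, y, cur = p[keep], y[keep], cur[keep]
    out: dict[str, float] = {}
    if y.size == 0:
        return {m: UNDEFINED for m in METRIC_NAMES}
    try:
        curves = weighted_ovr_curves(p, y)
        out["auroc"], out["auprc"] = curves.auroc, curves.auprc
    except ValueError:
        out["auroc"] = out["auprc"] = UNDEFINED
    out["accuracy"] = accuracy_argmax(p, y)
    out["sensitivity"], out["specificity"] = worsening_metrics(p, y, cur)
    return out


@dataclass
class MetricsReport:
    """Split-level metric values with mean and 95% CI per metric and mode."""

    per_split: dict[str, list[dict[str, float]]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for mode, reports in self.per_split.items():
            for metric in METRIC_NAMES:
                values = [r[metric] for r in reports]
                mean, lo, hi, n_def = summarize_values(values)
                for split_idx, v in enumerate(values):
                    rows.append(
                        dict(mode=mode, metric=metric, split=split_idx, value=v,
                             mean=mean, ci_lo=lo, ci_hi=hi, n_defined=n_def)
                    )
        return pd.DataFrame(rows)


def summarize_values(values: Sequence[float]) -> tuple[float, float, float, int]:
    """Mean and t-based 95% CI (``mean ± t_{0.975, n−1}·sd/√n``) across splits.

    Undefined (NaN) split values propagate with reduced n; a single defined
    value yields a degenerate CI at the point.
    """
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    n = defined.size
    if n == 0:
        return UNDEFINED, UNDEFINED, UNDEFINED, 0
    mean = float(defined.mean())
    if n == 1:
        return mean, mean, mean, 1
    sd = float(defined.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return mean, mean - half, mean + half, n


def summarize_splits(
    per_split: Mapping[str, Sequence[dict[str, float]]]
) -> MetricsReport:
    """Assemble a :class:`MetricsReport` from per-mode lists of metric dicts."""
    if any(len(v) < 1 for v in per_split.values()):
        raise ValueError("at least one split report required per mode")
    return MetricsReport(per_split={k: list(v) for k, v in per_split.items()})


def metrics_table(
    report: MetricsReport, model: str, task: int, cohort: str = "synthetic"
) -> pd.DataFrame:
    """Long-format metrics table: model, task, cohort, mode, metric, split, value, mean, CI."""
    df = report.summary()
    df.insert(0, "model", model)
    df.insert(1, "task", task)
    df.insert(2, "cohort", cohort)
    return df


def plot_metrics_radar(summary: pd.DataFrame, path: str) -> None:
    """Radar chart of mean metric values per model (one axis per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = list(METRIC_NAMES)
    angles = np.linspace(0, 2 * np.pi, len(metrics), endpoint=False).tolist()
    angles += angles[:1]
    fig, ax = plt.subplots(subplot_kw=dict(polar=True), figsize=(5, 5))
    for (model, mode), grp in summary.groupby(["model", "mode"]):
        means = [grp.loc[grp.metric == m, "mean"].iloc[0] for m in metrics]
        means += means[:1]
        ax.plot(angles, means, label=f"{model} ({mode})")
        ax.fill(angles, means, alpha=0.08)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(metrics)
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
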