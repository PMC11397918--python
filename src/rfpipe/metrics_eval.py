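"""Segmentation and classification evaluation metrics with ROC/AUC.

Segmentation metrics are the standard overlap measures between a predicted
mask A and a reference mask B (Jaccard, Dice, pixel accuracy, sensitivity,
precision, specificity).  Classification metrics are frame-level accuracy,
sensitivity, specificity from the confusion counts, plus the area under
the ROC curve computed by a threshold sweep over the per-frame scores with
trapezoidal integration (equal scores collapse into one threshold step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve, auc as _sk_auc


@dataclass
class SegMetrics:
    jsc: float
    dsc: float
    acc: float
    sen: float
    pre: float
    spe: float
    empty_pair: bool = False   # both masks empty; overlap defined as 1

    def as_dict(self):
        return asdict(self)


@dataclass
class ClfMetrics:
    acc: float
    sen: float
    spe: float
    auc: float = np.nan
    roc: list = field(default_factory=list)   # [(FPR, TPR), ...]

    def as_dict(self):
        d = asdict(self)
        d.pop("roc")
        return d


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Overlap metrics between binary masks of equal shape."""
    a = _as_binary(pred, "pred")
    b = _as_binary(truth, "truth")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tp = int(np.sum(a & b))
    fp = int(np.sum(a & ~b))
    fn = int(np.sum(~a & b))
    tn = int(np.sum(~a & ~b))
    union = tp + fp + fn
    if union == 0:   # identical empty masks
        return SegMetrics(jsc=1.0, dsc=1.0, acc=1.0,
                          sen=1.0, pre=1.0, spe=_ratio(tn, tn + fp),
                          empty_pair=True)
    jsc = tp / union
    dsc = 2 * tp / (2 * tp + fp + fn)
    return SegMetrics(
        jsc=jsc, dsc=dsc,
        acc=(tp + tn) / (tp + tn + fp + fn),
        sen=_ratio(tp, tp + fn), pre=_ratio(tp, tp + fp),
        spe=_ratio(tn, tn + fp))


def _as_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} mask must be binary")
    return m.astype(bool)


def _ratio(num, den):
    return num / den if den else 1.0


def mean_seg_metrics(pairs, mode: str = "macro") -> SegMetrics:
    """Cohort segmentation score over (pred, truth) mask pairs.

    ``macro`` computes metrics per image then averages; ``micro`` pools
    pixel counts across the cohort first.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no mask pairs")
    if mode == "macro":
        ms = [seg_metrics(p, t) for p, t in pairs]
        return SegMetrics(*[float(np.mean([getattr(m, f) for m in ms]))
                            for f in ("jsc", "dsc", "acc", "sen", "pre", "spe")])
    if mode == "micro":
        pred = np.concatenate([np.ravel(p) for p, _ in pairs])
        truth = np.concatenate([np.ravel(t) for _, t in pairs])
        return seg_metrics(pred, truth)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def clf_metrics(predicted: np.ndarray, labels: np.ndarray) -> ClfMetrics:
    """Frame-level accuracy/sensitivity/specificity from predicted classes."""
    predicted = np.asarray(predicted).astype(int)
    labels = np.asarray(labels).astype(int)
    if predicted.size == 0 or predicted.shape != labels.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    tp = int(np.sum((predicted == 1) & (labels == 1)))
    tn = int(np.sum((predicted == 0) & (labels == 0)))
    fp = int(np.sum((predicted == 1) & (labels == 0)))
    fn = int(np.sum((predicted == 0) & (labels == 1)))
    acc = (tp + tn) / (tp + tn + fp + fn)
    if tp + fn == 0:
        warnings.warn("no positive frames: sensitivity undefined")
        sen = np.nan
    else:
        sen = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative frames: specificity undefined")
        spe = np.nan
    else:
        spe = tn / (tn + fp)
    return ClfMetrics(acc=acc, sen=sen, spe=spe)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ClfMetrics:
    """ROC curve and AUC from continuous per-frame scores.

    Thresholds sweep the unique score values (ties grouped into a single
    step); the area is the trapezoidal integral of TPR over FPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_sk_auc(fpr, tpr))
    pred = (scores > 0.5).astype(int)
    m = clf_metrics(pred, labels)
    m.auc = auc
    m.roc = list(zip(fpr.tolist(), tpr.tolist()))
    return m


# ---------------------------------------------------------------------------
# Reports and plots
# ---------------------------------------------------------------------------

def report_frame(seg: dict[str, SegMetrics] | None = None,
                 clf: dict[str, ClfMetrics] | None = None) -> pd.DataFrame:
    """Flatten named metric sets into one tidy table."""
    rows = []
    for name, m in (seg or {}).items():
        rows.append({"name": name, "kind": "segmentation", **m.as_dict()})
    for name, m in (clf or {}).items():
        rows.append({"name": name, "kind": "classification", **m.as_dict()})
    return pd.DataFrame(rows)


def save_roc_csv(m: ClfMetrics, path) -> None:
    pd.DataFrame(m.roc, columns=["fpr", "tpr"]).to_csv(path, index=False)


def plot_roc(metrics: dict[str, ClfMetrics], path) -> None:
    """ROC curves for several tasks on one axis (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, m in metrics.items():
        pts = np.array(m.roc)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {m.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
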