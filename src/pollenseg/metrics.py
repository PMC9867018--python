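"""Classification and segmentation evaluation metrics.

Classification metrics are one-vs-rest per class from the confusion counts:

    precision = TP/(TP+FP)    recall = TP/(TP+FN)
    specificity = TN/(TN+FP)  F1 = 2*precision*recall/(precision+recall)

with unweighted (macro) averages across classes and overall accuracy.
Segmentation metrics come from the pixel confusion matrix P (C+1 classes
including background):

    MIoU = mean_i  P_ii / (sum_j P_ij + sum_j P_ji - P_ii)
    MPA  = mean_i  P_ii / sum_j P_ij

Classes absent from both prediction and ground truth are excluded from the
means.  Any zero-denominator metric evaluates to 0 (with a warning) so reports
stay finite on degenerate inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "MetricsReport",
    "classification_metrics",
    "f1_from_pr",
    "macro_average",
    "segmentation_metrics",
    "round3",
]


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, the display convention of the reports."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics; all values in [0, 1]."""

    per_class: dict[str, list[float]] = field(default_factory=dict)
    macro: dict[str, float] = field(default_factory=dict)
    accuracy: float | None = None
    miou: float | None = None
    mpa: float | None = None
    pixel_accuracy: float | None = None

    def rounded(self) -> dict:
        out: dict = {}
        for k, vs in self.per_class.items():
            out[k] = [round3(v) for v in vs]
        for k, v in self.macro.items():
            out[f"macro_{k}"] = round3(v)
        for k in ("accuracy", "miou", "mpa", "pixel_accuracy"):
            v = getattr(self, k)
            if v is not None:
                out[k] = round3(v)
        return out


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(values) -> float:
    """Unweighted arithmetic mean over classes."""
    vals = list(values)
    if not vals:
        raise ValueError("cannot average an empty list")
    return float(np.mean(vals))


def classification_metrics(
    true_labels, predicted_labels, num_classes: int, average: str = "macro"
) -> MetricsReport:
    """One-vs-rest precision/recall/specificity/F1 per class plus aggregates.

    ``average='weighted'`` weights per-class metrics by class support instead
    of the committed macro convention.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if y.size == 0:
        raise ValueError("empty label vectors")
    if ((y < 0) | (y >= num_classes) | (p < 0) | (p >= num_classes)).any():
        raise ValueError(f"labels must lie in [0, {num_classes})")
    if average not in ("macro", "weighted"):
        raise ValueError("average must be 'macro' or 'weighted'")

    n = y.size
    report = MetricsReport()
    per: dict[str, list[float]] = {"precision": [], "recall": [], "specificity": [], "f1": []}
    support = []
    for c in range(num_classes):
        tp = int(((y == c) & (p == c)).sum())
        fp = int(((y != c) & (p == c)).sum())
        fn = int(((y == c) & (p != c)).sum())
        tn = n - tp - fp - fn
        prec = _safe_div(tp, tp + fp, f"precision[class {c}]")
        rec = _safe_div(tp, tp + fn, f"recall[class {c}]")
        spec = _safe_div(tn, tn + fp, f"specificity[class {c}]")
        per["precision"].append(prec)
        per["recall"].append(rec)
        per["specificity"].append(spec)
        per["f1"].append(f1_from_pr(prec, rec))
        support.append(int((y == c).sum()))
    report.per_class = per
    if average == "macro":
        report.macro = {k: macro_average(v) for k, v in per.items()}
    else:
        w = np.asarray(support, dtype=float) / n
        report.macro = {k: float(np.dot(w, v)) for k, v in per.items()}
    report.accuracy = float((y == p).mean())
    return report


def segmentation_metrics(pred, gt, num_classes: int = 2) -> MetricsReport:
    """MIoU, MPA and pixel accuracy from per-pixel class maps.

    Binary masks (bool) are treated as {background, foreground} class maps.
    Classes absent from both maps contribute nothing to the means.
    """
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    p = p.astype(int).ravel()
    g = g.astype(int).ravel()
    if ((p < 0) | (p >= num_classes) | (g < 0) | (g >= num_classes)).any():
        raise ValueError(f"pixel classes must lie in [0, {num_classes})")
    conf = np.bincount(g * num_classes + p, minlength=num_classes**2).reshape(
        num_classes, num_classes
    )
    diag = np.diag(conf).astype(float)
    gt_tot = conf.sum(axis=1).astype(float)  # sum_j P_ij
    pred_tot = conf.sum(axis=0).astype(float)  # sum_j P_ji
    union = gt_tot + pred_tot - diag
    present = union > 0
    if not present.any():
        raise ValueError("no classes present")
    iou = diag[present] / union[present]
    pa = np.array(
        [_safe_div(diag[c], gt_tot[c], f"pixel accuracy[class {c}]")
         for c in np.flatnonzero(present)]
    )
    report = MetricsReport()
    report.per_class = {"iou": iou.tolist(), "pa": pa.tolist()}
    report.miou = float(iou.mean())
    report.mpa = float(pa.mean())
    report.pixel_accuracy = float(diag.sum() / conf.sum())
    return report
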