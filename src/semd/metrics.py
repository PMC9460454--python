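"""Segmentation evaluation: confusion matrix, MIoU, MPA, MSE/PSNR.

With K+1 classes (background is class 0), the pixel confusion matrix has
entries p_ij = number of pixels of true class i predicted as class j.
MIoU averages p_ii / (Σ_j p_ij + Σ_j p_ji − p_ii) over classes; MPA averages
the per-class recall p_ii / Σ_j p_ij.  Classes absent from both prediction
and truth (an empty union, 0/0) are excluded from the means.

PSNR = 10·log10((2ⁿ−1)² / MSE) in dB for n-bit images; identical images
return ``math.inf``.
"""

from __future__ import annotations

import json
import math

import numpy as np


class ConfusionMatrix:
    """Accumulable (K+1)×(K+1) pixel-count confusion matrix."""

    def __init__(self, num_classes: int):
        if num_classes < 1:
            raise ValueError("need at least one class")
        self.num_classes = num_classes
        self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)

    def update(self, gt, pred) -> "ConfusionMatrix":
        gt = np.asarray(gt).ravel()
        pred = np.asarray(pred).ravel()
        if gt.shape != pred.shape:
            raise ValueError("gt and pred must have the same shape")
        k = self.num_classes
        if gt.size and (gt.min() < 0 or gt.max() >= k or pred.min() < 0 or pred.max() >= k):
            raise ValueError(f"labels must lie in [0, {k})")
        idx = gt.astype(np.int64) * k + pred.astype(np.int64)
        self.counts += np.bincount(idx, minlength=k * k).reshape(k, k)
        return self

    @classmethod
    def from_arrays(cls, gt, pred, num_classes: int) -> "ConfusionMatrix":
        return cls(num_classes).update(gt, pred)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        out = ConfusionMatrix(self.num_classes)
        out.counts = self.counts + other.counts
        return out


def _as_counts(cm) -> np.ndarray:
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty — no pixels evaluated")
    return counts


def per_class_iou(cm) -> np.ndarray:
    """IoU per class; NaN where the class union is empty."""
    counts = _as_counts(cm)
    diag = np.diag(counts).astype(np.float64)
    union = counts.sum(axis=1) + counts.sum(axis=0) - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, diag / union, np.nan)


def miou(cm) -> float:
    """Mean intersection-over-union over classes with a non-empty union."""
    return float(np.nanmean(per_class_iou(cm)))


def mpa(cm) -> float:
    """Mean per-class pixel accuracy (recall); empty ground-truth rows excluded."""
    counts = _as_counts(cm)
    diag = np.diag(counts).astype(np.float64)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(row > 0, diag / row, np.nan)
    return float(np.nanmean(acc))


def mse(reference, test) -> float:
    """Mean squared pixel difference."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    return float(np.mean((reference - test) ** 2))


def psnr(reference, test, n_bits: int = 8) -> float:
    """Peak signal-to-noise ratio in decibels; ``math.inf`` for identical images."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    err = mse(reference, test)
    if err == 0.0:
        return math.inf
    peak = (2 ** n_bits - 1) ** 2
    return 10.0 * math.log10(peak / err)


def metric_report(cm, psnr_values=None) -> dict:
    """Machine-readable metric summary {miou, mpa, per_class_iou, psnr}."""
    ious = per_class_iou(cm)
    report = {
        "miou": miou(cm),
        "mpa": mpa(cm),
        "per_class_iou": [None if math.isnan(v) else float(v) for v in ious],
    }
    if psnr_values is not None:
        finite = [v for v in psnr_values if math.isfinite(v)]
        report["psnr"] = float(np.mean(finite)) if finite else math.inf
    return report


def format_report(report: dict) -> str:
    """Human-readable table for a metric report."""
    lines = [f"{'metric':<16}{'value':>10}"]
    lines.append(f"{'MIoU':<16}{report['miou']:>10.4f}")
    lines.append(f"{'MPA':<16}{report['mpa']:>10.4f}")
    for i, v in enumerate(report["per_class_iou"]):
        shown = "   n/a" if v is None else f"{v:10.4f}"
        lines.append(f"{f'IoU[class {i}]':<16}{shown:>10}")
    if "psnr" in report:
        lines.append(f"{'PSNR (dB)':<16}{report['psnr']:>10.2f}")
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps({k: (None if isinstance(v, float) and math.isinf(v) else v)
                       for k, v in report.items()}, indent=2)
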