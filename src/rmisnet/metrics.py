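"""Pixel-level segmentation metrics from confusion counts.

Accuracy, precision, recall, F1 and IoU are the usual ratios of the
per-pixel confusion tallies with foreground (value 1) as the positive
class.  Zero-denominator cases return 0 by convention.  Metrics can be
aggregated either per image and then averaged (default) or over the
pooled pixels of a whole set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "segmentation_metrics",
    "evaluate_masks",
    "write_metrics_report",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def _as_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def confusion_counts(pred_mask, target_mask) -> ConfusionCounts:
    """Per-pixel TP/FP/FN/TN tallies; foreground (1) is positive."""
    pred = _as_binary(pred_mask, "pred_mask")
    target = _as_binary(target_mask, "target_mask")
    if pred.shape != target.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs target {target.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & target)),
        fp=int(np.sum(pred & ~target)),
        fn=int(np.sum(~pred & target)),
        tn=int(np.sum(~pred & ~target)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def segmentation_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and IoU from confusion counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "precision": precision,
        "recall": recall,
        "f1": _ratio(2 * precision * recall, precision + recall),
        "iou": _ratio(tp, tp + fp + fn),
    }


def evaluate_masks(
    pred_masks, target_masks, mode: str = "per_image"
) -> dict[str, float]:
    """Aggregate metrics over a set of mask pairs.

    ``per_image`` computes the five ratios per pair and averages them;
    ``pooled`` sums the confusion counts over all pairs first.
    """
    if mode not in ("per_image", "pooled"):
        raise ValueError("mode must be 'per_image' or 'pooled'")
    pairs = list(zip(pred_masks, target_masks))
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    if mode == "pooled":
        total = ConfusionCounts(0, 0, 0, 0)
        for pred, target in pairs:
            total = total + confusion_counts(pred, target)
        return segmentation_metrics(total)
    per = [segmentation_metrics(confusion_counts(p, t)) for p, t in pairs]
    return {k: float(np.mean([m[k] for m in per])) for k in METRIC_NAMES}


def write_metrics_report(metrics: dict[str, float], path, fmt: str = "csv"):
    """Emit a flat key -> value table as CSV or aligned plain text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key, value in metrics.items():
                writer.writerow([key, f"{value:.6f}"])
    elif fmt == "text":
        width = max(len(k) for k in metrics)
        lines = [f"{k.ljust(width)}  {v:.6f}" for k, v in metrics.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("fmt must be 'csv' or 'text'")
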