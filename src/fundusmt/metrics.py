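"""Confusion-count evaluation of segmentation and grading.

Segmentation metrics are computed from pooled pixel counts: Accuracy =
(TP+TN)/N, IoU = TP/(TP+FP+FN), Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R).  Computed from a single pooled count these satisfy the
algebraic identity F1 = 2*IoU/(1+IoU).

Dataset-level numbers pool counts over all images before applying the
formulas (per-image averaging is available but not the default — pooling
preserves the F1/IoU identity and count additivity).  Field-of-view masks
are not applied unless explicitly passed: every pixel counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .specs import N_GRADES

__all__ = [
    "BinaryMask", "ProbabilityMap", "ConfusionCounts", "MetricReport",
    "binarize", "confusion", "segmentation_metrics", "grading_accuracy",
    "evaluate_dataset",
]


def as_probability_map(p: np.ndarray) -> np.ndarray:
    """Validate a 2-D probability map: finite values in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {p.shape}")
    if not np.isfinite(p).all():
        raise ValueError("probability map contains non-finite values")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError(f"probabilities outside [0,1]: min {p.min()}, max {p.max()}")
    return p


def as_binary_mask(m: np.ndarray) -> np.ndarray:
    """Validate a 2-D {0,1} mask; returns a uint8 array."""
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask values must be exactly 0 or 1, got {vals[:8]}")
    return m.astype(np.uint8)


# Aliases documenting intent at call sites.
BinaryMask = np.ndarray
ProbabilityMap = np.ndarray


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies: TP/FP/TN/FN of predicted vs. true vessel masks."""
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """The five segmentation metrics, each in [0, 1].

    ``degenerate`` flags any ratio that was 0/0 and returned as 0.
    """
    accuracy: float
    iou: float
    precision: float
    recall: float
    f1: float
    degenerate: tuple[str, ...] = ()

    CSV_HEADER = "accuracy,iou,precision,recall,f1"

    def to_csv_row(self) -> str:
        return (f"{self.accuracy:.6f},{self.iou:.6f},{self.precision:.6f},"
                f"{self.recall:.6f},{self.f1:.6f}")

    def to_json(self) -> str:
        return json.dumps({
            "accuracy": self.accuracy, "iou": self.iou,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "degenerate": list(self.degenerate),
        })


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map; ties at exactly ``threshold`` map to 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    p = as_probability_map(p)
    return (p >= threshold).astype(np.uint8)


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    pred = as_binary_mask(pred)
    truth = as_binary_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def segmentation_metrics(c: ConfusionCounts) -> MetricReport:
    """Apply the five metric formulas to one (possibly pooled) count."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    deg: list[str] = []
    accuracy = (c.tp + c.tn) / c.total
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, "iou", deg)
    precision = _ratio(c.tp, c.tp + c.fp, "precision", deg)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", deg)
    if precision + recall == 0.0:
        deg.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    if deg:
        warnings.warn(f"degenerate 0/0 metrics returned as 0: {deg}",
                      RuntimeWarning, stacklevel=2)
    return MetricReport(accuracy, iou, precision, recall, f1, tuple(deg))


def grading_accuracy(pred_grades: Sequence[int], true_grades: Sequence[int]) -> float:
    """Fraction of exactly matching retinopathy grades (0-4)."""
    pred = np.asarray(pred_grades)
    true = np.asarray(true_grades)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("grade sequences must be equal-length, 1-D, non-empty")
    for arr, name in ((pred, "predicted"), (true, "true")):
        if arr.min() < 0 or arr.max() >= N_GRADES:
            raise ValueError(f"{name} grades outside 0..{N_GRADES - 1}")
    return float(np.mean(pred == true))


def evaluate_dataset(pairs: Iterable[tuple[BinaryMask, BinaryMask]],
                     *, per_image: bool = False,
                     fov_masks: Optional[Iterable[np.ndarray]] = None
                     ) -> MetricReport:
    """Metrics over (pred, truth) mask pairs.

    Default pools pixel counts globally; ``per_image=True`` averages the
    per-image metric values instead.  ``fov_masks`` optionally restricts
    counting to field-of-view pixels.
    """
    fov_iter = iter(fov_masks) if fov_masks is not None else None
    counts: list[ConfusionCounts] = []
    for pred, truth in pairs:
        if fov_iter is not None:
            fov = np.asarray(next(fov_iter)).astype(bool)
            pred = np.asarray(pred)[fov].reshape(1, -1)
            truth = np.asarray(truth)[fov].reshape(1, -1)
        counts.append(confusion(pred, truth))
    if not counts:
        raise ValueError("no mask pairs supplied")
    if per_image:
        reports = [segmentation_metrics(c) for c in counts]
        return MetricReport(
            accuracy=float(np.mean([r.accuracy for r in reports])),
            iou=float(np.mean([r.iou for r in reports])),
            precision=float(np.mean([r.precision for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            degenerate=tuple(sorted({d for r in reports for d in r.degenerate})),
        )
    pooled = counts[0]
    for c in counts[1:]:
        pooled = pooled + c
    return segmentation_metrics(pooled)
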