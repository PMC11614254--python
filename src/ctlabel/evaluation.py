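"""Segmentation and slice-level detection metrics.

Segmentation quality is summarised by the Dice similarity coefficient

    DSC = 2*TP / (2*TP + FP + FN)

together with recall TP/(TP+FN) and precision TP/(TP+FP), computed from
pixel confusion counts. Table-style summaries pool pixel counts over a whole
scan volume and report one metric per scan (per-volume convention); a
per-slice mode is available. Dataset summaries report mean +/- sample
standard deviation over scans.

Slice-level detection classifies every axial slice by whether the predicted
and ground-truth masks overlap: a slice with ground truth is a TP if the
prediction touches it anywhere (else FN, including the nonempty-but-disjoint
case — the miss dominates); a slice without ground truth is an FP if the
prediction marks anything (else TN). The tally is summarised by accuracy,
specificity, sensitivity, PPV and NPV; ratios with a zero denominator are
reported as missing (None), never as 0.

Degenerate-mask conventions (where the DSC formula is 0/0): two empty masks
score DSC 1.0, and an empty prediction has precision 1.0 (it made no false
positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np


class ShapeError(ValueError):
    pass


class NoDataError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel- or slice-level confusion counts; soft (real) counts allowed."""

    tp: float
    fp: float
    fn: float
    tn: float = 0.0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    recall: float
    precision: float


@dataclass
class DetectionTally:
    """Slice-level detection counts; sum equals the number of slices."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def add(self, outcome: str):
        setattr(self, outcome.lower(), getattr(self, outcome.lower()) + 1)


def _as_bool(mask) -> np.ndarray:
    arr = getattr(mask, "pixels", mask)
    return np.asarray(arr, dtype=bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


def _recall(c: ConfusionCounts) -> float:
    return 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)


def _precision(c: ConfusionCounts) -> float:
    # empty prediction made no false positives
    return 1.0 if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)


def seg_metrics(pred_masks: Sequence, gt_masks: Sequence,
                per: str = "volume") -> "SegMetrics | List[SegMetrics]":
    """DSC/recall/precision for one scan.

    ``per="volume"`` (default) pools pixel counts over all slices and returns
    a single :class:`SegMetrics`; ``per="slice"`` returns one per slice.
    """
    pred_masks, gt_masks = list(pred_masks), list(gt_masks)
    if len(pred_masks) != len(gt_masks):
        raise ShapeError("prediction and ground-truth slice counts differ")
    if not pred_masks:
        raise NoDataError("no slices to evaluate")
    per_slice = [confusion_counts(p, g) for p, g in zip(pred_masks, gt_masks)]
    if per == "slice":
        return [SegMetrics(dsc(c), _recall(c), _precision(c)) for c in per_slice]
    total = ConfusionCounts(0, 0, 0, 0)
    for c in per_slice:
        total = total + c
    return SegMetrics(dsc(total), _recall(total), _precision(total))


def detect_slice(pred, gt) -> str:
    """Classify one slice as 'TP', 'FP', 'FN' or 'TN' by mask overlap."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {g.shape}")
    if g.any():
        return "TP" if (p & g).any() else "FN"
    return "FP" if p.any() else "TN"


def detection_tally(pred_masks: Sequence, gt_masks: Sequence) -> DetectionTally:
    tally = DetectionTally()
    for p, g in zip(pred_masks, gt_masks):
        tally.add(detect_slice(p, g))
    return tally


def _ratio(num: int, denom: int) -> Optional[float]:
    return None if denom == 0 else num / denom


def detection_metrics(tally: DetectionTally) -> dict:
    """Accuracy, specificity, sensitivity, PPV and NPV as fractions in [0,1].

    Ratios whose denominator is zero are returned as None (missing).
    """
    if tally.n == 0:
        raise NoDataError("empty detection tally")
    return {
        "accuracy": (tally.tp + tally.tn) / tally.n,
        "specificity": _ratio(tally.tn, tally.tn + tally.fp),
        "sensitivity": _ratio(tally.tp, tally.tp + tally.fn),
        "ppv": _ratio(tally.tp, tally.tp + tally.fp),
        "npv": _ratio(tally.tn, tally.tn + tally.fn),
    }


def dataset_summary(per_scan: Sequence[SegMetrics]) -> dict:
    """Mean and sample SD (ddof=1; 0.0 for a single scan) per metric."""
    per_scan = list(per_scan)
    if not per_scan:
        raise NoDataError("no scans to summarise")
    out = {}
    for name in ("dsc", "recall", "precision"):
        vals = np.array([getattr(m, name) for m in per_scan], dtype=np.float64)
        sd = 0.0 if len(vals) < 2 else float(vals.std(ddof=1))
        out[name] = {"mean": float(vals.mean()), "sd": sd}
    return out
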