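"""Pixel-level evaluation metrics for binary panicle segmentation.

Implements the standard confusion-count metrics for a single foreground
class (panicle = 1, background = 0): pixel accuracy, precision, recall,
F1, per-class intersection-over-union and their mean (mIoU). mIoU here
averages the panicle and background IoU, the convention under which a
heavily background-dominated canopy image can score pixel accuracy near
0.99 while mIoU sits far lower.

Zero-denominator metrics are defined as 0 and flagged rather than NaN so
that dataset-level aggregation stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "evaluate_dataset"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts with panicle (1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

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


@dataclass
class MetricReport:
    pixel_accuracy: float
    precision: float
    recall: float
    f1: float
    iou_panicle: float
    iou_background: float
    miou: float
    zero_denominator: list[str] = field(default_factory=list)
    aggregation: str | None = None

    def as_dict(self) -> dict:
        d = {
            "pixel_accuracy": self.pixel_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "iou_panicle": self.iou_panicle,
            "iou_background": self.iou_background,
            "miou": self.miou,
        }
        if self.aggregation is not None:
            d["aggregation"] = self.aggregation
        if self.zero_denominator:
            d["zero_denominator"] = list(self.zero_denominator)
        return d


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must contain only {{0, 1}}, found values {vals}")
    return arr.astype(bool)


def confusion(pred, ref) -> ConfusionCounts:
    """Exact pixel confusion counts between predicted and reference masks."""
    pred_arr = np.asarray(pred)
    ref_arr = np.asarray(ref)
    if pred_arr.shape != ref_arr.shape:
        raise ValueError(
            f"shape mismatch: pred {pred_arr.shape} vs ref {ref_arr.shape}"
        )
    p = _check_binary(pred_arr, "pred")
    r = _check_binary(ref_arr, "ref")
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """All confusion-based metrics from one set of counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 is their harmonic
    mean; IoU_panicle = TP/(TP+FP+FN); IoU_background = TN/(TN+FP+FN);
    mIoU averages the two class IoUs.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    flags: list[str] = []
    acc = (c.tp + c.tn) / c.total
    prec = _safe_div(c.tp, c.tp + c.fp, "precision", flags)
    rec = _safe_div(c.tp, c.tp + c.fn, "recall", flags)
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1", flags)
    iou_p = _safe_div(c.tp, c.tp + c.fp + c.fn, "iou_panicle", flags)
    iou_b = _safe_div(c.tn, c.tn + c.fp + c.fn, "iou_background", flags)
    miou = (iou_p + iou_b) / 2.0
    return MetricReport(
        pixel_accuracy=acc,
        precision=prec,
        recall=rec,
        f1=f1,
        iou_panicle=iou_p,
        iou_background=iou_b,
        miou=miou,
        zero_denominator=flags,
    )


def evaluate_dataset(pairs, aggregation: str = "micro") -> MetricReport:
    """Aggregate metrics over (pred, ref) mask pairs.

    ``micro`` sums confusion counts over all pairs and computes metrics
    once; ``macro`` averages per-image metrics. The report records which
    convention was used.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset requires at least one mask pair")
    if aggregation not in ("micro", "macro"):
        raise ValueError(f"aggregation must be 'micro' or 'macro', got {aggregation!r}")
    counts = [confusion(p, r) for p, r in pairs]
    if aggregation == "micro":
        total = counts[0]
        for c in counts[1:]:
            total = total + c
        rep = metrics(total)
        rep.aggregation = "micro"
        return rep
    reports = [metrics(c) for c in counts]
    flags = sorted({f for r in reports for f in r.zero_denominator})
    n = len(reports)
    return MetricReport(
        pixel_accuracy=sum(r.pixel_accuracy for r in reports) / n,
        precision=sum(r.precision for r in reports) / n,
        recall=sum(r.recall for r in reports) / n,
        f1=sum(r.f1 for r in reports) / n,
        iou_panicle=sum(r.iou_panicle for r in reports) / n,
        iou_background=sum(r.iou_background for r in reports) / n,
        miou=sum(r.miou for r in reports) / n,
        zero_denominator=flags,
        aggregation="macro",
    )
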