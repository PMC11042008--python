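"""Pixel-level segmentation metrics: ACC, SE, SP, IoU and Dice.

All five derive from the pixel confusion counts of a predicted vs.
ground-truth binary mask pair:

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    SE   = TP / (TP + FN)          (sensitivity / recall on lesion pixels)
    SP   = TN / (TN + FP)          (specificity on background pixels)
    IoU  = TP / (TP + FP + FN)
    Dice = 2*TP / (2*TP + FP + FN) = 2*IoU / (1 + IoU)

A 0/0 denominator means both masks agree that the class is absent; by the
package's convention that metric is 1.0 (an alternative NaN mode skips it).
Dataset aggregation is either ``micro`` (pool counts, compute once — the
headline default) or ``macro`` (compute per image, average).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "aggregate",
    "write_report",
    "REPORT_COLUMNS",
]

# Column order used by every report this package writes.
REPORT_COLUMNS = ("acc", "iou", "dice", "se", "sp")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    se: float
    sp: float
    iou: float
    dice: float

    def as_row(self) -> tuple[float, ...]:
        return tuple(getattr(self, k) for k in REPORT_COLUMNS)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact integer pixel tallies; masks must be same-shape and strictly 0/1."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask contains non-binary values {vals[:5]}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: int, den: int, zero_division: str) -> float:
    if den == 0:
        return float("nan") if zero_division == "nan" else 1.0
    return num / den


def compute_metrics(c: ConfusionCounts, zero_division: str = "one") -> MetricsReport:
    """Evaluate the five metrics from counts; ``zero_division`` is 'one' or 'nan'."""
    if c.total == 0:
        raise ValueError("no pixels evaluated")
    if zero_division not in ("one", "nan"):
        raise ValueError(f"unknown zero_division mode {zero_division!r}")
    return MetricsReport(
        acc=(c.tp + c.tn) / c.total,
        se=_ratio(c.tp, c.tp + c.fn, zero_division),
        sp=_ratio(c.tn, c.tn + c.fp, zero_division),
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, zero_division),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, zero_division),
    )


def aggregate(counts_per_image: Sequence[ConfusionCounts], mode: str = "micro") -> MetricsReport:
    """micro: pool counts then compute once; macro: average per-image metrics."""
    counts = list(counts_per_image)
    if not counts:
        raise ValueError("aggregate needs at least one image")
    if mode == "micro":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return compute_metrics(pooled)
    if mode == "macro":
        reports = [compute_metrics(c) for c in counts]
        return MetricsReport(
            **{k: float(np.mean([getattr(r, k) for r in reports])) for k in ("acc", "se", "sp", "iou", "dice")}
        )
    raise ValueError(f"unknown aggregation mode {mode!r}")


def write_report(path, per_image: Iterable[tuple[str, MetricsReport]], summary: MetricsReport) -> None:
    """Per-image CSV plus a summary row, columns Acc, IoU, Dice, SE, SP."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("id",) + tuple(c.upper() for c in REPORT_COLUMNS))
        for image_id, report in per_image:
            writer.writerow((image_id,) + tuple(f"{v:.6f}" for v in report.as_row()))
        writer.writerow(("SUMMARY",) + tuple(f"{v:.6f}" for v in summary.as_row()))
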