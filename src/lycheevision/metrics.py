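"""Detection evaluation: circle matching and precision/recall/F1.

Detections are matched one-to-one to ground-truth circles greedily by
descending circle IoU (closed-form lens-area intersection). Precision is
``TP / (TP + FP)``, recall ``TP / (TP + FN)`` and the F1-score their
harmonic mean ``2 P Rc / (P + Rc)``; reported values are percentages
rounded half-up to two decimals, with the unrounded fractions retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .core import Circle

__all__ = ["MetricsReport", "circle_iou", "match_detections", "compute_report"]


def _lens_area(d: float, r1: float, r2: float) -> float:
    """Intersection area of two discs with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rm = min(r1, r2)
        return math.pi * rm * rm
    a1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    return (
        r1 * r1 * (a1 - math.sin(2 * a1) / 2)
        + r2 * r2 * (a2 - math.sin(2 * a2) / 2)
    )


def circle_iou(a: Circle, b: Circle) -> float:
    """Intersection over union of two disc areas (closed form)."""
    d = math.hypot(a.cx - b.cx, a.cy - b.cy)
    inter = _lens_area(d, a.r, b.r)
    union = a.area + b.area - inter
    return inter / union


def match_detections(
    dets: list[Circle], truth: list[Circle], iou_thr: float = 0.4
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching by descending IoU.

    Returns ``(tp, fn, fp, assignment)`` where assignment holds
    (detection index, truth index) pairs with IoU >= ``iou_thr``.
    """
    if not (0.0 < iou_thr < 1.0):
        raise ValueError("iou_thr must be in (0, 1)")
    pairs = [
        (circle_iou(d, t), di, ti)
        for di, d in enumerate(dets)
        for ti, t in enumerate(truth)
    ]
    # sort by IoU descending; index keys make ties deterministic
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    assignment: list[tuple[int, int]] = []
    for iou, di, ti in pairs:
        if iou < iou_thr:
            break
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        assignment.append((di, ti))
    tp = len(assignment)
    return tp, len(truth) - tp, len(dets) - tp, assignment


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """TP/FN/FP counts with derived percentage metrics.

    ``precision``/``recall``/``f1`` are display percentages rounded
    half-up to two decimals; the ``*_raw`` fields keep full precision
    (as fractions in [0, 1]).
    """

    tp: int
    fn: int
    fp: int
    precision_raw: float
    recall_raw: float
    f1_raw: float

    @property
    def total(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> float:
        return _round2(100.0 * self.precision_raw)

    @property
    def recall(self) -> float:
        return _round2(100.0 * self.recall_raw)

    @property
    def f1(self) -> float:
        return _round2(100.0 * self.f1_raw)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def as_table_row(self) -> str:
        return (
            f"{self.tp}\t{self.fn}\t{self.fp}\t"
            f"{self.precision:.2f}\t{self.recall:.2f}\t{self.f1:.2f}"
        )


def compute_report(tp: int, fn: int, fp: int) -> MetricsReport:
    """Precision, recall and F1 from raw counts.

    Degenerate cases: ``tp + fp == 0`` leaves precision undefined and
    raises, likewise ``tp + fn == 0`` for recall — except the all-zero-TP
    case with both denominators positive, where P = Rc = 0 and F1 is
    defined as 0.
    """
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("precision undefined: tp + fp == 0")
    if tp + fn == 0:
        raise ValueError("recall undefined: tp + fn == 0")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(tp, fn, fp, precision, recall, f1)
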