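"""Detection scoring, parameter tuning, and the daily status rule.

Detections are matched to ground-truth lying boxes greedily by descending
IoU, one-to-one. A matched pair at or above the IoU threshold is a true
positive; unmatched detections are false positives; unmatched lying
annotations are false negatives. Because a pure detection task has no
natural negatives, a frame containing neither lying annotations nor
detections contributes one frame-level true negative — the only
consistent way to populate the accuracy formula A = (TP+TN)/(TP+TN+FP+FN).

The daily status rule flags a bird as abnormal (possible atrophy or
illness) when at least half of its daytime observations show the lying
posture; under uniform sampling the observation fraction is the fraction
of photographed time.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DetectionParams, PipelineConfig
from .posture import detect_lying

__all__ = [
    "ConfusionCounts",
    "EvalSummary",
    "StatusReport",
    "iou",
    "match_and_count",
    "evaluate_frames",
    "metrics",
    "grid_search",
    "daily_status",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalSummary:
    accuracy: float
    precision: float
    recall: float
    f1: float
    iou_threshold: float | None = None


@dataclass(frozen=True)
class StatusReport:
    bird_id: str
    lying_fraction: float
    status: str  # "normal" | "abnormal"


def _as_box(b) -> tuple:
    if hasattr(b, "box"):
        return tuple(b.box)
    if hasattr(b, "as_tuple"):
        return b.as_tuple()
    return tuple(b)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes; 0 when disjoint
    or when either box has zero area."""
    ax, ay, aw, ah = _as_box(box_a)
    bx, by, bw, bh = _as_box(box_b)
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        return 0.0
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def match_and_count(detections, annotations, iou_thr: float = 0.5) -> ConfusionCounts:
    """Greedy one-to-one IoU matching for a single frame.

    ``annotations`` may carry labels; only "lying" boxes are positives
    (unlabeled boxes are treated as lying). Other labels (standing,
    pillar) are context only and never matched.
    """
    lying = [
        b for b in annotations if getattr(b, "label", "lying") == "lying"
    ]
    dets = list(detections)
    if not lying and not dets:
        return ConfusionCounts(tn=1)
    pairs = sorted(
        (
            (iou(d, a), di, ai)
            for di, d in enumerate(dets)
            for ai, a in enumerate(lying)
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_d, used_a = set(), set()
    tp = 0
    for score, di, ai in pairs:
        if score < iou_thr:
            break
        if di in used_d or ai in used_a:
            continue
        used_d.add(di)
        used_a.add(ai)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(dets) - tp, fn=len(lying) - tp)


def evaluate_frames(per_frame, iou_thr: float = 0.5) -> ConfusionCounts:
    """Sum frame-level counts over (detections, annotations) pairs."""
    total = ConfusionCounts()
    for dets, anns in per_frame:
        total = total + match_and_count(dets, anns, iou_thr)
    return total


def metrics(counts: ConfusionCounts, iou_threshold: float | None = None) -> EvalSummary:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with zero denominators are reported as 0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    a = counts.tp + counts.tn, counts.total
    p = ratio(counts.tp, counts.tp + counts.fp, "precision")
    r = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvalSummary(
        accuracy=a[0] / a[1], precision=p, recall=r, f1=f1, iou_threshold=iou_threshold
    )


def grid_search(
    frames,
    grid: dict,
    iou_thr: float = 0.5,
    config: PipelineConfig | None = None,
    base_params: DetectionParams | None = None,
):
    """Exhaustive enumeration of parameter combinations, scored by F1.

    ``frames`` is a sequence of (MergedFrame, Annotation) pairs; ``grid``
    maps DetectionParams field names (k1..k5, ...) to candidate values.
    Returns (best DetectionParams, table) where the table holds one row
    per combination with its confusion counts and metrics. Roll
    correction and trough location do not depend on k1–k5, so they are
    computed once per frame and the grid loops only over the downstream
    stages. The result is deterministic and order-independent: ties on F1
    go to the first combination in grid order.
    """
    from .correction import correct_frame
    from .posture import (
        denoise_mask,
        extract_boxes,
        filter_columns,
        merge_contours,
        segment_key_area,
    )
    from .trough import TroughNotFoundError, compute_key_area, locate_trough

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must provide at least one value per parameter")
    config = config or PipelineConfig()
    base_params = base_params or config.params

    prepared = []  # (corrected frame, trough or None, annotation)
    for frame, ann in frames:
        corrected, _ = correct_frame(frame, config.correction)
        try:
            trough = locate_trough(corrected.depth, config.trough)
        except TroughNotFoundError:
            trough = None
        prepared.append((corrected, trough, ann))

    names = list(grid.keys())
    rows = []
    best = None  # (f1, index, params)
    for idx, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        try:
            params = base_params.replace(**dict(zip(names, combo)))
        except ValueError:
            continue  # infeasible corner of the grid (e.g. k2 ≥ k3)
        counts = ConfusionCounts()
        for corrected, trough, ann in prepared:
            dets = []
            if trough is not None:
                try:
                    key = compute_key_area(
                        trough,
                        (corrected.width, corrected.height),
                        k1=params.k1,
                        side_margin=config.key_area_side_margin,
                    )
                except ValueError:
                    key = None
                if key is not None:
                    mask = segment_key_area(
                        corrected.depth, trough, key, k2=params.k2, k3=params.k3
                    )
                    mask = denoise_mask(mask, params)
                    mask = filter_columns(mask, key.h, k4=params.k4)
                    mask = merge_contours(mask, gap=params.merge_gap_px)
                    dets = extract_boxes(
                        mask, min_area=params.min_contour_area_px, k5=params.k5
                    )
            counts = counts + match_and_count(dets, ann.boxes, iou_thr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = metrics(counts, iou_threshold=iou_thr)
        row = {n: v for n, v in zip(names, combo)}
        row.update(
            tp=counts.tp, tn=counts.tn, fp=counts.fp, fn=counts.fn,
            accuracy=summary.accuracy, precision=summary.precision,
            recall=summary.recall, f1=summary.f1,
        )
        rows.append(row)
        if best is None or summary.f1 > best[0]:
            best = (summary.f1, idx, params)
    if best is None:
        raise ValueError("no feasible parameter combination in the grid")
    return best[2], pd.DataFrame(rows)


def daily_status(observations, bird_id: str = "") -> StatusReport:
    """Classify one bird's day from (timestamp, lying) observations.

    Abnormal (possible atrophy) iff the lying fraction is ≥ 0.5 — the
    boundary itself counts as abnormal.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    lying = sum(1 for _, flag in obs if flag)
    frac = lying / len(obs)
    return StatusReport(
        bird_id=bird_id,
        lying_fraction=frac,
        status="abnormal" if frac >= 0.5 else "normal",
    )
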