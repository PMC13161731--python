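"""Pixel-level overlap metrics and instance-level detection metrics.

Pixel level: Dice = 2TP / (2TP + FP + FN) and IoU = TP / (TP + FP + FN) over
a pixel confusion table, optionally restricted to the ROI (pixel centres
inside the polygon, the same membership rule used for instance centroids).

Instance level: precision, recall and F1 from one-to-one match counts, with
Wilson score intervals.  Ratios with zero denominators are *undefined* and
reported as ``None``, never coerced to 0 or 1 — in low-prevalence regions
that distinction changes the interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely import contains_xy
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, UndefinedMetricError
from .mask_io import LabelField
from .matching import MatchResult


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DetectionSummary:
    """Instance-level detection counts and rates for one evaluation.

    ``precision``/``recall``/``f1`` are ``None`` when undefined (0/0).
    Wilson intervals are ``None`` whenever the corresponding rate is.
    """

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    wilson_precision: Optional[tuple[float, float]]
    wilson_recall: Optional[tuple[float, float]]


def _roi_mask(shape: tuple[int, int], roi: Polygon, microns_per_pixel: float) -> np.ndarray:
    """Boolean mask of pixels whose centre falls inside (or on) the ROI."""
    h, w = shape
    s = microns_per_pixel
    xs = (np.arange(w) + 0.5) * s
    ys = (np.arange(h) + 0.5) * s
    xx, yy = np.meshgrid(xs, ys)
    inside = contains_xy(roi, xx.ravel(), yy.ravel()).reshape(shape)
    # contains_xy is strict interior; include the boundary to match the
    # instance-centroid rule
    boundary = contains_xy(roi.boundary.buffer(1e-9), xx.ravel(), yy.ravel()).reshape(shape)
    return inside | boundary


def pixel_confusion(
    pred: LabelField, ref: LabelField, roi: Polygon | None = None
) -> PixelConfusion:
    """Pixel confusion counts between two masks of identical geometry."""
    if pred.labels.shape != ref.labels.shape:
        raise InputError(
            f"mask shapes differ: {pred.labels.shape} vs {ref.labels.shape}"
        )
    if pred.calib != ref.calib:
        raise InputError("masks carry different calibrations")
    p = pred.binary()
    g = ref.binary()
    if roi is not None:
        keep = _roi_mask(p.shape, roi, pred.calib.microns_per_pixel)
        p = p[keep]
        g = g[keep]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return PixelConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(conf: PixelConfusion) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN); undefined when all are zero."""
    denom = 2 * conf.tp + conf.fp + conf.fn
    if denom == 0:
        raise UndefinedMetricError("Dice is undefined: no foreground in either mask")
    return 2 * conf.tp / denom


def iou(conf: PixelConfusion) -> float:
    """Jaccard index TP / (TP + FP + FN); undefined when all are zero."""
    denom = conf.tp + conf.fp + conf.fn
    if denom == 0:
        raise UndefinedMetricError("IoU is undefined: no foreground in either mask")
    return conf.tp / denom


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion ``k/n``."""
    if n <= 0:
        raise InputError(f"trials must be positive, got n={n}")
    if not 0 <= k <= n:
        raise InputError(f"successes must lie in [0, n], got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    return (float(lo), float(hi))


def detection_summary(m: MatchResult, confidence: float = 0.95) -> DetectionSummary:
    """Precision/recall/F1 with Wilson intervals from a match result."""
    return summary_from_counts(m.tp, m.fp, m.fn, confidence)


def summary_from_counts(
    tp: int, fp: int, fn: int, confidence: float = 0.95
) -> DetectionSummary:
    if min(tp, fp, fn) < 0:
        raise InputError("detection counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    return DetectionSummary(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        wilson_precision=wilson_ci(tp, tp + fp, confidence) if tp + fp > 0 else None,
        wilson_recall=wilson_ci(tp, tp + fn, confidence) if tp + fn > 0 else None,
    )


def pooled_detection_summary(
    summaries: Sequence[DetectionSummary], confidence: float = 0.95
) -> DetectionSummary:
    """Pooled (summed-count) detection metrics across regions.

    Distinct from averaging per-region rates; both views are reported by the
    evaluation outputs and labelled accordingly.
    """
    tp = sum(s.tp for s in summaries)
    fp = sum(s.fp for s in summaries)
    fn = sum(s.fn for s in summaries)
    return summary_from_counts(tp, fp, fn, confidence)
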