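"""The fixed three-step post-processing procedure for predicted vessels.

Every evaluation applies the same sequence:

1. **ROI restriction** — predictions whose centroid falls outside a convex
   hull built around the annotation points (a "rubber band" proxy for the
   capsule-bounded nodal region) are removed.
2. **Minimum-area filter** — objects smaller than 6 µm² (by default) are
   discarded as staining noise.
3. **Centroid-distance NMS** — duplicate detections are suppressed: when two
   objects have centroid distance ≤ factor × min(equivalent radii), only the
   larger-area object is retained (default factor 0.7).

The pipeline never creates instances, each step's output is a subset of its
input, and the whole procedure is idempotent.  An audit trail records the
retained/removed count after each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon

from .errors import InputError
from .geometry import InstanceRecord, centroid_distance

#: Default minimum instance area (µm²); smaller objects are treated as noise.
DEFAULT_MIN_AREA_UM2 = 6.0
#: Default NMS distance factor applied to min(equivalent radii).
DEFAULT_NMS_FACTOR = 0.7


@dataclass(frozen=True)
class PostprocessConfig:
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    nms_factor: float = DEFAULT_NMS_FACTOR
    nms_mode: Literal["suppress", "union"] = "suppress"
    roi_rule: Literal["centroid"] = "centroid"

    def __post_init__(self) -> None:
        if not self.min_area_um2 > 0:
            raise InputError(f"min_area_um2 must be positive, got {self.min_area_um2}")
        if not 0 < self.nms_factor <= 1:
            raise InputError(f"nms_factor must lie in (0, 1], got {self.nms_factor}")
        if self.nms_mode not in ("suppress", "union"):
            raise InputError(f"unknown nms_mode {self.nms_mode!r}")


@dataclass
class PipelineAudit:
    """Per-step instance accounting of one pipeline run."""

    steps: list[dict] = field(default_factory=list)

    def record(self, step: str, retained: int, removed: int) -> None:
        self.steps.append({"step": step, "retained": retained, "removed": removed})

    def removed(self, step: str) -> int:
        for entry in self.steps:
            if entry["step"] == step:
                return entry["removed"]
        raise KeyError(step)


def convex_hull_roi(points: np.ndarray | Sequence[Sequence[float]]) -> Polygon:
    """Convex hull ("rubber band") around annotation points, as a proxy ROI.

    Fewer than 3 points, or all-collinear points, give a degenerate hull and
    are rejected: a zero-area ROI would silently empty every count.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"annotation points must be (n, 2), got shape {pts.shape}")
    if len(pts) < 3:
        raise InputError(f"convex-hull ROI needs ≥ 3 points, got {len(pts)}")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise InputError(
            "annotation points are collinear; the convex hull is degenerate"
        )
    return hull


def restrict_to_roi(
    instances: Sequence[InstanceRecord], roi: Polygon
) -> list[InstanceRecord]:
    """Keep instances whose centroid lies inside or on the ROI boundary."""
    return [r for r in instances if roi.covers(Point(r.centroid_x_um, r.centroid_y_um))]


def fraction_outside_roi(instances: Sequence[InstanceRecord], roi: Polygon) -> float:
    """Fraction of instances with centroid outside the ROI (NaN if empty)."""
    if not instances:
        return float("nan")
    inside = len(restrict_to_roi(instances, roi))
    return 1.0 - inside / len(instances)


def filter_min_area(
    instances: Sequence[InstanceRecord], min_area_um2: float
) -> list[InstanceRecord]:
    """Remove objects *smaller than* the area threshold (strict inequality)."""
    if not min_area_um2 > 0:
        raise InputError(f"min_area_um2 must be positive, got {min_area_um2}")
    return [r for r in instances if r.area_um2 >= min_area_um2]


def _nms_order(instances: Sequence[InstanceRecord]) -> list[InstanceRecord]:
    # descending area; ties broken by ascending id for determinism
    return sorted(instances, key=lambda r: (-r.area_um2, r.id))


def nms_merge(
    instances: Sequence[InstanceRecord],
    factor: float = DEFAULT_NMS_FACTOR,
    mode: Literal["suppress", "union"] = "suppress",
) -> list[InstanceRecord]:
    """Centroid-distance non-maximum suppression of duplicate detections.

    Two objects conflict when their centroid distance is ≤
    ``factor × min(r_i, r_j)`` with ``r`` the equivalent radius.  Objects are
    visited greedily in order of descending area; an object within the gate
    of an already-retained object is suppressed.  A single greedy pass is a
    fixed point: no two retained objects conflict, so reapplication changes
    nothing.

    ``mode='suppress'`` keeps the larger object's geometry unchanged.
    ``mode='union'`` additionally folds each suppressed object into its
    suppressor: areas are summed and the centroid becomes the area-weighted
    mean, approximating a union of the duplicate detections at the record
    level (the retained object's perimeter is kept as-is).
    """
    if not factor > 0:
        raise InputError(f"NMS factor must be positive, got {factor}")
    kept: list[InstanceRecord] = []
    absorbed: dict[int, list[InstanceRecord]] = {}
    for cand in _nms_order(instances):
        suppressor = None
        for k in kept:
            if centroid_distance(cand, k) <= factor * min(
                cand.eq_radius_um, k.eq_radius_um
            ):
                suppressor = k
                break
        if suppressor is None:
            kept.append(cand)
        elif mode == "union":
            absorbed.setdefault(suppressor.id, []).append(cand)
    if mode == "union" and absorbed:
        merged: list[InstanceRecord] = []
        for k in kept:
            cluster = [k] + absorbed.get(k.id, [])
            if len(cluster) == 1:
                merged.append(k)
                continue
            total = sum(c.area_um2 for c in cluster)
            cx = sum(c.centroid_x_um * c.area_um2 for c in cluster) / total
            cy = sum(c.centroid_y_um * c.area_um2 for c in cluster) / total
            merged.append(
                replace(
                    k,
                    centroid_x_um=cx,
                    centroid_y_um=cy,
                    area_um2=total,
                    eq_radius_um=None,
                    area_px=sum(c.area_px for c in cluster),
                )
            )
        kept = merged
    # restore input order among the kept ids for stable downstream output
    kept_ids = {r.id: r for r in kept}
    return [kept_ids[r.id] for r in instances if r.id in kept_ids]


def apply_fixed_pipeline(
    instances: Sequence[InstanceRecord],
    roi_points: np.ndarray | Sequence[Sequence[float]] | None,
    config: PostprocessConfig = PostprocessConfig(),
    roi: Polygon | None = None,
) -> tuple[list[InstanceRecord], PipelineAudit]:
    """Run the fixed ROI → min-area → NMS sequence with an audit trail.

    The ROI is either given directly (``roi``) or built as the convex hull of
    ``roi_points``; passing neither skips Step 1 (recorded in the audit with
    zero removals).
    """
    audit = PipelineAudit()
    current = list(instances)

    if roi is None and roi_points is not None:
        roi = convex_hull_roi(roi_points)
    if roi is not None:
        kept = restrict_to_roi(current, roi)
        audit.record("roi", len(kept), len(current) - len(kept))
        current = kept
    else:
        audit.record("roi", len(current), 0)

    kept = filter_min_area(current, config.min_area_um2)
    audit.record("min_area", len(kept), len(current) - len(kept))
    current = kept

    kept = nms_merge(current, config.nms_factor, config.nms_mode)
    audit.record("nms", len(kept), len(current) - len(kept))
    return kept, audit
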