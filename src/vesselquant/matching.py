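"""One-to-one matching of predicted and reference vessel instances.

A predicted object ``p`` and a reference object ``g`` may be paired only if
their geometry agrees.  The default (geometric) gate requires, simultaneously
and with strict inequalities,

* centroid proximity: ``d(p, g) < alpha * min(r_p, r_g)``, where ``r`` is the
  equivalent radius, and
* area agreement: ``|A_p - A_g| / A_g < tau`` (reference area in the
  denominator).

An alternative gate accepts a pair when the intersection-over-union of the
two *equivalent circles* reaches a threshold (default 0.50), the usual
Dice/Jaccard-style criterion.

Among all admissible pairs, a globally optimal one-to-one assignment is
computed with the Hungarian algorithm: the number of matched pairs is
maximized first, and among maximum-cardinality assignments the total centroid
distance is minimal.  Unmatched predictions are false positives; unmatched
references are false negatives.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InputError
from .geometry import InstanceRecord, centroid_distance, circle_iou


@dataclass(frozen=True)
class MatchCriteria:
    """Admissibility gates for pairing predicted and reference instances.

    alpha : centroid-gate multiplier on min(equivalent radii) (default 1.0)
    tau : maximum relative area difference vs the reference area (default 0.30)
    mode : 'geometric' (centroid + area gates) or 'circle_iou'
    iou_threshold : equivalent-circle IoU cut-off for 'circle_iou' mode
    iou_comparator : 'ge' (default) or 'gt' — whether the IoU threshold
        itself is admissible
    """

    alpha: float = 1.0
    tau: float = 0.30
    mode: Literal["geometric", "circle_iou"] = "geometric"
    iou_threshold: float = 0.50
    iou_comparator: Literal["ge", "gt"] = "ge"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InputError(f"alpha must be positive, got {self.alpha}")
        if not self.tau > 0:
            raise InputError(f"tau must be positive, got {self.tau}")
        if not 0 < self.iou_threshold <= 1:
            raise InputError(f"iou_threshold must lie in (0, 1], got {self.iou_threshold}")
        if self.mode not in ("geometric", "circle_iou"):
            raise InputError(f"unknown matching mode {self.mode!r}")


@dataclass
class MatchedPair:
    pred_id: int
    ref_id: int
    distance_um: float
    rel_area_diff: float


@dataclass
class MatchResult:
    """Outcome of one-to-one instance matching."""

    pairs: list[MatchedPair] = field(default_factory=list)
    false_positives: list[int] = field(default_factory=list)
    false_negatives: list[int] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


def gate_pair(p: InstanceRecord, g: InstanceRecord, c: MatchCriteria) -> bool:
    """True iff (p, g) is an admissible pair under the criteria."""
    d = centroid_distance(p, g)
    if c.mode == "geometric":
        if g.area_um2 <= 0:
            raise InputError("reference area must be positive")
        if not d < c.alpha * min(p.eq_radius_um, g.eq_radius_um):
            return False
        return abs(p.area_um2 - g.area_um2) / g.area_um2 < c.tau
    cmp: Callable[[float, float], bool] = (
        operator.ge if c.iou_comparator == "ge" else operator.gt
    )
    return cmp(circle_iou(p.eq_radius_um, g.eq_radius_um, d), c.iou_threshold)


def build_cost_matrix(
    preds: Sequence[InstanceRecord],
    refs: Sequence[InstanceRecord],
    c: MatchCriteria,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise centroid distances and admissibility flags.

    Returns ``(cost, admissible)`` of shape (n_preds, n_refs); ``cost`` holds
    the centroid distance for every cell, ``admissible`` marks cells that the
    gates allow.
    """
    cost = np.zeros((len(preds), len(refs)))
    admissible = np.zeros((len(preds), len(refs)), dtype=bool)
    for i, p in enumerate(preds):
        for j, g in enumerate(refs):
            cost[i, j] = centroid_distance(p, g)
            admissible[i, j] = gate_pair(p, g, c)
    return cost, admissible


def hungarian_assign(
    cost: np.ndarray, admissible: np.ndarray
) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-cost one-to-one assignment.

    Forbidden cells are excluded by giving them a sentinel cost that strictly
    dominates any feasible total, so the solver first maximizes the number of
    admissible pairs and, among those, minimizes the summed cost; sentinel
    pairs are discarded from the returned assignment.
    """
    cost = np.asarray(cost, dtype=float)
    admissible = np.asarray(admissible, dtype=bool)
    if cost.shape != admissible.shape:
        raise InputError("cost and admissibility tables must share a shape")
    if cost.size == 0 or not admissible.any():
        return []
    sentinel = cost[admissible].sum() + 1.0
    work = np.where(admissible, cost, sentinel)
    rows, cols = linear_sum_assignment(work)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if admissible[i, j]]


def match_instances(
    preds: Sequence[InstanceRecord],
    refs: Sequence[InstanceRecord],
    c: MatchCriteria = MatchCriteria(),
) -> MatchResult:
    """Match predictions to references one-to-one under the gating criteria."""
    cost, admissible = build_cost_matrix(preds, refs, c)
    assignment = hungarian_assign(cost, admissible)
    # deterministic output order regardless of solver internals
    assignment.sort()
    pairs = [
        MatchedPair(
            pred_id=preds[i].id,
            ref_id=refs[j].id,
            distance_um=float(cost[i, j]),
            rel_area_diff=abs(preds[i].area_um2 - refs[j].area_um2) / refs[j].area_um2,
        )
        for i, j in assignment
    ]
    matched_p = {i for i, _ in assignment}
    matched_g = {j for _, j in assignment}
    return MatchResult(
        pairs=pairs,
        false_positives=[p.id for k, p in enumerate(preds) if k not in matched_p],
        false_negatives=[g.id for k, g in enumerate(refs) if k not in matched_g],
    )
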