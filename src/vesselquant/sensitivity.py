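"""One-at-a-time parameter sweeps and repeated-measures statistics.

Three post-processing / matching parameters are varied systematically while
the others stay at their base values:

* matching centroid-gate multiplier ``alpha`` (default grid 0.1–1.0, step 0.1),
* minimum-area threshold (default 2–8 µm², step 1),
* NMS distance factor (default 0.3–0.7, step 0.1).

For every (ROI, parameter value) the full fixed pipeline, matching and
detection metrics are recomputed.  ROIs are treated as repeated-measure
blocks: global differences across parameter values (or model variants) are
tested with the Friedman test, pairwise contrasts with the Wilcoxon
signed-rank test plus Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .geometry import InstanceRecord
from .matching import MatchCriteria, match_instances
from .metrics import detection_summary
from .postprocess import PostprocessConfig, apply_fixed_pipeline


def _grid(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


@dataclass(frozen=True)
class SweepGrid:
    alpha_values: tuple[float, ...] = tuple(_grid(0.1, 1.0, 0.1))
    min_area_values: tuple[float, ...] = tuple(_grid(2.0, 8.0, 1.0))
    nms_values: tuple[float, ...] = tuple(_grid(0.3, 0.7, 0.1))

    def __post_init__(self) -> None:
        for name in ("alpha_values", "min_area_values", "nms_values"):
            vals = getattr(self, name)
            if not vals:
                raise InputError(f"{name} must be non-empty")
            if any(v <= 0 for v in vals):
                raise InputError(f"{name} must be positive")


@dataclass
class RoiData:
    """Per-ROI evaluation inputs: raw predictions, references, ROI points."""

    roi_id: str
    preds: Sequence[InstanceRecord]
    refs: Sequence[InstanceRecord]
    roi_points: Optional[np.ndarray] = None


def _evaluate_once(
    roi: RoiData, post: PostprocessConfig, crit: MatchCriteria
) -> dict:
    processed, _ = apply_fixed_pipeline(roi.preds, roi.roi_points, post)
    result = match_instances(processed, list(roi.refs), crit)
    summary = detection_summary(result)
    pred_count = len(processed)
    gt_count = len(roi.refs)
    return {
        "roi_id": roi.roi_id,
        "tp": summary.tp,
        "fp": summary.fp,
        "fn": summary.fn,
        "precision": summary.precision,
        "recall": summary.recall,
        "f1": summary.f1,
        "pred_count": pred_count,
        "gt_count": gt_count,
        "abs_count_error": abs(pred_count - gt_count),
    }


def run_sweep(
    rois: Sequence[RoiData],
    grid: SweepGrid = SweepGrid(),
    base_post: PostprocessConfig = PostprocessConfig(),
    base_criteria: MatchCriteria = MatchCriteria(),
) -> pd.DataFrame:
    """One-at-a-time sweep over alpha, min-area and NMS factor.

    Returns a long-format table with one row per (ROI, parameter, value);
    ``abs_count_error`` is the per-ROI |Pred − GT| whose mean over ROIs is
    the MAE for that parameter value.
    """
    if not rois:
        raise InputError("no ROIs supplied")
    rows = []
    for a in grid.alpha_values:
        crit = dc_replace(base_criteria, alpha=a)
        for roi in rois:
            rows.append({"parameter": "alpha", "value": a, **_evaluate_once(roi, base_post, crit)})
    for m in grid.min_area_values:
        post = dc_replace(base_post, min_area_um2=m)
        for roi in rois:
            rows.append({"parameter": "min_area", "value": m, **_evaluate_once(roi, post, base_criteria)})
    for f in grid.nms_values:
        post = dc_replace(base_post, nms_factor=f)
        for roi in rois:
            rows.append({"parameter": "nms", "value": f, **_evaluate_once(roi, post, base_criteria)})
    return pd.DataFrame(rows)


def select_min_area(sweep: pd.DataFrame) -> float:
    """Recommended minimum-area threshold from a sweep table.

    Picks the value minimizing mean |Pred − GT| across ROIs; ties are broken
    by higher mean F1, then by the smaller threshold.
    """
    sub = sweep[sweep["parameter"] == "min_area"]
    if sub.empty:
        raise InputError("sweep contains no min-area rows")
    agg = (
        sub.groupby("value")
        .agg(mae=("abs_count_error", "mean"), f1=("f1", "mean"))
        .reset_index()
    )
    agg = agg.sort_values(["mae", "f1", "value"], ascending=[True, False, True])
    return float(agg.iloc[0]["value"])


def friedman_test(table: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a blocks × treatments table.

    Rank-based chi-square statistic with average ranks for ties; the p-value
    comes from the chi-square distribution with (k − 1) degrees of freedom.
    A table whose blocks are all internally tied carries no ordering
    information: statistic 0, p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InputError("Friedman test needs a (≥2 blocks) × (≥2 treatments) table")
    if not np.all(np.isfinite(table)):
        raise InputError("Friedman test does not accept missing cells")
    if np.all(table == table[:, [0]]):
        return 0.0, 1.0
    n, k = table.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, table)  # average ranks for ties
    col_sums = ranks.sum(axis=0)
    # tie-corrected chi-square form (reduces to the classic statistic when
    # no ties are present)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    stat = numer / denom
    p = stats.chi2.sf(stat, k - 1)
    return float(stat), float(p)


@dataclass
class WilcoxonResult:
    statistic: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    n_effective: int
    method: str


def wilcoxon_bonferroni(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    m: Optional[int] = None,
) -> list[WilcoxonResult]:
    """Wilcoxon signed-rank tests with Bonferroni-adjusted p-values.

    Zero differences are dropped, ties are mid-ranked; the exact null
    distribution is used for n ≤ 25 (when no ties remain) and the normal
    approximation above.  ``m`` defaults to the number of comparisons.
    Adjusted p = min(1, m × raw p).  All-zero difference lists yield an
    undefined p rather than a number.
    """
    if m is None:
        m = len(pairs)
    if m < 1:
        raise InputError("number of comparisons must be ≥ 1")
    out: list[WilcoxonResult] = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.size == 0:
            raise InputError("paired lists must share a positive length")
        d = x - y
        n_eff = int(np.count_nonzero(d))
        if n_eff == 0:
            out.append(WilcoxonResult(None, None, None, 0, "undefined"))
            continue
        method = "exact" if n_eff <= 25 else "approx"
        res = stats.wilcoxon(x, y, zero_method="wilcox", method=method if method == "approx" else "auto")
        p = float(res.pvalue)
        out.append(
            WilcoxonResult(
                statistic=float(res.statistic),
                p_raw=p,
                p_adjusted=min(1.0, m * p),
                n_effective=n_eff,
                method=method,
            )
        )
    return out
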