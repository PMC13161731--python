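"""ROI-level count agreement between predicted and reference vessel counts.

Given one (predicted count, reference count) pair per region of interest,
computes:

* **bias** = Pred − GT per ROI, its mean, and the mean absolute error (MAE);
* **ICC(3,1)** — the two-way mixed, single-measure, *consistency*
  intraclass correlation between the two fixed "raters" (model vs reference);
* **Bland–Altman** limits of agreement, mean difference ± 1.96 × SD with the
  n−1 sample standard deviation and the literal 1.96 multiplier;
* **proportional bias** — ordinary least squares of the difference on the
  mean count, and on ROI area, with two-sided t-test p-values.  Single-
  covariate and joint fits are both exposed; with very few ROIs the joint
  fit has no residual degrees of freedom and its p-values are reported as
  undefined rather than invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InputError, UndefinedMetricError

#: literal Bland–Altman multiplier (not a t-quantile)
BA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class CountRow:
    roi_id: str
    pred_count: int
    gt_count: int
    roi_area_um2: float = float("nan")

    def __post_init__(self) -> None:
        if self.pred_count < 0 or self.gt_count < 0:
            raise InputError("counts must be non-negative")


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class RegressionSlope:
    slope: float
    p_value: Optional[float]
    significant: Optional[bool]


@dataclass
class AgreementReport:
    per_roi_bias: dict[str, int]
    mean_bias: float
    mae: float
    icc_3_1: Optional[float]
    bland_altman: BlandAltman
    prop_bias_mean: RegressionSlope
    prop_bias_area: RegressionSlope
    prop_bias_joint_mean: Optional[RegressionSlope]
    prop_bias_joint_area: Optional[RegressionSlope]

    def to_dict(self) -> dict:
        def _slope(s: Optional[RegressionSlope]) -> Optional[dict]:
            if s is None:
                return None
            return {"slope": s.slope, "p": s.p_value, "significant": s.significant}

        return {
            "per_roi_bias": self.per_roi_bias,
            "mean_bias": self.mean_bias,
            "mae": self.mae,
            "icc_3_1": self.icc_3_1,
            "icc_form": "two-way mixed, single measure, consistency (Shrout-Fleiss 3,1)",
            "bland_altman": {
                "mean_diff": self.bland_altman.mean_diff,
                "sd_diff": self.bland_altman.sd_diff,
                "loa_low": self.bland_altman.loa_low,
                "loa_high": self.bland_altman.loa_high,
                "multiplier": BA_MULTIPLIER,
            },
            "proportional_bias": {
                "mean_count": _slope(self.prop_bias_mean),
                "roi_area": _slope(self.prop_bias_area),
                "joint_mean_count": _slope(self.prop_bias_joint_mean),
                "joint_roi_area": _slope(self.prop_bias_joint_area),
            },
        }


def bias_mae(table: Sequence[CountRow]) -> tuple[list[int], float, float]:
    """Per-ROI bias (Pred − GT), mean bias, and mean absolute error."""
    if not table:
        raise InputError("count table is empty")
    biases = [r.pred_count - r.gt_count for r in table]
    mean_bias = float(np.mean(biases))
    mae = float(np.mean(np.abs(biases)))
    return biases, mean_bias, mae


def icc_3_1(table: Sequence[CountRow]) -> float:
    """ICC(3,1): two-way mixed, single-measure, consistency coefficient.

    Computed from the two-way ANOVA mean squares with k = 2 raters:
    ``(BMS − EMS) / (BMS + (k−1)·EMS)`` where BMS is the between-target
    (ROI) mean square and EMS the residual mean square.  Invariant under
    adding a constant to either rater and under common positive rescaling.
    """
    if len(table) < 2:
        raise InputError("ICC needs at least 2 ROIs")
    data = np.array([[r.pred_count, r.gt_count] for r in table], dtype=float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems == 0:
        raise UndefinedMetricError("ICC undefined: no between-ROI variance")
    return float((bms - ems) / (bms + (k - 1) * ems))


def bland_altman(table: Sequence[CountRow]) -> BlandAltman:
    """Limits of agreement for the paired differences Pred − GT."""
    if len(table) < 2:
        raise InputError("Bland-Altman needs at least 2 ROIs")
    diffs = np.array([r.pred_count - r.gt_count for r in table], dtype=float)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - BA_MULTIPLIER * sd,
        loa_high=mean + BA_MULTIPLIER * sd,
    )


def bland_altman_from_differences(diffs: Sequence[float]) -> BlandAltman:
    """Limits of agreement directly from paired differences (any units)."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise InputError("Bland-Altman needs at least 2 differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - BA_MULTIPLIER * sd,
        loa_high=mean + BA_MULTIPLIER * sd,
    )


def _ols_slopes(
    y: np.ndarray, X: pd.DataFrame, alpha: float = 0.05
) -> dict[str, RegressionSlope]:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    out = {}
    for name in X.columns:
        p = float(model.pvalues[name])
        if model.df_resid <= 0 or not math.isfinite(p):
            p_val, sig = None, None
        else:
            p_val, sig = p, bool(p < alpha)
        out[name] = RegressionSlope(
            slope=float(model.params[name]), p_value=p_val, significant=sig
        )
    return out


def proportional_bias(
    table: Sequence[CountRow], alpha: float = 0.05
) -> tuple[RegressionSlope, RegressionSlope, Optional[RegressionSlope], Optional[RegressionSlope]]:
    """Regression of the count difference on the mean count and ROI area.

    Returns (slope on mean count, slope on ROI area, joint-fit slope on mean
    count, joint-fit slope on ROI area).  Joint slopes are ``None`` when the
    joint model cannot be fit (too few ROIs).
    """
    if len(table) < 3:
        raise InputError("proportional-bias regression needs at least 3 ROIs")
    diff = np.array([r.pred_count - r.gt_count for r in table], dtype=float)
    mean_count = np.array(
        [(r.pred_count + r.gt_count) / 2.0 for r in table], dtype=float
    )
    area = np.array([r.roi_area_um2 for r in table], dtype=float)
    have_area = np.all(np.isfinite(area))

    s_mean = _ols_slopes(diff, pd.DataFrame({"mean_count": mean_count}), alpha)["mean_count"]
    if have_area:
        s_area = _ols_slopes(diff, pd.DataFrame({"roi_area": area}), alpha)["roi_area"]
    else:
        s_area = RegressionSlope(slope=float("nan"), p_value=None, significant=None)

    joint_mean = joint_area = None
    if have_area and len(table) >= 3:
        joint = _ols_slopes(
            diff, pd.DataFrame({"mean_count": mean_count, "roi_area": area}), alpha
        )
        joint_mean, joint_area = joint["mean_count"], joint["roi_area"]
    return s_mean, s_area, joint_mean, joint_area


def agreement_report(table: Sequence[CountRow], alpha: float = 0.05) -> AgreementReport:
    """Full count-agreement analysis of a per-ROI count table."""
    biases, mean_bias, mae = bias_mae(table)
    try:
        icc = icc_3_1(table)
    except (InputError, UndefinedMetricError):
        icc = None
    ba = bland_altman(table)
    try:
        s_mean, s_area, j_mean, j_area = proportional_bias(table, alpha)
    except InputError:
        nan_slope = RegressionSlope(float("nan"), None, None)
        s_mean = s_area = nan_slope
        j_mean = j_area = None
    return AgreementReport(
        per_roi_bias={r.roi_id: b for r, b in zip(table, biases)},
        mean_bias=mean_bias,
        mae=mae,
        icc_3_1=icc,
        bland_altman=ba,
        prop_bias_mean=s_mean,
        prop_bias_area=s_area,
        prop_bias_joint_mean=j_mean,
        prop_bias_joint_area=j_area,
    )


def read_counts_csv(path) -> list[CountRow]:
    """Read a per-ROI count table (roi_id, pred_count, gt_count[, roi_area_um2])."""
    df = pd.read_csv(path)
    required = {"roi_id", "pred_count", "gt_count"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            CountRow(
                roi_id=str(rec.roi_id),
                pred_count=int(rec.pred_count),
                gt_count=int(rec.gt_count),
                roi_area_um2=float(getattr(rec, "roi_area_um2", float("nan"))),
            )
        )
    return rows
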