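"""Descriptive region statistics, colocalization and simple regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterLabeling
from .features import FeatureTable

__all__ = [
    "RegionSummary",
    "ColocResult",
    "RegressionResult",
    "region_summary",
    "pearson_coloc",
    "linear_fit",
]


@dataclass
class RegionSummary:
    """Per-region feature means/sds/counts and fold changes vs control.

    ``table`` is indexed by (region, feature) with columns mean, sd, n,
    fold_change.  Regions: control, ipsilateral (the whole test table, as
    a conventional whole-ROI analysis would use), distal, proximal, focal.
    """

    table: pd.DataFrame

    def fold_change(self, region: str, feature: str) -> float:
        return float(self.table.loc[(region, feature), "fold_change"])

    def n(self, region: str) -> int:
        sub = self.table.xs(region, level="region")
        return int(sub["n"].iloc[0]) if len(sub) else 0


def region_summary(
    test_table: FeatureTable,
    labeling: ClusterLabeling,
    control_table: FeatureTable,
) -> RegionSummary:
    """Summarise each feature per region and relative to control.

    Empty regions keep their rows with n = 0 and NaN means.  Region counts
    partition the test table: every test window contributes to exactly one
    of distal/proximal/focal (and also to the pooled "ipsilateral" row).
    """
    feats = test_table.feature_columns
    merged = test_table.data.merge(
        labeling.labels[["section_id", "x_um", "y_um", "region"]],
        on=["section_id", "x_um", "y_um"],
        how="left",
    )
    if merged["region"].isna().any():
        raise ValueError("labeling does not cover the test table")
    ctrl_mean = control_table.data[feats].mean()
    rows = []

    def add(region: str, sub: pd.DataFrame):
        for f in feats:
            vals = sub[f].astype(float)
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            fold = mean / ctrl_mean[f] if n and ctrl_mean[f] != 0 else np.nan
            rows.append({
                "region": region, "feature": f, "mean": mean,
                "sd": float(vals.std(ddof=1)) if n > 1 else np.nan,
                "n": n, "fold_change": fold,
            })

    add("control", control_table.data)
    add("ipsilateral", merged)
    for region in ("distal", "proximal", "focal"):
        add(region, merged[merged["region"] == region])
    table = pd.DataFrame(rows).set_index(["region", "feature"])
    # fold changes are relative to the control mean; control row is 1 by
    # construction
    return RegionSummary(table)


@dataclass(frozen=True)
class ColocResult:
    """Pearson pixel colocalization of two channels inside an ROI."""

    R: float
    n_pixels: int
    roi: str = ""


def pearson_coloc(plane_a, plane_b, roi_mask=None, roi_label: str = "") -> ColocResult:
    """Pearson correlation of paired pixel intensities inside a mask.

    Symmetric in its channels; raises on constant input (R undefined).
    """
    a = np.asarray(plane_a.pixels if hasattr(plane_a, "pixels") else plane_a, dtype=float)
    b = np.asarray(plane_b.pixels if hasattr(plane_b, "pixels") else plane_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if roi_mask is None:
        va, vb = a.ravel(), b.ravel()
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if not roi_mask.any():
            raise ValueError("ROI is empty")
        va, vb = a[roi_mask], b[roi_mask]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant channel: Pearson R undefined")
    r = float(stats.pearsonr(va, vb).statistic)
    return ColocResult(R=r, n_pixels=int(va.size), roi=roi_label)


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares y = slope·x + intercept with R²."""

    slope: float
    intercept: float
    r_squared: float


def linear_fit(x, y) -> RegressionResult:
    """OLS fit; used for cluster-size correlations and count validation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance x")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
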