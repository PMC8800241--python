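"""Spatial clustering of outlier windows into proximal and focal regions.

Flagged windows are clustered with DBSCAN on their centre coordinates
(neighbour radius = the window diagonal rounded up, 142 µm for a 100 µm
window).  Clustered outliers form *proximal* activation regions.  Within
the proximal windows of each section, the sorted integrated-density curve
is elbow-thresholded; windows above the elbow are re-clustered into
*focal* cores when the curve is steep enough.  Every remaining test window
is *distal*.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN

from .outliers import OutlierFlags

__all__ = [
    "ClusterParams",
    "ElbowResult",
    "ClusterFootprint",
    "ClusterLabeling",
    "default_eps",
    "cluster_proximal",
    "elbow_threshold",
    "cluster_focal",
    "assign_regions",
    "cluster_area_fraction",
    "cluster_overlap",
]


def default_eps(window_side: float) -> float:
    """DBSCAN neighbour radius: the window diagonal, rounded up to a whole
    µm (⌈side·√2⌉; 142 µm for the default 100 µm window)."""
    if not window_side > 0:
        raise ValueError("window side must be > 0")
    return float(math.ceil(window_side * math.sqrt(2.0)))


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: neighbour radius eps (µm) and minimum cluster
    size.  A core point needs >= min_size neighbours within eps, counting
    itself."""

    eps: float = 142.0
    min_size: int = 5

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be > 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass(frozen=True)
class ClusterFootprint:
    """One spatial cluster: member windows and their union polygon."""

    section_id: str
    region: str  # "proximal" | "focal"
    cluster_id: int
    indices: tuple[int, ...]  # row indices into the labeling frame
    polygon: object  # shapely geometry, union of member window squares

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)


@dataclass
class ClusterLabeling:
    """Per-window region assignment plus per-cluster footprints.

    labels: DataFrame (section_id, x_um, y_um, region, cluster_id) — one
    row per test window; region in {distal, proximal, focal}; cluster_id is
    -1 outside clusters.  Focal windows are a subset of proximal windows
    (they keep the focal label in ``labels`` but remain members of their
    proximal footprint).
    """

    labels: pd.DataFrame
    clusters: list[ClusterFootprint] = field(default_factory=list)
    window_side: float = 100.0

    def footprints(self, region: str) -> list[ClusterFootprint]:
        return [c for c in self.clusters if c.region == region]

    def region_union(self, region: str):
        polys = [c.polygon for c in self.footprints(region)]
        return unary_union(polys) if polys else None

    def total_area(self, region: str) -> float:
        u = self.region_union(region)
        return float(u.area) if u is not None else 0.0


def _window_boxes(xs: np.ndarray, ys: np.ndarray, side: float):
    h = side / 2.0
    return [box(x - h, y - h, x + h, y + h) for x, y in zip(xs, ys)]


def _dbscan_labels(xy: np.ndarray, params: ClusterParams) -> np.ndarray:
    if len(xy) == 0:
        return np.zeros(0, dtype=int)
    return DBSCAN(eps=params.eps, min_samples=params.min_size).fit(xy).labels_


def cluster_proximal(
    flags: OutlierFlags,
    params: ClusterParams | None = None,
    window_side: float = 100.0,
) -> ClusterLabeling:
    """DBSCAN the outlier windows of each section into proximal clusters.

    Noise windows (outliers that fail to cluster) stay distal.  Rows are
    processed in (section, y, x) order so border-point assignment is
    deterministic.  No outliers is a valid result with zero clusters.
    """
    params = params or ClusterParams(eps=default_eps(window_side), min_size=5)
    data = flags.data.sort_values(["section_id", "y_um", "x_um"], kind="mergesort")
    data = data.reset_index(drop=True)
    labels = data[["section_id", "x_um", "y_um"]].copy()
    labels["region"] = "distal"
    labels["cluster_id"] = -1
    clusters: list[ClusterFootprint] = []
    next_id = 0
    for section in sorted(data["section_id"].unique()):
        sel = (data["section_id"] == section) & data["is_outlier"]
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx) == 0:
            continue
        xy = data.loc[idx, ["x_um", "y_um"]].to_numpy(dtype=float)
        lab = _dbscan_labels(xy, params)
        for k in sorted(set(lab) - {-1}):
            members = idx[lab == k]
            labels.loc[members, "region"] = "proximal"
            labels.loc[members, "cluster_id"] = next_id
            poly = unary_union(
                _window_boxes(xy[lab == k, 0], xy[lab == k, 1], window_side)
            )
            clusters.append(
                ClusterFootprint(section, "proximal", next_id,
                                 tuple(int(i) for i in members), poly)
            )
            next_id += 1
    out = ClusterLabeling(labels=labels, clusters=clusters, window_side=window_side)
    out._flag_data = data  # retained for the focal stage
    return out


@dataclass(frozen=True)
class ElbowResult:
    """Outcome of the chord-distance elbow scan on a sorted value curve.

    threshold_value is the value at the modal elbow; max_perp_magnitude is
    max(|A1Bx|) of the full (first-iteration) curve — effectively the
    curve's maximal vertical deviation from its chord in z-score units;
    the focal stage runs only when that magnitude strictly exceeds the
    floor.
    """

    threshold_value: float
    max_perp_magnitude: float
    modal_index: int
    passes_floor: bool
    magnitude_floor: float = 0.5


def _elbow_scan(values: np.ndarray) -> tuple[int, float]:
    """Elbow of one curve: index and |A1Bx| of the farthest point from the
    first-to-last chord.

    The curve is (rank, z-value); because the rank axis dwarfs the value
    axis, the perpendicular magnitude is in effect the vertical deviation
    of the curve from its chord in z-score units, so the 0.5 floor reads
    "the sorted curve must bow away from linearity by more than half a
    z-score" — count-free and exactly zero for a linear ramp.
    """
    n = len(values)
    x = np.arange(n, dtype=float)
    y = values
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        d = np.abs(y - y[0])
    else:
        d = np.abs(chord[0] * (p0[1] - y) - chord[1] * (p0[0] - x)) / norm
    i = int(np.argmax(d))
    return i, float(d[i])


def elbow_threshold(values, magnitude_floor: float = 0.5) -> ElbowResult:
    """Modal elbow of the ascending integrated-density curve.

    The values are sorted ascending and the chord-perpendicular elbow is
    located; the scan is then repeated with the leading point removed each
    iteration (down to 3 remaining points), and the mode of the elbows'
    original positions is the threshold point.  Ties take the smaller
    threshold value (more inclusive focal set).  The floor test uses the
    first-iteration magnitude and is strict: a magnitude of exactly the
    floor does not pass.  Fewer than 3 values yields a no-elbow result.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) < 3:
        return ElbowResult(np.nan, 0.0, -1, False, magnitude_floor)
    votes: Counter[int] = Counter()
    full_mag = None
    for start in range(0, len(values) - 2):
        i, mag = _elbow_scan(values[start:])
        if full_mag is None:
            full_mag = mag
        votes[start + i] += 1
    best = max(votes, key=lambda k: (votes[k], -values[k]))
    return ElbowResult(
        threshold_value=float(values[best]),
        max_perp_magnitude=float(full_mag),
        modal_index=int(best),
        passes_floor=bool(full_mag > magnitude_floor),
        magnitude_floor=magnitude_floor,
    )


def cluster_focal(
    labeling: ClusterLabeling,
    focal_params: ClusterParams | None = None,
    magnitude_floor: float = 0.5,
    intensity_column: str = "IntDen_z",
) -> ClusterLabeling:
    """Derive focal sub-clusters inside proximal regions, per section.

    For each section the integrated-density z-scores of its proximal
    windows are elbow-thresholded; when the curve passes the magnitude
    floor, proximal windows strictly above the threshold are DBSCAN-ed
    (defaults: eps 142 µm, min size 5) into focal clusters.  Focal windows
    remain a subset of proximal windows; proximal clusters are unchanged.
    """
    focal_params = focal_params or ClusterParams(eps=142.0, min_size=5)
    data = getattr(labeling, "_flag_data", None)
    if data is None:
        raise ValueError("labeling lacks flag data; run cluster_proximal first")
    if intensity_column not in data.columns:
        raise ValueError(f"flag data lacks {intensity_column!r}")
    labels = labeling.labels
    clusters = list(labeling.clusters)
    next_id = 0
    elbows: dict[str, ElbowResult] = {}
    for section in sorted(data["section_id"].unique()):
        prox = np.flatnonzero(
            ((labels["section_id"] == section)
             & (labels["region"].isin(["proximal", "focal"]))).to_numpy()
        )
        vals = data.loc[prox, intensity_column].to_numpy(dtype=float)
        elbow = elbow_threshold(vals, magnitude_floor)
        elbows[section] = elbow
        if not elbow.passes_floor:
            continue
        above = prox[vals > elbow.threshold_value]
        if len(above) == 0:
            continue
        xy = data.loc[above, ["x_um", "y_um"]].to_numpy(dtype=float)
        lab = _dbscan_labels(xy, focal_params)
        for k in sorted(set(lab) - {-1}):
            members = above[lab == k]
            labels.loc[members, "region"] = "focal"
            poly = unary_union(
                _window_boxes(xy[lab == k, 0], xy[lab == k, 1], labeling.window_side)
            )
            clusters.append(
                ClusterFootprint(section, "focal", next_id,
                                 tuple(int(i) for i in members), poly)
            )
            next_id += 1
    out = ClusterLabeling(labels=labels, clusters=clusters,
                          window_side=labeling.window_side)
    out._flag_data = data
    out.elbows = elbows
    return out


def assign_regions(test_table_data: pd.DataFrame, labeling: ClusterLabeling) -> ClusterLabeling:
    """Complete the labelling: every test window gets exactly one region.

    Windows absent from the labelling frame (none, in the standard
    pipeline) default to distal; focal ⊂ proximal holds by construction.
    """
    merged = test_table_data[["section_id", "x_um", "y_um"]].merge(
        labeling.labels, on=["section_id", "x_um", "y_um"], how="left"
    )
    merged["region"] = merged["region"].fillna("distal")
    merged["cluster_id"] = merged["cluster_id"].fillna(-1).astype(int)
    out = ClusterLabeling(labels=merged, clusters=list(labeling.clusters),
                          window_side=labeling.window_side)
    out.elbows = getattr(labeling, "elbows", {})
    out._flag_data = getattr(labeling, "_flag_data", None)
    return out


def cluster_area_fraction(labeling: ClusterLabeling, tissue_area: float) -> dict[str, float]:
    """Per-region footprint area as a fraction of the tissue area.

    Footprints are unions of member window squares, so overlapping windows
    are counted once.
    """
    if not tissue_area > 0:
        raise ValueError("tissue_area must be > 0")
    return {
        region: labeling.total_area(region) / tissue_area
        for region in ("proximal", "focal")
    }


def cluster_overlap(label_a: ClusterLabeling, label_b: ClusterLabeling,
                    region: str = "proximal") -> tuple[float, float]:
    """Mutual footprint overlap between two labelings of the same section
    geometry (e.g. microglia vs astrocyte clusters).

    Returns (fraction of A's area inside B, fraction of B's area inside A);
    (0, 0) when either footprint is empty.
    """
    ua = label_a.region_union(region)
    ub = label_b.region_union(region)
    if ua is None or ub is None or ua.area == 0 or ub.area == 0:
        return 0.0, 0.0
    inter = ua.intersection(ub).area
    return float(inter / ua.area), float(inter / ub.area)
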