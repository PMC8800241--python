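"""Per-window morphometric feature tables.

One row per sliding window; the table CSV is the boundary between image
processing and the statistical pipeline, so feature tables produced by
other extraction front-ends can be dropped in as long as the column schema
matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .image import ImagePlane, ThresholdConfig, preprocess_plane, local_threshold
from .morphometry import segment_somata, skeleton_stats, fractal_dimension
from .windows import Window, WindowSpec, enumerate_windows, intensity_features
from skimage.measure import perimeter_crofton

__all__ = [
    "FeatureTable",
    "MICROGLIA_FEATURES",
    "ASTROCYTE_FEATURES",
    "FEATURE_SETS",
    "CSV_COLUMNS",
    "build_feature_table",
]

#: Index / metadata columns of every feature table.
META_COLUMNS = ["section_id", "group", "x_um", "y_um"]

#: All measured feature columns, in canonical CSV order.
ALL_FEATURES = [
    "Area", "Mean", "IntDen", "FracDim", "NumCells", "MeanNND",
    "MeanSomaArea", "MeanSomaCirc", "NumBranches", "BranchLength",
    "NumJunctions", "NumTriplePoints", "NumEndPoints", "NumSlabPixels",
    "Perimeter",
]

CSV_COLUMNS = META_COLUMNS + ALL_FEATURES

#: The 13 features of the microglia (IBA1) model.
MICROGLIA_FEATURES = [
    "Area", "Mean", "FracDim", "NumCells", "MeanNND", "MeanSomaArea",
    "MeanSomaCirc", "NumBranches", "BranchLength", "NumJunctions",
    "NumTriplePoints", "NumEndPoints", "Perimeter",
]

#: The 7 features of the astrocyte (GFAP) model; soma-channel features are
#: not part of this set.
ASTROCYTE_FEATURES = [
    "Area", "Mean", "NumJunctions", "NumEndPoints", "NumSlabPixels",
    "NumTriplePoints", "Perimeter",
]

FEATURE_SETS: Mapping[str, list[str]] = {
    "microglia": MICROGLIA_FEATURES,
    "astrocyte": ASTROCYTE_FEATURES,
}


@dataclass
class FeatureTable:
    """A per-window feature table plus its provenance.

    data
        DataFrame with META_COLUMNS plus feature columns; one row per
        window.  Unused columns of the astrocyte set are NaN.
    feature_set
        ``"microglia"`` (13 model features) or ``"astrocyte"`` (7).
    window_spec
        The sliding-window geometry the rows were extracted with.
    """

    data: pd.DataFrame
    feature_set: Literal["microglia", "astrocyte"] = "microglia"
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        missing = [c for c in META_COLUMNS + self.feature_columns
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        # canonical dtypes: coordinates and features are float64, so CSV
        # round-trips compare equal regardless of integral formatting
        num = [c for c in ["x_um", "y_um"] + ALL_FEATURES if c in self.data.columns]
        if any(self.data[c].dtype != np.float64 for c in num):
            self.data = self.data.copy()
            self.data[num] = self.data[num].astype(np.float64)

    @property
    def feature_columns(self) -> list[str]:
        return list(FEATURE_SETS[self.feature_set])

    @property
    def numeric_columns(self) -> list[str]:
        """All populated numeric feature columns (model features + IntDen)."""
        cols = [c for c in ALL_FEATURES if c in self.data.columns
                and not self.data[c].isna().all()]
        return cols

    def __len__(self) -> int:
        return len(self.data)

    def sections(self) -> list[str]:
        return sorted(self.data["section_id"].unique().tolist())

    def sorted(self) -> "FeatureTable":
        """Rows sorted by (section_id, y, x) — the canonical order used
        before model fitting so results do not depend on input order."""
        d = self.data.sort_values(["section_id", "y_um", "x_um"], kind="mergesort")
        return FeatureTable(d.reset_index(drop=True), self.feature_set, self.window_spec)


def _window_perimeter(mask_win: np.ndarray, scale: float) -> float:
    if not mask_win.any():
        return 0.0
    return float(perimeter_crofton(mask_win, directions=4)) / scale


def build_feature_table(
    planes: Mapping[str, ImagePlane],
    spec: WindowSpec | None = None,
    cfg: ThresholdConfig | None = None,
    feature_set: Literal["microglia", "astrocyte"] = "microglia",
    section_id: str = "S1",
    group: Literal["control", "test"] = "control",
    preprocessed: bool = False,
    include_soma: bool | None = None,
) -> FeatureTable:
    """Extract a full feature table from one section's channel planes.

    Parameters
    ----------
    planes
        For ``feature_set="microglia"``: ``{"IBA1": plane}`` (the same
        channel provides branching, intensity and soma measures).  For
        ``"astrocyte"``: ``{"GFAP": plane}`` and optionally
        ``{"S100B": plane}`` — branching and intensity come from GFAP; the
        S100B soma channel is only needed when soma features are requested
        (the 7-feature astrocyte model needs none).
    preprocessed
        Set True when planes already went through ``preprocess_plane``.
    include_soma
        Force soma segmentation on/off; defaults to True for microglia and
        to whether an S100B plane is present for astrocytes.

    Returns a table with one row per enumerated window; soma-derived
    features aggregate the somata whose centroid falls inside each window,
    and are 0 in windows without somata so every window stays classifiable.
    """
    spec = spec or WindowSpec()
    cfg = cfg or ThresholdConfig()
    if feature_set == "microglia":
        if "IBA1" not in planes:
            raise ValueError("microglia feature set requires an 'IBA1' plane")
        branch_plane = planes["IBA1"]
        soma_source = planes["IBA1"]
        soma_protocol = "microglia"
        if include_soma is None:
            include_soma = True
    elif feature_set == "astrocyte":
        if "GFAP" not in planes:
            raise ValueError("astrocyte feature set requires a 'GFAP' plane")
        branch_plane = planes["GFAP"]
        soma_source = planes.get("S100B")
        soma_protocol = "astrocyte"
        if include_soma is None:
            include_soma = soma_source is not None
        if include_soma and soma_source is None:
            raise ValueError("astrocyte soma features require an 'S100B' plane")
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")

    if not preprocessed:
        proto = "microglia" if feature_set == "microglia" else "astrocyte_branching"
        branch_proc = preprocess_plane(branch_plane, proto)
    else:
        branch_proc = branch_plane
    mask = local_threshold(branch_proc, cfg)
    windows = enumerate_windows(branch_proc, spec)
    diag = spec.side * np.sqrt(2.0)

    somata = []
    if include_soma and soma_source is not None:
        soma_proc = soma_source if preprocessed else preprocess_plane(soma_source, "soma")
        somata = segment_somata(soma_proc, soma_protocol, fallback_nnd=diag)
    soma_xy = np.array([s.centroid for s in somata]).reshape(-1, 2)

    rows = []
    scale = branch_proc.scale
    for win in windows:
        rs, cs = win.pixel_slice(scale)
        mask_win = mask[rs, cs]
        mean, intden, area = intensity_features(branch_proc, mask, win)
        skel = skeleton_stats(mask_win, scale)
        row = {
            "section_id": section_id,
            "group": group,
            "x_um": win.center[0],
            "y_um": win.center[1],
            "Area": area,
            "Mean": mean,
            "IntDen": intden,
            "FracDim": fractal_dimension(mask_win),
            "NumBranches": skel.n_branches,
            "BranchLength": skel.total_branch_length,
            "NumJunctions": skel.n_junctions,
            "NumTriplePoints": skel.n_triple_points,
            "NumEndPoints": skel.n_end_points,
            "NumSlabPixels": skel.n_slab_pixels,
            "Perimeter": _window_perimeter(mask_win, scale),
        }
        if include_soma:
            inside = (
                (soma_xy[:, 0] >= win.x0) & (soma_xy[:, 0] < win.x0 + win.side)
                & (soma_xy[:, 1] >= win.y0) & (soma_xy[:, 1] < win.y0 + win.side)
            ) if len(soma_xy) else np.zeros(0, dtype=bool)
            members = [s for s, keep in zip(somata, inside) if keep]
            row["NumCells"] = len(members)
            row["MeanNND"] = float(np.mean([s.nnd for s in members])) if members else 0.0
            row["MeanSomaArea"] = float(np.mean([s.area for s in members])) if members else 0.0
            row["MeanSomaCirc"] = float(np.mean([s.circularity for s in members])) if members else 0.0
        else:
            row["NumCells"] = np.nan
            row["MeanNND"] = np.nan
            row["MeanSomaArea"] = np.nan
            row["MeanSomaCirc"] = np.nan
        rows.append(row)
    data = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return FeatureTable(data, feature_set=feature_set, window_spec=spec)
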