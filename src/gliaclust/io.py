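"""Readers and writers for the pipeline's on-disk formats.

TIFF planes in, CSV feature tables and labels out, GeoJSON for cluster
footprints and tissue ROIs, JSON for fitted models and run logs.  Feature
CSVs round-trip bit-identically (floats at full precision) and are the
module boundary: tables produced by other extraction front-ends can be
dropped in as long as the columns match.
"""

from __future__ import annotations

import json
import platform
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .clustering import ClusterLabeling
from .features import CSV_COLUMNS, FeatureTable
from .image import ImagePlane
from .pipeline import PipelineModel
from .windows import WindowSpec

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_feature_csv",
    "write_feature_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_geojson",
    "read_roi_geojson",
    "save_model",
    "load_model",
    "read_config",
    "write_run_log",
]

LABEL_COLUMNS = ["section_id", "x_um", "y_um", "region", "cluster_id"]


def read_tiff(path, scale: float = 1.5, channel: str = "",
              project: bool = True) -> ImagePlane:
    """Read a grayscale TIFF (optionally a z-stack, max-projected)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if not project:
            raise ValueError(f"{path}: z-stack given with project=False")
        arr = arr.max(axis=0)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return ImagePlane(np.asarray(arr, dtype=np.float64), scale=scale, channel=channel)


def write_tiff(path, plane: ImagePlane) -> None:
    tifffile.imwrite(str(path), plane.pixels.astype(np.float32))


def write_feature_csv(path, table: FeatureTable) -> None:
    """Write a feature table with the canonical column order; floats use
    repr precision so read-back is bit-identical."""
    table.data[CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path, feature_set: str = "microglia",
                     window_spec: WindowSpec | None = None) -> FeatureTable:
    df = pd.read_csv(path)
    missing = [c for c in ("section_id", "group", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature CSV missing columns {missing}")
    for c in CSV_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return FeatureTable(df[CSV_COLUMNS], feature_set=feature_set,
                        window_spec=window_spec or WindowSpec())


def write_labels_csv(path, labeling: ClusterLabeling) -> None:
    labeling.labels[LABEL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: labels CSV missing columns {missing}")
    df = df[LABEL_COLUMNS].copy()
    df[["x_um", "y_um"]] = df[["x_um", "y_um"]].astype(np.float64)
    df["cluster_id"] = df["cluster_id"].astype(int)
    return df


def write_geojson(path, labeling: ClusterLabeling) -> None:
    """Cluster footprints as a GeoJSON FeatureCollection (µm coordinates)."""
    features = [
        {
            "type": "Feature",
            "properties": {
                "section_id": c.section_id,
                "region": c.region,
                "cluster_id": c.cluster_id,
                "area_um2": c.area_um2,
            },
            "geometry": mapping(c.polygon),
        }
        for c in labeling.clusters
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_roi_geojson(path):
    """Read a tissue-ROI polygon (first feature) from GeoJSON."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        feats = doc.get("features", [])
        if not feats:
            raise ValueError(f"{path}: empty FeatureCollection")
        return shape(feats[0]["geometry"])
    if doc.get("type") == "Feature":
        return shape(doc["geometry"])
    return shape(doc)


def save_model(path, model: PipelineModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path) -> PipelineModel:
    return PipelineModel.from_dict(json.loads(Path(path).read_text()))


def read_config(path) -> dict:
    """Read a YAML-or-JSON configuration mapping with validation."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")

    def check(name, pred, rule):
        if name not in cfg:
            return
        vals = cfg[name] if isinstance(cfg[name], (list, tuple)) else [cfg[name]]
        for v in vals:
            if not pred(v):
                raise ValueError(f"{path}: {name} must be {rule}, got {v}")

    check("nu", lambda v: 0 < v <= 1, "in (0, 1]")
    check("gamma", lambda v: v > 0, "> 0")
    check("min_size", lambda v: v >= 1, ">= 1")
    return cfg


def write_run_log(path, command: str, params: dict, seed: int | None = None) -> None:
    """Record command, parameters, seed and versions for reproducibility."""
    import sklearn
    import skimage

    log = {
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "params": params,
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    Path(path).write_text(json.dumps(log, indent=1))
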