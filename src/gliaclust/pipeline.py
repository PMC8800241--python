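"""End-to-end orchestration: control-fit models, test-set labelling.

The canonical chain is

    control table ──fit──> normalizer ──> PCA ──> one-class SVM
    test table  ──apply──> z-scores ──> PC scores ──> outlier flags
                 ──floor filter──> DBSCAN proximal ──> elbow ──> focal

wrapped here so the tuning loops, the CLI and the examples all run the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .clustering import (
    ClusterLabeling,
    ClusterParams,
    assign_regions,
    cluster_focal,
    cluster_proximal,
    default_eps,
)
from .features import FeatureTable
from .normalize import (
    NormalizationModel,
    ProjectionModel,
    apply_normalizer,
    apply_projection,
    fit_normalizer,
    fit_projection,
)
from .outliers import (
    OcsvmConfig,
    OutlierModel,
    fit_model,
    intensity_floor_filter,
    predict_outliers,
)

__all__ = ["PipelineModel", "fit_pipeline", "label_table"]


@dataclass
class PipelineModel:
    """The three control-fitted models plus the clustering configuration."""

    normalizer: NormalizationModel
    projection: ProjectionModel
    outlier_model: OutlierModel
    cluster_params: ClusterParams
    floor_z: float = -1.0
    window_side: float = 100.0
    focal_params: ClusterParams = field(
        default_factory=lambda: ClusterParams(eps=142.0, min_size=5)
    )
    magnitude_floor: float = 0.5

    def to_dict(self) -> dict:
        return {
            "normalizer": self.normalizer.to_dict(),
            "projection": self.projection.to_dict(),
            "outlier_model": self.outlier_model.to_dict(),
            "cluster_params": {"eps": self.cluster_params.eps,
                               "min_size": self.cluster_params.min_size},
            "floor_z": self.floor_z,
            "window_side": self.window_side,
            "focal_params": {"eps": self.focal_params.eps,
                             "min_size": self.focal_params.min_size},
            "magnitude_floor": self.magnitude_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineModel":
        return cls(
            normalizer=NormalizationModel.from_dict(d["normalizer"]),
            projection=ProjectionModel.from_dict(d["projection"]),
            outlier_model=OutlierModel.from_dict(d["outlier_model"]),
            cluster_params=ClusterParams(**d["cluster_params"]),
            floor_z=d["floor_z"],
            window_side=d["window_side"],
            focal_params=ClusterParams(**d["focal_params"]),
            magnitude_floor=d["magnitude_floor"],
        )


def fit_pipeline(
    control: FeatureTable,
    ocsvm: OcsvmConfig,
    min_size: int = 5,
    eps: float | None = None,
    variance_target: float = 0.99,
    floor_z: float = -1.0,
) -> PipelineModel:
    """Fit normalizer, PCA and one-class SVM on a control feature table."""
    control = control.sorted()
    norm = fit_normalizer(control)
    z = apply_normalizer(norm, control)
    feature_cols = [c for c in control.feature_columns if c in norm.feature_names]
    proj = fit_projection(z, feature_cols, variance_target)
    scores = apply_projection(proj, z)
    svm = fit_model(scores, ocsvm)
    side = control.window_spec.side
    params = ClusterParams(eps=eps if eps is not None else default_eps(side),
                           min_size=min_size)
    return PipelineModel(
        normalizer=norm,
        projection=proj,
        outlier_model=svm,
        cluster_params=params,
        floor_z=floor_z,
        window_side=side,
    )


def label_table(
    model: PipelineModel,
    table: FeatureTable,
    with_focal: bool = True,
) -> ClusterLabeling:
    """Apply a fitted pipeline to a feature table and label every window."""
    table = table.sorted()
    z = apply_normalizer(model.normalizer, table)
    scores = apply_projection(model.projection, z)
    flags = predict_outliers(model.outlier_model, scores)
    flags = intensity_floor_filter(flags, model.floor_z)
    labeling = cluster_proximal(flags, model.cluster_params, model.window_side)
    if with_focal:
        labeling = cluster_focal(labeling, model.focal_params,
                                 model.magnitude_floor)
    return assign_regions(table.data, labeling)
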