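"""Control-anchored normalisation and PCA projection.

Both models are fitted on control (non-activated) windows only and then
applied unchanged to test windows, so a test window's transform never
depends on other test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import FeatureTable

__all__ = [
    "NormalizationModel",
    "ProjectionModel",
    "fit_normalizer",
    "apply_normalizer",
    "fit_projection",
    "apply_projection",
]


@dataclass
class NormalizationModel:
    """Per-feature z-score statistics, fitted on training data.

    z = (x - mu) / s with s the unbiased (n-1) standard deviation.
    Zero-variance features are dropped at fit time with a warning.
    """

    mu: pd.Series
    s: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.mu.index)

    def to_dict(self) -> dict:
        return {"mu": self.mu.to_dict(), "s": self.s.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        return cls(mu=pd.Series(d["mu"]), s=pd.Series(d["s"]))


def fit_normalizer(train: FeatureTable, columns: list[str] | None = None) -> NormalizationModel:
    """Fit per-feature mean and sd on the training table.

    Statistics are computed over every populated numeric feature column
    (model features plus IntDen, which the focal threshold needs), or over
    ``columns`` when given.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    cols = columns if columns is not None else train.numeric_columns
    X = train.data[cols].astype(float)
    mu = X.mean(axis=0)
    s = X.std(axis=0, ddof=1)
    zero = s[s == 0].index.tolist()
    if zero:
        warnings.warn(f"dropping zero-variance features: {zero}")
        mu = mu.drop(zero)
        s = s.drop(zero)
    return NormalizationModel(mu=mu, s=s)


def apply_normalizer(model: NormalizationModel, table: FeatureTable) -> pd.DataFrame:
    """Z-score a table with training statistics.

    Returns a DataFrame of the metadata columns plus one z-scored column
    per feature retained by the model.
    """
    missing = [c for c in model.feature_names if c not in table.data.columns]
    if missing:
        raise ValueError(f"table missing features required by the model: {missing}")
    z = (table.data[model.feature_names].astype(float) - model.mu) / model.s
    out = table.data[["section_id", "group", "x_um", "y_um"]].copy()
    for c in model.feature_names:
        out[c] = z[c]
    return out


@dataclass
class ProjectionModel:
    """PCA loadings retaining a target fraction of training variance.

    ``n_retained`` is the minimal component count whose cumulative
    explained-variance fraction reaches ``variance_target``.  Loadings are
    orthonormal rows with the sign fixed so each component's
    largest-magnitude entry is positive (determinism).
    """

    loadings: np.ndarray
    variance_fractions: np.ndarray
    n_retained: int
    variance_target: float
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_retained": int(self.n_retained),
            "variance_target": float(self.variance_target),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_fractions=np.asarray(d["variance_fractions"], dtype=float),
            n_retained=int(d["n_retained"]),
            variance_target=float(d["variance_target"]),
            feature_names=list(d["feature_names"]),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_projection(
    train_z: pd.DataFrame,
    feature_names: list[str],
    variance_target: float = 0.99,
) -> ProjectionModel:
    """Fit PCA on z-scored training features; keep components until the
    cumulative explained variance reaches ``variance_target`` (weak
    inequality, minimal count)."""
    X = np.asarray(train_z[feature_names], dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a projection")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    n_ret = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_ret = min(n_ret, len(frac))
    return ProjectionModel(
        loadings=_fix_signs(pca.components_),
        variance_fractions=frac,
        n_retained=n_ret,
        variance_target=variance_target,
        feature_names=list(feature_names),
    )


def apply_projection(model: ProjectionModel, z_table: pd.DataFrame) -> pd.DataFrame:
    """Project z-scored rows onto the retained principal components.

    Returns metadata columns, the raw ``Mean`` and ``IntDen`` z-scores
    (needed downstream by the intensity floor and the focal threshold), and
    score columns ``PC1..PCk``.
    """
    missing = [c for c in model.feature_names if c not in z_table.columns]
    if missing:
        raise ValueError(f"z-table missing features: {missing}")
    X = np.asarray(z_table[model.feature_names], dtype=float)
    scores = X @ model.loadings.T
    out = z_table[["section_id", "group", "x_um", "y_um"]].copy()
    for carried in ("Mean", "IntDen"):
        if carried in z_table.columns:
            out[carried + "_z"] = z_table[carried]
    for i in range(model.n_retained):
        out[f"PC{i + 1}"] = scores[:, i]
    return out
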