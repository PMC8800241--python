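"""One-class SVM outlier detection over PC scores, with the intensity floor.

A ν-SVM with RBF kernel is trained on control windows only; test windows
with a negative decision value are morphological outliers.  Because an
outlier can be hypo- as well as hyper-intense (e.g. off-tissue or damaged
regions), putative outliers whose raw mean-intensity z-score is at or
below −1 are demoted before spatial clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

__all__ = [
    "OcsvmConfig",
    "OutlierModel",
    "OutlierFlags",
    "fit_model",
    "predict_outliers",
    "intensity_floor_filter",
]


@dataclass(frozen=True)
class OcsvmConfig:
    """ν-SVM hyperparameters.

    nu upper-bounds the fraction of training windows outside the decision
    boundary (and lower-bounds the support-vector fraction); gamma is the
    RBF kernel width.
    """

    nu: float = 0.1
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.nu <= 1.0:
            raise ValueError("nu must be in (0, 1]")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")


@dataclass
class OutlierModel:
    """A fitted one-class SVM in representation-agnostic form.

    Holds the support vectors, dual coefficients and offset of the fitted
    decision function f(x) = Σ αᵢ·exp(−γ‖x − svᵢ‖²) + ρ, evaluated
    directly so a model serialised to JSON reproduces decision values
    exactly.
    """

    config: OcsvmConfig
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    n_train: int
    score_columns: list[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sv = self.support_vectors
        d2 = ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.config.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "nu": self.config.nu,
            "gamma": self.config.gamma,
            "n_train": self.n_train,
            "score_columns": self.score_columns,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutlierModel":
        return cls(
            config=OcsvmConfig(nu=d["nu"], gamma=d["gamma"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            n_train=int(d["n_train"]),
            score_columns=list(d["score_columns"]),
        )


def _score_columns(scores: pd.DataFrame) -> list[str]:
    return [c for c in scores.columns if c.startswith("PC")]


def fit_model(train_scores: pd.DataFrame, cfg: OcsvmConfig) -> OutlierModel:
    """Fit a one-class SVM on control PC scores.

    Rows are sorted by (section_id, y, x) before fitting so the result is
    independent of input ordering.  Degenerate (all-identical) training
    sets are rejected.
    """
    cols = _score_columns(train_scores)
    if not cols:
        raise ValueError("train_scores has no PC columns")
    ordered = train_scores.sort_values(["section_id", "y_um", "x_um"], kind="mergesort")
    X = np.asarray(ordered[cols], dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training set: all rows identical")
    svm = OneClassSVM(kernel="rbf", nu=cfg.nu, gamma=cfg.gamma, tol=1e-4)
    svm.fit(X)
    return OutlierModel(
        config=cfg,
        support_vectors=np.asarray(svm.support_vectors_, dtype=float),
        dual_coef=np.asarray(svm.dual_coef_, dtype=float).ravel(),
        intercept=float(svm.intercept_[0]),
        n_train=X.shape[0],
        score_columns=cols,
    )


@dataclass
class OutlierFlags:
    """Per-window outlier verdicts.

    data carries section/coordinate metadata, the SVM decision value,
    the raw mean-intensity z-score, and the boolean ``is_outlier``.
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_outliers(self) -> int:
        return int(self.data["is_outlier"].sum())


def predict_outliers(model: OutlierModel, test_scores: pd.DataFrame) -> OutlierFlags:
    """Flag windows with a negative decision value as outliers.

    Ties (decision value exactly 0) count as inliers.  The test table's
    ``Mean_z`` column is carried through for the intensity floor.
    """
    cols = model.score_columns
    missing = [c for c in cols if c not in test_scores.columns]
    if missing:
        raise ValueError(f"test scores missing columns: {missing}")
    out = test_scores[[c for c in ("section_id", "group", "x_um", "y_um",
                                   "Mean_z", "IntDen_z") if c in test_scores.columns]].copy()
    if len(test_scores) == 0:
        out["decision_value"] = np.array([], dtype=float)
        out["is_outlier"] = np.array([], dtype=bool)
        return OutlierFlags(out)
    dv = model.decision_values(np.asarray(test_scores[cols], dtype=float))
    out["decision_value"] = dv
    out["is_outlier"] = dv < 0
    return OutlierFlags(out)


def intensity_floor_filter(flags: OutlierFlags, floor_z: float = -1.0) -> OutlierFlags:
    """Demote outliers whose raw mean-intensity z-score is ≤ floor_z.

    Only demotions happen: the filtered outlier set is a subset of the
    input outlier set.  ``floor_z = -inf`` is the identity.
    """
    data = flags.data.copy()
    if "Mean_z" not in data.columns:
        raise ValueError("flags lack the Mean_z column needed by the floor filter")
    data["is_outlier"] = data["is_outlier"] & (data["Mean_z"] > floor_z)
    return OutlierFlags(data)
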