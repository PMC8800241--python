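"""Two-stage hyperparameter search.

Stage 1 (feasibility): cross-validate over control sections and keep only
(nu, gamma, min_size) combinations that yield *zero* proximal clusters in
every held-out control section — the zero-false-positive constraint that
anchors specificity.  Stage 2 (selection): among feasible combinations,
train on all control data and pick the one that maximises the total
proximal cluster area in the test tissue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable
from .outliers import OcsvmConfig
from .pipeline import fit_pipeline, label_table

__all__ = [
    "ParameterGrid",
    "ComboResult",
    "TuningResult",
    "NoFeasibleParameters",
    "make_folds",
    "feasibility_scan",
    "select_params",
    "tune",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Grid-search ranges for nu, gamma and the DBSCAN minimum cluster
    size.  Defaults cover the plausible operating range at modest cost and
    are fully user-overridable."""

    nu: tuple[float, ...] = (0.02, 0.05, 0.1, 0.15, 0.2)
    gamma: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0)
    min_size: tuple[int, ...] = (5, 10, 15, 20, 30)

    def __post_init__(self) -> None:
        if not (self.nu and self.gamma and self.min_size):
            raise ValueError("all grid axes must be nonempty")
        for v in self.nu:
            if not 0 < v <= 1:
                raise ValueError("nu values must be in (0, 1]")
        for v in self.gamma:
            if not v > 0:
                raise ValueError("gamma values must be > 0")
        for v in self.min_size:
            if v < 1:
                raise ValueError("min_size values must be >= 1")

    def combinations(self) -> list[tuple[float, float, int]]:
        return list(itertools.product(self.nu, self.gamma, self.min_size))


@dataclass
class ComboResult:
    nu: float
    gamma: float
    min_size: int
    feasible: bool
    control_cluster_area: float = 0.0
    test_cluster_area: float | None = None


@dataclass
class TuningResult:
    combos: list[ComboResult] = field(default_factory=list)
    selected: tuple[float, float, int] | None = None

    @property
    def feasible_set(self) -> list[tuple[float, float, int]]:
        return [(c.nu, c.gamma, c.min_size) for c in self.combos if c.feasible]

    def combo(self, key: tuple[float, float, int]) -> ComboResult:
        for c in self.combos:
            if (c.nu, c.gamma, c.min_size) == key:
                return c
        raise KeyError(key)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected) if self.selected else None,
            "combinations": [
                {
                    "nu": c.nu, "gamma": c.gamma, "min_size": c.min_size,
                    "feasible": c.feasible,
                    "control_cluster_area": c.control_cluster_area,
                    "test_cluster_area": c.test_cluster_area,
                }
                for c in self.combos
            ],
        }


class NoFeasibleParameters(RuntimeError):
    """No grid combination met the zero-control-cluster constraint; widen
    the grid (larger min_size, smaller nu) and retry."""


def make_folds(control_sections: list[str], k: int = 10, seed: int = 0) -> list[list[str]]:
    """Partition sections into min(k, n) balanced folds with a seeded
    shuffle; with fewer sections than folds this degrades to
    leave-one-section-out."""
    sections = list(control_sections)
    if len(sections) < 2:
        raise ValueError("need at least 2 control sections to cross-validate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sections))
    n_folds = min(k, len(sections))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(sections[idx])
    return folds


def _subset(table: FeatureTable, sections: list[str]) -> FeatureTable:
    d = table.data[table.data["section_id"].isin(sections)].reset_index(drop=True)
    return FeatureTable(d, table.feature_set, table.window_spec)


def _proximal_area(control: FeatureTable, target: FeatureTable,
                   nu: float, gamma: float, min_size: int) -> float:
    model = fit_pipeline(control, OcsvmConfig(nu=nu, gamma=gamma), min_size=min_size)
    labeling = label_table(model, target, with_focal=False)
    return labeling.total_area("proximal")


def feasibility_scan(
    control_table: FeatureTable,
    grid: ParameterGrid,
    folds: list[list[str]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> TuningResult:
    """Stage 1: mark each combination feasible iff the full proximal
    pipeline finds zero clusters in every held-out control section of
    every fold."""
    sections = control_table.sections()
    if len(sections) < 2:
        raise ValueError("control table must span at least 2 sections")
    if folds is None:
        folds = make_folds(sections, k=k, seed=seed)
    result = TuningResult()
    for nu, gamma, min_size in grid.combinations():
        total_area = 0.0
        feasible = True
        for held_out in folds:
            train_secs = [s for s in sections if s not in held_out]
            train = _subset(control_table, train_secs)
            for sec in held_out:
                area = _proximal_area(train, _subset(control_table, [sec]),
                                      nu, gamma, min_size)
                total_area += area
                if area > 0:
                    feasible = False
        result.combos.append(
            ComboResult(nu, gamma, min_size, feasible, control_cluster_area=total_area)
        )
    return result


def select_params(
    control_table: FeatureTable,
    test_table: FeatureTable,
    grid: ParameterGrid,
    feasibility: TuningResult,
) -> TuningResult:
    """Stage 2: among feasible combinations, train on all control rows and
    select the combination maximising total proximal cluster area over the
    test sections.  Ties prefer the largest nu, then gamma, then min_size
    (the most conservative boundary with equal yield)."""
    feasible = feasibility.feasible_set
    if not feasible:
        raise NoFeasibleParameters(
            "no hyperparameter combination yielded zero control clusters; "
            "widen the grid (larger min_size, smaller nu) and retry"
        )
    best_key = None
    best_area = -1.0
    for key in feasible:
        nu, gamma, min_size = key
        area = _proximal_area(control_table, test_table, nu, gamma, min_size)
        feasibility.combo(key).test_cluster_area = area
        better = area > best_area + 1e-9
        tie = abs(area - best_area) <= 1e-9 and best_key is not None and key > best_key
        if better or tie:
            best_area = area
            best_key = key
    feasibility.selected = best_key
    return feasibility


def tune(
    control_table: FeatureTable,
    test_table: FeatureTable,
    grid: ParameterGrid | None = None,
    k: int = 10,
    seed: int = 0,
) -> TuningResult:
    """Run both stages and return the audited result."""
    grid = grid or ParameterGrid()
    feas = feasibility_scan(control_table, grid, k=k, seed=seed)
    return select_params(control_table, test_table, grid, feas)
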