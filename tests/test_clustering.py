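import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import gliaclust as g
from gliaclust.clustering import (
    ClusterParams,
    _dbscan_labels,
    assign_regions,
    cluster_area_fraction,
    cluster_focal,
    cluster_overlap,
    cluster_proximal,
    default_eps,
    elbow_threshold,
)
from gliaclust.outliers import OutlierFlags
from oracles import dbscan_oracle, elbow_oracle, partition_of


def flags_from(xy, outlier=None, intden_z=None, section="S"):
    n = len(xy)
    d = pd.DataFrame({
        "section_id": section,
        "x_um": np.asarray(xy)[:, 0] if n else np.array([]),
        "y_um": np.asarray(xy)[:, 1] if n else np.array([]),
        "Mean_z": 1.0,
        "IntDen_z": intden_z if intden_z is not None else 0.0,
        "decision_value": -1.0,
        "is_outlier": outlier if outlier is not None else np.ones(n, bool),
    })
    return OutlierFlags(d)


class TestDefaultEps:
    def test_hundred_micron_window(self):
        assert default_eps(100) == 142.0

    def test_fifty_micron_window(self):
        assert default_eps(50) == 71.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            default_eps(0)


class TestDbscanAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_point_sets_match(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 61)
        xy = rng.uniform(0, 500, size=(n, 2))
        eps = rng.uniform(30, 160)
        min_size = int(rng.integers(2, 8))
        ours = _dbscan_labels(xy, ClusterParams(eps=eps, min_size=min_size))
        oracle = dbscan_oracle(xy, eps, min_size)
        # compare as partitions: same noise set, same clusters
        assert partition_of(ours) == partition_of(oracle)


class TestClusterProximal:
    def test_line_of_six_forms_one_cluster(self):
        xy = [(50.0 + 50 * i, 50.0) for i in range(6)]
        lab = cluster_proximal(flags_from(xy), ClusterParams(eps=142, min_size=5))
        assert (lab.labels["region"] == "proximal").sum() == 6
        assert len(lab.footprints("proximal")) == 1

    def test_below_min_size_no_cluster(self):
        xy = [(50.0 + 50 * i, 50.0) for i in range(3)]
        lab = cluster_proximal(flags_from(xy), ClusterParams(eps=142, min_size=5))
        assert (lab.labels["region"] == "distal").all()

    def test_two_far_groups_two_clusters(self):
        xy = [(50.0 + 50 * i, 50.0) for i in range(6)]
        xy += [(50.0 + 50 * i, 800.0) for i in range(6)]
        lab = cluster_proximal(flags_from(xy), ClusterParams(eps=142, min_size=5))
        assert len(lab.footprints("proximal")) == 2

    def test_no_outliers_is_valid_zero_cluster_result(self):
        xy = [(50.0, 50.0), (500.0, 500.0)]
        lab = cluster_proximal(flags_from(xy, outlier=[False, False]))
        assert lab.footprints("proximal") == []
        assert (lab.labels["region"] == "distal").all()

    def test_sections_clustered_independently(self):
        a = flags_from([(50.0 + 50 * i, 50.0) for i in range(3)], section="A").data
        b = flags_from([(50.0 + 50 * i, 50.0) for i in range(3)], section="B").data
        lab = cluster_proximal(OutlierFlags(pd.concat([a, b], ignore_index=True)),
                               ClusterParams(eps=142, min_size=5))
        # 3 + 3 windows in different sections never merge into one cluster
        assert lab.footprints("proximal") == []


class TestElbow:
    def test_hockey_stick_breakpoint_found(self):
        vals = np.concatenate([np.zeros(80), np.linspace(0.05, 4.0, 20)])
        res = elbow_threshold(vals)
        assert res.passes_floor
        assert abs(res.modal_index - 80) <= 2
        i_oracle, d_oracle = elbow_oracle(vals)
        assert abs(res.modal_index - i_oracle) <= 2
        assert res.max_perp_magnitude == pytest.approx(d_oracle, rel=1e-6)

    def test_linear_ramp_fails_floor(self):
        res = elbow_threshold(np.linspace(0.0, 4.0, 100))
        assert res.max_perp_magnitude == pytest.approx(0.0, abs=1e-9)
        assert not res.passes_floor

    def test_magnitude_exactly_at_floor_fails(self):
        # the floor comparison is strict: a curve whose magnitude equals
        # the floor exactly does not unlock the focal stage
        vals = np.concatenate([np.zeros(80), np.linspace(0.05, 4.0, 20)])
        mag = elbow_threshold(vals).max_perp_magnitude
        res = elbow_threshold(vals, magnitude_floor=mag)
        assert not res.passes_floor
        assert elbow_threshold(vals, magnitude_floor=mag - 1e-9).passes_floor

    def test_threshold_is_an_input_value(self, rng):
        vals = rng.normal(size=57)
        res = elbow_threshold(vals)
        assert res.threshold_value in np.sort(vals)

    def test_too_few_values(self):
        res = elbow_threshold([1.0, 2.0])
        assert not res.passes_floor
        assert np.isnan(res.threshold_value)


class TestClusterFocal:
    def grid_flags(self, intden):
        # an 8x8 window grid, all outliers, with prescribed IntDen z
        xs, ys = np.meshgrid(np.arange(8), np.arange(8))
        xy = np.stack([50.0 + 50 * xs.ravel(), 50.0 + 50 * ys.ravel()], axis=1)
        return flags_from(xy, intden_z=intden)

    def test_bright_core_yields_focal_inside_proximal(self):
        intden = np.zeros(64)
        core = []
        for i in range(64):
            x, y = i % 8, i // 8
            if 2 <= x <= 4 and 2 <= y <= 4:  # 9 contiguous windows
                intden[i] = 8.0
                core.append(i)
        flags = self.grid_flags(intden)
        lab = cluster_proximal(flags, ClusterParams(eps=142, min_size=5))
        lab = cluster_focal(lab)
        regions = lab.labels["region"]
        assert set(regions[core]) == {"focal"} or (regions == "focal").sum() >= 8
        assert len(lab.footprints("focal")) == 1
        # focal windows are a subset of the proximal footprint
        prox_poly = lab.region_union("proximal")
        focal_poly = lab.region_union("focal")
        assert focal_poly.within(prox_poly.buffer(1e-6))

    def test_floor_failure_blocks_focal(self):
        flags = self.grid_flags(np.linspace(0, 4, 64))
        lab = cluster_focal(cluster_proximal(flags, ClusterParams(142, 5)))
        assert lab.footprints("focal") == []

    def test_scattered_bright_windows_below_min_size(self):
        intden = np.zeros(64)
        intden[[0, 27, 55]] = 10.0  # bright but isolated
        lab = cluster_focal(cluster_proximal(self.grid_flags(intden),
                                             ClusterParams(142, 5)))
        assert lab.footprints("focal") == []

    def test_proximal_clusters_unchanged_by_focal_stage(self):
        intden = np.zeros(64)
        intden[:9] = 8.0
        lab1 = cluster_proximal(self.grid_flags(intden), ClusterParams(142, 5))
        prox_before = [(c.cluster_id, c.indices) for c in lab1.footprints("proximal")]
        lab2 = cluster_focal(lab1)
        prox_after = [(c.cluster_id, c.indices) for c in lab2.footprints("proximal")]
        assert prox_before == prox_after


class TestAssignRegions:
    def test_partition_and_no_double_counting(self):
        xs, ys = np.meshgrid(np.arange(8), np.arange(8))
        xy = np.stack([50.0 + 50 * xs.ravel(), 50.0 + 50 * ys.ravel()], axis=1)
        outlier = np.zeros(64, bool)
        outlier[:16] = True
        intden = np.zeros(64)
        intden[:9] = 9.0
        flags = flags_from(xy, outlier=outlier, intden_z=intden)
        lab = cluster_focal(cluster_proximal(flags, ClusterParams(142, 5)))
        table = flags.data[["section_id", "x_um", "y_um"]].copy()
        full = assign_regions(table, lab)
        counts = full.labels["region"].value_counts()
        assert counts.sum() == 64
        assert set(full.labels["region"]) <= {"distal", "proximal", "focal"}

    def test_no_outliers_all_distal(self):
        xy = [(50.0 * i, 50.0) for i in range(1, 5)]
        flags = flags_from(xy, outlier=[False] * 4)
        lab = cluster_proximal(flags)
        full = assign_regions(flags.data[["section_id", "x_um", "y_um"]], lab)
        assert (full.labels["region"] == "distal").all()


class TestAreasAndOverlap:
    def test_single_window_cluster_fraction(self):
        lab = cluster_proximal(
            flags_from([(50.0 + 50 * i, 50.0) for i in range(6)]),
            ClusterParams(eps=142, min_size=5))
        # 6 windows at stride 50 -> union 100 x 350 µm = 35000 µm²
        assert lab.total_area("proximal") == pytest.approx(35000.0)
        frac = cluster_area_fraction(lab, tissue_area=1e6)
        assert frac["proximal"] == pytest.approx(0.035)
        assert frac["focal"] == 0.0

    def test_overlapping_windows_counted_once(self):
        lab = cluster_proximal(flags_from([(50.0, 50.0), (100.0, 50.0),
                                           (150.0, 50.0), (200.0, 50.0),
                                           (250.0, 50.0)]),
                               ClusterParams(eps=142, min_size=5))
        # five 100-µm windows at 50% overlap: 100 x 300 µm
        assert lab.total_area("proximal") == pytest.approx(30000.0)

    def test_invalid_tissue_area(self):
        lab = cluster_proximal(flags_from([(50.0, 50.0)]), ClusterParams(142, 1))
        with pytest.raises(ValueError):
            cluster_area_fraction(lab, 0.0)

    def test_overlap_identical_disjoint_and_half(self):
        def labeling_with(footprint):
            lab = cluster_proximal(flags_from([(50.0, 50.0)]), ClusterParams(142, 1))
            lab.clusters = [type(lab.clusters[0])(
                section_id="S", region="proximal", cluster_id=0,
                indices=(0,), polygon=footprint)]
            return lab

        a = labeling_with(box(0, 0, 100, 100))
        same = labeling_with(box(0, 0, 100, 100))
        disjoint = labeling_with(box(500, 500, 600, 600))
        half = labeling_with(box(0, 0, 50, 100))
        assert cluster_overlap(a, same) == (1.0, 1.0)
        assert cluster_overlap(a, disjoint) == (0.0, 0.0)
        assert cluster_overlap(a, half) == (0.5, 1.0)
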