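import json

import numpy as np
import pandas as pd
import pytest

import gliaclust as g
from gliaclust import io as gio
from gliaclust.image import ImagePlane
from gliaclust.report import linear_fit, pearson_coloc, region_summary


@pytest.fixture(scope="module")
def labelled():
    ctrl, test, truth = g.generate_feature_table(g.SyntheticFeatureSpec(
        n_sections_control=3, n_sections_test=2, grid_shape=(12, 12),
        activation_rect=(3, 3, 8, 8), focal_rect=(5, 5, 7, 7), seed=17))
    model = g.fit_pipeline(ctrl, g.OcsvmConfig(nu=0.05, gamma=0.1), min_size=5)
    labeling = g.label_table(model, test)
    return ctrl, test, truth, model, labeling


class TestRegionSummary:
    def test_counts_partition_test_table(self, labelled):
        ctrl, test, _, _, labeling = labelled
        s = region_summary(test, labeling, ctrl)
        n_regions = sum(s.n(r) for r in ("distal", "proximal", "focal"))
        assert n_regions == len(test)
        assert s.n("ipsilateral") == len(test)

    def test_control_fold_change_is_one(self, labelled):
        ctrl, _, _, _, labeling = labelled
        s = region_summary(ctrl.sorted(), _all_distal(ctrl), ctrl)
        for f in ctrl.feature_columns:
            assert s.fold_change("control", f) == pytest.approx(1.0)

    def test_proximal_intensity_fold_near_generator_truth(self, labelled):
        # summarise without the focal stage so the proximal label covers
        # the whole implant (the focal stage deliberately strips the
        # brightest windows out of proximal)
        ctrl, test, _, model, _ = labelled
        labeling = g.label_table(model, test, with_focal=False)
        s = region_summary(test, labeling, ctrl)
        assert s.fold_change("proximal", "Mean") == pytest.approx(1.4, abs=0.15)

    def test_empty_region_rows_present(self, labelled):
        ctrl, _, _, _, _ = labelled
        s = region_summary(ctrl.sorted(), _all_distal(ctrl), ctrl)
        assert s.n("proximal") == 0
        assert np.isnan(s.table.loc[("proximal", "Mean"), "mean"])


def _all_distal(table):
    labels = table.data[["section_id", "x_um", "y_um"]].copy()
    labels["region"] = "distal"
    labels["cluster_id"] = -1
    return g.ClusterLabeling(labels=labels, clusters=[])


class TestPearsonColoc:
    def test_identical_channels_full_correlation(self, rng):
        a = rng.uniform(0, 100, (50, 50))
        res = pearson_coloc(a, a)
        assert res.R == pytest.approx(1.0)

    def test_inverted_channel_anticorrelated(self, rng):
        a = rng.uniform(0, 100, (50, 50))
        assert pearson_coloc(a, -a + 100).R == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self, rng):
        a = rng.normal(size=(100, 100))
        b = rng.normal(size=(100, 100))
        assert abs(pearson_coloc(a, b).R) <= 0.05

    def test_symmetry(self, rng):
        a = rng.uniform(size=(30, 30))
        b = rng.uniform(size=(30, 30))
        assert pearson_coloc(a, b).R == pytest.approx(pearson_coloc(b, a).R)

    def test_roi_mask_restricts_pixels(self, rng):
        a = rng.uniform(size=(20, 20))
        b = a.copy()
        b[10:] = rng.uniform(size=(10, 20))  # decorrelate bottom half
        roi = np.zeros((20, 20), bool)
        roi[:10] = True
        res = pearson_coloc(a, b, roi_mask=roi)
        assert res.R == pytest.approx(1.0)
        assert res.n_pixels == 200

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_coloc(np.ones((5, 5)), np.random.default_rng(0).uniform(size=(5, 5)))


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linear_fit(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_y_low_r2(self, rng):
        x = np.arange(2000.0)
        y = rng.normal(size=2000)
        assert linear_fit(x, y).r_squared < 0.01

    def test_three_collinear_points(self):
        res = linear_fit([0.0, 1.0, 2.0], [5.0, 4.0, 3.0])
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            linear_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestRoundTrips:
    def test_feature_csv_bit_identical(self, labelled, tmp_path):
        ctrl, _, _, _, _ = labelled
        path = tmp_path / "ctrl.csv"
        gio.write_feature_csv(path, ctrl)
        back = gio.read_feature_csv(path, "microglia")
        pd.testing.assert_frame_equal(back.data, ctrl.data[back.data.columns])

    def test_labels_csv_schema_and_roundtrip(self, labelled, tmp_path):
        _, _, _, _, labeling = labelled
        path = tmp_path / "labels.csv"
        gio.write_labels_csv(path, labeling)
        back = gio.read_labels_csv(path)
        assert list(back.columns) == ["section_id", "x_um", "y_um", "region", "cluster_id"]
        pd.testing.assert_frame_equal(back, labeling.labels[back.columns])

    def test_tiff_roundtrip(self, tmp_path, rng):
        img = rng.uniform(0, 255, (40, 60)).astype(np.float32)
        gio.write_tiff(tmp_path / "p.tif", ImagePlane(img, scale=1.5))
        back = gio.read_tiff(tmp_path / "p.tif", scale=1.5)
        np.testing.assert_array_equal(back.pixels, img)

    def test_zstack_tiff_projected(self, tmp_path, rng):
        import tifffile

        stack = rng.uniform(0, 100, (4, 20, 20)).astype(np.float32)
        tifffile.imwrite(tmp_path / "z.tif", stack)
        back = gio.read_tiff(tmp_path / "z.tif")
        np.testing.assert_array_equal(back.pixels, stack.max(axis=0))

    def test_model_json_roundtrip(self, labelled, tmp_path):
        _, test, _, model, labeling = labelled
        path = tmp_path / "model.json"
        gio.save_model(path, model)
        clone = gio.load_model(path)
        lab2 = g.label_table(clone, test)
        pd.testing.assert_frame_equal(lab2.labels, labeling.labels)

    def test_geojson_footprints(self, labelled, tmp_path):
        _, _, _, _, labeling = labelled
        path = tmp_path / "clusters.geojson"
        gio.write_geojson(path, labeling)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == len(labeling.clusters)
        from shapely.geometry import shape

        for feat, cl in zip(doc["features"], labeling.clusters):
            assert shape(feat["geometry"]).equals_exact(cl.polygon, 1e-9)
            assert feat["properties"]["region"] == cl.region

    def test_roi_geojson_reader(self, tmp_path):
        poly = {"type": "Polygon",
                "coordinates": [[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]]}
        (tmp_path / "roi.json").write_text(json.dumps(
            {"type": "Feature", "geometry": poly, "properties": {}}))
        roi = gio.read_roi_geojson(tmp_path / "roi.json")
        assert roi.area == 100.0

    def test_config_validation(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"nu": 0.0}))
        with pytest.raises(ValueError, match="nu"):
            gio.read_config(p)
        p2 = tmp_path / "cfg.yaml"
        p2.write_text("nu: 0.1\ngamma: 0.5\nmin_size: 5\n")
        cfg = gio.read_config(p2)
        assert cfg == {"nu": 0.1, "gamma": 0.5, "min_size": 5}

    def test_run_log_written(self, tmp_path):
        gio.write_run_log(tmp_path / "log.json", "train", {"nu": 0.1}, seed=3)
        log = json.loads((tmp_path / "log.json").read_text())
        assert log["command"] == "train"
        assert log["seed"] == 3
        assert "numpy" in log["versions"]
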