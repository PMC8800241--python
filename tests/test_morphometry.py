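import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import perimeter_crofton

from gliaclust.image import ImagePlane
from gliaclust.morphometry import (
    SkeletonStats,
    circularity,
    fractal_dimension,
    segment_somata,
    skeleton_stats,
)
from oracles import box_count_oracle


def y_mask(arm=20, size=60):
    """Clean one-pixel 'Y': one vertical arm up, two diagonal arms down."""
    m = np.zeros((size, size), bool)
    cy = cx = size // 2
    for i in range(arm):
        m[cy - i, cx] = True
    for i in range(1, arm):
        m[cy + i, cx - i] = True
        m[cy + i, cx + i] = True
    return m


class TestFractalDimension:
    def test_empty_mask_is_zero(self):
        assert fractal_dimension(np.zeros((64, 64), bool)) == 0.0

    def test_line_dimension_near_one(self):
        line = np.zeros((256, 256), bool)
        line[128, :] = True
        assert abs(fractal_dimension(line) - 1.0) <= 0.15

    def test_filled_square_dimension_near_two(self):
        assert abs(fractal_dimension(np.ones((256, 256), bool)) - 2.0) <= 0.1

    def test_box_counts_match_oracle(self, rng):
        mask = rng.uniform(size=(64, 64)) > 0.7
        for s in (2, 3, 4, 8, 16):
            nh, nw = -(-64 // s), -(-64 // s)
            padded = np.zeros((nh * s, nw * s), bool)
            padded[:64, :64] = mask
            fast = padded.reshape(nh, s, nw, s).any(axis=(1, 3)).sum()
            assert fast == box_count_oracle(mask, s)

    def test_monotone_complexity_ordering(self):
        line = np.zeros((256, 256), bool)
        line[128, :] = True
        tree = np.zeros((256, 256), bool)
        # dense branching structure: a grid of lines
        tree[::16, :] = True
        tree[:, ::16] = True
        full = np.ones((256, 256), bool)
        d_line, d_tree, d_full = map(fractal_dimension, (line, tree, full))
        assert d_line < d_tree < d_full


class TestSkeletonStats:
    def test_empty_mask_all_zero(self):
        assert skeleton_stats(np.zeros((30, 30), bool)) == SkeletonStats()

    def test_straight_bar(self):
        bar = np.zeros((40, 40), bool)
        bar[20, 5:35] = True
        s = skeleton_stats(bar, scale=1.0)
        assert s.n_branches == 1
        assert s.n_end_points == 2
        assert s.n_junctions == 0
        assert s.total_branch_length == pytest.approx(29.0)

    def test_y_fixture(self):
        s = skeleton_stats(y_mask(), scale=1.0)
        assert s.n_end_points == 3
        assert s.n_junctions == 1
        assert s.n_triple_points == 1
        assert s.n_branches == 3

    def test_disjoint_union_additive(self):
        a = np.zeros((120, 120), bool)
        a[20, 10:40] = True  # bar
        b = np.zeros((120, 120), bool)
        b[70:110, 70:110] |= y_mask(arm=15, size=40)
        both = a | b
        sa, sb, sab = (skeleton_stats(m, 1.5) for m in (a, b, both))
        s_sum = sa + sb
        for attr in ("n_branches", "n_junctions", "n_triple_points",
                     "n_end_points", "n_slab_pixels"):
            assert getattr(sab, attr) == getattr(s_sum, attr)
        assert sab.total_branch_length == pytest.approx(s_sum.total_branch_length)

    def test_scale_converts_length(self):
        bar = np.zeros((20, 40), bool)
        bar[10, 5:35] = True
        s1 = skeleton_stats(bar, scale=1.0)
        s2 = skeleton_stats(bar, scale=2.0)
        assert s2.total_branch_length == pytest.approx(s1.total_branch_length / 2)

    def test_invariant_triple_le_junctions(self):
        with pytest.raises(ValueError):
            SkeletonStats(n_junctions=0, n_triple_points=1)


class TestCircularity:
    def test_formula(self):
        # a perfect circle: area = pi r^2, perimeter = 2 pi r
        r = 7.3
        assert circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_shape_ordering(self):
        # circle > square > elongated bar, strictly
        shapes = {}
        disk_m = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 15)
        disk_m[rr, cc] = True
        square = np.zeros((64, 64), bool)
        square[16:48, 16:48] = True
        bar = np.zeros((64, 64), bool)
        bar[30:34, 4:60] = True
        for name, m in [("disk", disk_m), ("square", square), ("bar", bar)]:
            shapes[name] = circularity(m.sum(), perimeter_crofton(m, directions=4))
        assert shapes["disk"] > shapes["square"] > shapes["bar"]

    def test_rasterized_convex_upper_bound(self):
        for r in (8, 12, 20):
            m = np.zeros((64, 64), bool)
            rr, cc = draw_disk((32, 32), r)
            m[rr, cc] = True
            c = circularity(m.sum(), perimeter_crofton(m, directions=4))
            assert c <= 1.1

    def test_zero_perimeter(self):
        assert circularity(10.0, 0.0) == 0.0


class TestSegmentSomata:
    def test_blank_image_empty(self):
        assert segment_somata(ImagePlane(np.zeros((80, 80)))) == []

    def test_two_disks_nnd_and_circularity(self):
        img = np.zeros((200, 200))
        for c in ((50, 50), (50, 150)):
            rr, cc = draw_disk(c, 10)
            img[rr, cc] = 200.0
        recs = segment_somata(ImagePlane(img, scale=1.5), "microglia")
        assert len(recs) == 2
        for r in recs:
            assert r.nnd == pytest.approx(100 / 1.5, rel=0.02)
            assert 0.9 <= r.circularity <= 1.1
        # centroids at the drawn centres (µm)
        got = sorted(r.centroid for r in recs)
        assert got[0] == pytest.approx((50 / 1.5, 50 / 1.5), abs=1.0)

    def test_size_filter_removes_small_components(self):
        # a component below the 25-px size filter yields no record
        img = np.zeros((100, 100))
        rr, cc = draw_disk((50, 50), 2.4)  # ~13 px after opening
        img[rr, cc] = 200.0
        assert segment_somata(ImagePlane(img, scale=1.5), "microglia") == []

    def test_single_soma_uses_fallback_nnd(self):
        img = np.zeros((120, 120))
        rr, cc = draw_disk((60, 60), 10)
        img[rr, cc] = 200.0
        recs = segment_somata(ImagePlane(img, scale=1.5), "microglia",
                              fallback_nnd=141.42)
        assert len(recs) == 1
        assert recs[0].nnd == pytest.approx(141.42)

    def test_astrocyte_protocol_size_filter_is_30(self):
        # a component passing 25 px but failing 30 px is kept for
        # microglia and dropped for astrocytes
        img = np.zeros((100, 100))
        rr, cc = draw_disk((50, 50), 3.1)  # 29 px component
        img[rr, cc] = 200.0
        mg = segment_somata(ImagePlane(img, scale=1.5), "microglia")
        ac = segment_somata(ImagePlane(img, scale=1.5), "astrocyte")
        assert len(mg) == 1
        assert ac == []

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            segment_somata(ImagePlane(np.zeros((10, 10))), "neuron")
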