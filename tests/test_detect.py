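"""Detection pipeline: thresholding, morphology, component filtering."""

import numpy as np
import pytest

from aimmtrack import detect
from aimmtrack.detect import (
    DetectConfig,
    binarize,
    detect_cells,
    dilate,
    extract_components,
    fill_holes,
    iterative_threshold,
    median_smooth,
    mend_edges,
)
from conftest import make_blob_frame


class TestIterativeThreshold:
    def test_two_level_image_fixed_point(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 100.0
        res = iterative_threshold(img, init=50.0)
        assert res.threshold == pytest.approx(50.0)
        assert not res.degenerate

    def test_small_image_converges_to_class_mean_midpoint(self):
        img = np.array([[0.0, 0.0], [0.0, 90.0]])
        res = iterative_threshold(img, init=10.0)
        assert res.threshold == pytest.approx(45.0)
        assert res.n_iter <= 3

    def test_constant_image_is_degenerate(self):
        img = np.full((4, 4), 7.0)
        res = iterative_threshold(img, init=100.0)
        assert res.degenerate
        assert res.threshold == pytest.approx(7.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_property(self, seed):
        # the returned TH reproduces itself (within tolerance) under one
        # more class-mean iteration
        r = np.random.default_rng(seed)
        img = r.uniform(0, 255, (20, 20))
        res = iterative_threshold(img)
        obj = img > res.threshold
        again = (img[obj].mean() + img[~obj].mean()) / 2.0
        assert abs(again - res.threshold) < 0.5

    def test_bad_init_recovers(self):
        img = np.zeros((4, 4))
        img[0, 0] = 200.0
        res = iterative_threshold(img, init=500.0)
        assert not res.degenerate
        assert 0 < res.threshold < 200


class TestBinarize:
    def test_strict_inequality(self):
        img = np.full((3, 3), 5.0)
        assert binarize(img, 5.0).sum() == 0
        assert binarize(img, 4.9).sum() == 9

    def test_mixed(self):
        img = np.array([[0.0, 100.0], [100.0, 0.0]])
        np.testing.assert_array_equal(binarize(img, 50.0), [[0, 1], [1, 0]])


class TestMendEdges:
    def test_bridges_single_gap(self):
        m = np.array([[1, 0, 1]], dtype=np.uint8)
        np.testing.assert_array_equal(mend_edges(m), [[1, 1, 1]])

    def test_single_neighbor_not_bridged(self):
        m = np.array([[1, 0, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(mend_edges(m), m)

    def test_diagonal_and_vertical_bridges(self):
        v = np.array([[1], [0], [1]], dtype=np.uint8)
        assert mend_edges(v)[1, 0] == 1
        d = np.eye(3, dtype=np.uint8)
        d[1, 1] = 0
        assert mend_edges(d)[1, 1] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_and_only_bridged_pixels_added(self, seed):
        r = np.random.default_rng(seed)
        m = (r.uniform(size=(25, 25)) < 0.4).astype(np.uint8)
        out = mend_edges(m)
        assert np.all(out >= m)  # never removes foreground
        # every added pixel has two opposite foreground neighbors in the input
        p = np.pad(m, 1)
        for y, x in zip(*np.nonzero(out & ~m)):
            pairs = [
                p[y + 1, x] & p[y + 1, x + 2],
                p[y, x + 1] & p[y + 2, x + 1],
                p[y, x] & p[y + 2, x + 2],
                p[y, x + 2] & p[y + 2, x],
            ]
            assert any(pairs)

    def test_idempotent_on_sparse_gaps(self):
        # isolated single-pixel breaks are repaired in one pass and a second
        # pass changes nothing
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, :] = 1
        m[3, 3] = 0
        out = mend_edges(m)
        assert out[3, 3] == 1
        np.testing.assert_array_equal(mend_edges(out), out)

    def test_all_zero(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        assert mend_edges(m).sum() == 0


class TestFillHoles:
    def test_ring_filled(self):
        m = np.ones((5, 5), dtype=np.uint8)
        m[2, 2] = 0
        assert fill_holes(m).sum() == 25

    def test_border_strip_untouched(self):
        m = np.ones((5, 5), dtype=np.uint8)
        m[0, 2] = 0
        m[1, 2] = 0
        np.testing.assert_array_equal(fill_holes(m), m)

    def test_no_hole_identity(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[1:3, 1:3] = 1
        np.testing.assert_array_equal(fill_holes(m), m)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_and_idempotent(self, seed):
        r = np.random.default_rng(seed)
        m = (r.uniform(size=(25, 25)) < 0.45).astype(np.uint8)
        out = fill_holes(m)
        assert np.all(out >= m)
        np.testing.assert_array_equal(fill_holes(out), out)


class TestMedianSmooth:
    def test_removes_isolated_pixel(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[3, 3] = 1
        assert median_smooth(m, 3).sum() == 0

    def test_preserves_solid_block_interior(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[2:7, 2:7] = 1
        out = median_smooth(m, 3)
        assert np.all(out[3:6, 3:6] == 1)

    def test_all_ones_invariant(self):
        m = np.ones((5, 5), dtype=np.uint8)
        # border handling uses zero padding, so only the interior is stable
        assert np.all(median_smooth(m, 3)[1:-1, 1:-1] == 1)

    @pytest.mark.parametrize("window", [2, 1, 0, -3, 4])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            median_smooth(np.zeros((3, 3), dtype=np.uint8), window)


class TestDilate:
    def test_single_pixel_grows_to_square(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        out = dilate(m, 1)
        assert out.sum() == 9
        assert np.all(out[1:4, 1:4] == 1)

    def test_radius_zero_identity(self):
        m = (np.random.default_rng(0).uniform(size=(8, 8)) < 0.5).astype(np.uint8)
        np.testing.assert_array_equal(dilate(m, 0), m)

    def test_contains_input(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[1, 1] = m[6, 6] = 1
        out = dilate(m, 2)
        assert np.all(out >= m)

    def test_close_blobs_may_merge(self):
        from skimage import measure

        m = np.zeros((5, 8), dtype=np.uint8)
        m[2, 2] = m[2, 4] = 1  # 2 px apart
        out = dilate(m, 1)
        assert measure.label(out, connectivity=2).max() == 1


class TestExtractComponents:
    def test_square_detection_geometry(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:5, 3:6] = 1
        dets = extract_components(m, 1, 100)
        assert len(dets) == 1
        d = dets[0]
        assert d.area == 9
        assert (d.x, d.y) == (4.0, 3.0)
        assert d.bbox == (3, 2, 3, 3)

    def test_elongated_bar_removed(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[4, 2:8] = 1  # 1x6: ratio 6.0
        assert extract_components(m, 1, 100) == []

    def test_area_bounds_are_inclusive(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:4, 2:4] = 1  # area 4
        assert len(extract_components(m, 4, 4)) == 1
        assert extract_components(m, 5, 100) == []

    def test_output_respects_filters_property(self, rng):
        m = (rng.uniform(size=(40, 40)) < 0.3).astype(np.uint8)
        dets = extract_components(m, 3, 50, 0.5, 5.0)
        for d in dets:
            assert 3 <= d.area <= 50
            assert 0.5 <= d.bbox[2] / d.bbox[3] <= 5.0


class TestDetectCells:
    def test_recovers_blob_count_with_noise(self, rng):
        cfg = DetectConfig(min_area=20, max_area=1000)
        img = make_blob_frame(4, rng)
        dets = detect_cells(img, cfg)
        assert len(dets) == 4

    def test_blank_frame_empty(self):
        assert detect_cells(np.full((50, 50), 12.0)) == []

    def test_bar_removed_blob_kept(self, rng):
        cfg = DetectConfig(min_area=20, max_area=1000)
        img = make_blob_frame(1, rng, with_salt=False, with_holes=False)
        dets = detect_cells(img, cfg)
        assert len(dets) == 1

    def test_centroid_accuracy(self, rng):
        cfg = DetectConfig(min_area=20, max_area=1000)
        img = make_blob_frame(1, rng, with_bar=False)
        (d,) = detect_cells(img, cfg)
        assert abs(d.x - 20) <= 1.0 and abs(d.y - 30) <= 1.0


def test_rescale_intensity_range():
    img = np.array([[100.0, 300.0], [500.0, 100.0]])
    out = detect.rescale_intensity(img)
    assert out.min() == pytest.approx(0.0)
    assert out.max() == pytest.approx(255.0)
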