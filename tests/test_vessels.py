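"""Vessel segmentation, distance fields, and per-region area metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from nichescape import (ImageStack, RegionMap, SegmentationParams, VesselMask,
                        distance_field, overlap_fraction, percent_area,
                        segment_vessels)

from conftest import brute_force_distance


def _stack(arr, s=1.0, name="CD31"):
    return ImageStack(np.asarray(arr, float)[None], [name], s)


class TestSegmentVessels:
    def test_elongated_tube_survives_dots_removed(self):
        """A straight tube passes the elongation filter; punctate background
        (isolated small dots) is removed."""
        img = np.zeros((60, 60))
        img[30:33, 5:55] = 100.0           # 3x50 tube, axis ratio >> 2.5
        for r, c in [(5, 5), (10, 40), (50, 20)]:
            img[r, c] = 100.0              # 1-px dots
        mask = segment_vessels(_stack(img), params=SegmentationParams("fixed:50"))
        assert mask.mask[31, 30]
        assert not mask.mask[5, 5] and not mask.mask[10, 40]
        # exactly the tube remains
        assert mask.mask.sum() == 3 * 50

    def test_round_blob_fails_elongation(self):
        img = np.zeros((40, 40))
        rr, cc = np.mgrid[:40, :40]
        img[(rr - 20) ** 2 + (cc - 20) ** 2 <= 64] = 100.0  # r=8 disk
        mask = segment_vessels(_stack(img), params=SegmentationParams("fixed:50"))
        assert mask.empty

    def test_blank_image_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = segment_vessels(_stack(np.zeros((10, 10))))
        assert mask.empty

    def test_truth_raster_fixed_threshold_identity(self, niche):
        img, cells, midline, regions, truth = niche
        truth_img = ImageStack(truth.vessel_mask.astype(float)[None],
                               ["CD31"], img.pixel_size_um)
        mask = segment_vessels(truth_img, params=SegmentationParams(
            "fixed:0.5", min_area_um2=0.0, min_elongation=1.0))
        assert np.array_equal(mask.mask, truth.vessel_mask)

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            segment_vessels(_stack(np.ones((5, 5)), name="GFAP"), "CD31")


class TestDistanceField:
    def test_single_pixel_closed_form(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 4] = True
        f = distance_field(VesselMask(mask, 0.5))
        for k in range(1, 10):
            assert f.dist[10, 4 + k] == pytest.approx(0.5 * k)
        assert f.dist[10, 4] == 0.0

    def test_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(5)
        mask = rng.uniform(size=(30, 30)) < 0.07
        mask[3, 3] = True
        f = distance_field(VesselMask(mask, 0.7))
        np.testing.assert_allclose(f.dist, brute_force_distance(mask, 0.7),
                                   atol=1e-9)

    def test_all_true_mask_zero_field(self):
        f = distance_field(VesselMask(np.ones((8, 8), bool), 1.0))
        assert np.all(f.dist == 0.0)

    def test_empty_mask_flagged_undefined(self):
        with pytest.warns(UserWarning):
            f = distance_field(VesselMask(np.zeros((8, 8), bool), 1.0))
        assert not f.defined
        assert np.all(np.isinf(f.dist))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(2, 64), st.integers(2, 64), st.integers(0, 10 ** 6),
           st.floats(0.02, 0.3))
    def test_oracle_equivalence_property(self, nr, nc, seed, p):
        """Exact Euclidean distance equals exhaustive nearest-pixel search
        on arbitrary masks up to 64x64."""
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(nr, nc)) < p
        if not mask.any():
            mask[rng.integers(nr), rng.integers(nc)] = True
        f = distance_field(VesselMask(mask, 1.0))
        np.testing.assert_allclose(f.dist, brute_force_distance(mask),
                                   atol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_monotone_under_added_vessel_pixels(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(32, 32)) < 0.05
        mask[0, 0] = True
        bigger = mask | (rng.uniform(size=(32, 32)) < 0.05)
        d1 = distance_field(VesselMask(mask, 1.0)).dist
        d2 = distance_field(VesselMask(bigger, 1.0)).dist
        assert np.all(d2 <= d1 + 1e-12)


def _rect_region(x0, y0, x1, y1, name="R"):
    return RegionMap({name: Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])})


class TestPercentArea:
    def test_half_covered_rectangle(self):
        mask = np.zeros((10, 20), bool)
        mask[:, :10] = True
        res = percent_area(VesselMask(mask, 1.0), _rect_region(0, 0, 20, 10))
        assert res["R"] == pytest.approx(50.0)

    def test_empty_mask_zero_everywhere(self):
        res = percent_area(VesselMask(np.zeros((10, 10), bool), 1.0),
                           _rect_region(0, 0, 10, 10))
        assert res["R"] == 0.0

    def test_bounded_zero_to_hundred(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(16, 16)) < 0.4
        res = percent_area(VesselMask(mask, 1.0), _rect_region(2, 2, 12, 12))
        assert 0.0 <= res["R"] <= 100.0

    def test_region_outside_image_is_nan(self):
        res = percent_area(VesselMask(np.ones((4, 4), bool), 1.0),
                           _rect_region(100, 100, 120, 120))
        assert np.isnan(res["R"])

    def test_rendered_tube_matches_analytic_area(self):
        """A horizontal tube of known pixel footprint inside a rectangular
        region yields the analytic area fraction."""
        mask = np.zeros((40, 40), bool)
        mask[18:23, :] = True  # 5 rows
        res = percent_area(VesselMask(mask, 1.0), _rect_region(0, 0, 40, 40))
        assert res["R"] == pytest.approx(100.0 * 5 / 40)


class TestOverlapFraction:
    def test_identity_is_hundred(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(20, 20)) < 0.3
        vm = VesselMask(m, 1.0)
        res = overlap_fraction(vm, vm, _rect_region(0, 0, 20, 20))
        assert res["R"] == pytest.approx(100.0)

    def test_disjoint_masks_zero(self):
        a = np.zeros((10, 10), bool); a[:5] = True
        b = np.zeros((10, 10), bool); b[5:] = True
        res = overlap_fraction(VesselMask(a, 1.0), VesselMask(b, 1.0),
                               _rect_region(0, 0, 10, 10))
        assert res["R"] == 0.0

    def test_matches_brute_force_pixel_ratio(self):
        rng = np.random.default_rng(2)
        num = rng.uniform(size=(50, 50)) < 0.4
        den = rng.uniform(size=(50, 50)) < 0.4
        res = overlap_fraction(VesselMask(num, 1.0), VesselMask(den, 1.0),
                               _rect_region(0, 0, 50, 50))
        expect = 100.0 * (num & den).sum() / den.sum()
        assert res["R"] == pytest.approx(expect)

    def test_empty_denominator_is_nan(self):
        res = overlap_fraction(VesselMask(np.ones((6, 6), bool), 1.0),
                               VesselMask(np.zeros((6, 6), bool), 1.0),
                               _rect_region(0, 0, 6, 6))
        assert np.isnan(res["R"])
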