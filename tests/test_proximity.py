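"""Nearest-vessel distances, the systematic null, and association indices."""

import numpy as np
import pandas as pd
import pytest

from nichescape import (MidlinePolyline, VesselMask, association_index,
                        distance_field, nearest_vessel_distance,
                        process_contact, sample_random_null)

from conftest import brute_force_distance_at


def _field(mask, s=0.5):
    return distance_field(VesselMask(mask, s))


def _cells(xs, ys, animal="m1", group="WT", pheno="IPC"):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(xs))],
        "animal_id": animal, "group": group, "phenotype": pheno,
        "x_um": xs, "y_um": ys,
    })


class TestNearestVesselDistance:
    def test_cell_on_vessel_reads_zero(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5] = True
        d = nearest_vessel_distance(_cells([2.75], [2.75]), _field(mask))
        assert d.iloc[0] == 0.0

    def test_closed_form_ten_pixels(self):
        mask = np.zeros((30, 30), bool)
        mask[10, 5] = True
        # centroid in the pixel 10 columns to the right, 0.5 µm/px -> 5 µm
        d = nearest_vessel_distance(_cells([7.7], [5.1]), _field(mask))
        assert d.iloc[0] == pytest.approx(5.0)

    def test_random_cells_match_brute_force(self):
        rng = np.random.default_rng(4)
        mask = rng.uniform(size=(50, 50)) < 0.05
        mask[0, 0] = True
        s = 0.5
        xs = rng.uniform(0, 25, 100)
        ys = rng.uniform(0, 25, 100)
        d = nearest_vessel_distance(_cells(xs, ys), _field(mask, s))
        bf = brute_force_distance_at(mask, (ys / s).astype(int),
                                     (xs / s).astype(int), s)
        np.testing.assert_allclose(d.to_numpy(), bf, atol=1e-9)

    def test_empty_mask_is_an_error(self):
        with pytest.warns(UserWarning):
            f = _field(np.zeros((10, 10), bool))
        with pytest.raises(ValueError, match="segmentation"):
            nearest_vessel_distance(_cells([1.0], [1.0]), f)


def _straight_midline(length=1000.0, y=50.0, halfwidth=10.0):
    return MidlinePolyline(np.array([[0.0, y], [length, y]]), halfwidth)


def _nuclei(xs, ys):
    return pd.DataFrame({"nucleus_id": range(len(xs)), "x_um": xs, "y_um": ys})


class TestSampleRandomNull:
    def test_station_count_matches_arclength_over_spacing(self):
        """A 1,000 µm midline at 100 µm spacing yields 10 sample stations."""
        mid = _straight_midline(1000.0)
        rng = np.random.default_rng(0)
        nuclei = _nuclei(rng.uniform(0, 1000, 400), rng.uniform(42, 58, 400))
        out = sample_random_null(mid, nuclei, spacing_um=100.0, seed=1)
        assert len(out) == 10  # dense nuclei: no skip, no dedup loss

    def test_nuclei_exactly_at_stations_returned_identically(self):
        mid = _straight_midline(1000.0)
        offset = np.random.default_rng(3).uniform(0, 100.0)  # same as seed=3
        stations = np.arange(offset, 1000.0, 100.0)
        nuclei = _nuclei(stations, np.full(len(stations), 50.0))
        out = sample_random_null(mid, nuclei, spacing_um=100.0, seed=3)
        assert sorted(out["x_um"]) == pytest.approx(sorted(stations))

    def test_deterministic_given_seed(self):
        mid = _straight_midline(800.0)
        rng = np.random.default_rng(2)
        nuclei = _nuclei(rng.uniform(0, 800, 200), rng.uniform(42, 58, 200))
        a = sample_random_null(mid, nuclei, seed=7)
        b = sample_random_null(mid, nuclei, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_short_midline_rejected(self):
        with pytest.raises(ValueError, match="arc length"):
            sample_random_null(_straight_midline(50.0), _nuclei([10], [50]))

    def test_isolated_station_skipped_with_warning(self):
        mid = _straight_midline(300.0)
        nuclei = _nuclei([10.0], [50.0])  # single nucleus near the start
        with pytest.warns(UserWarning, match="skipped"):
            out = sample_random_null(mid, nuclei, spacing_um=100.0, seed=0)
        assert len(out) <= 1

    def test_null_mean_robust_to_nucleus_density(self):
        """Systematic sampling is density-robust: doubling the nucleus count
        moves the null mean by less than one null-SE."""
        mask = np.random.default_rng(0).uniform(size=(200, 2000)) < 0.002
        mask[0, 0] = True
        f = _field(mask, 0.5)
        mid = _straight_midline(950.0, y=50.0)
        rng = np.random.default_rng(5)
        n1 = _nuclei(rng.uniform(0, 950, 300), rng.uniform(42, 58, 300))
        n2 = _nuclei(rng.uniform(0, 950, 600), rng.uniform(42, 58, 600))
        d1 = nearest_vessel_distance(sample_random_null(mid, n1, seed=1), f)
        d2 = nearest_vessel_distance(sample_random_null(mid, n2, seed=1), f)
        se = d1.std(ddof=1) / np.sqrt(len(d1))
        assert abs(d1.mean() - d2.mean()) < se


class TestAssociationIndex:
    def test_cells_equal_null_index_zero(self):
        mask = np.zeros((40, 40), bool)
        mask[20, :] = True
        f = _field(mask)
        cells = _cells([2.0, 4.0, 6.0], [3.0, 5.0, 7.0])
        null = cells.copy()
        res = association_index(cells, null, f, phenotype="IPC")
        assert res["association_index_um"].iloc[0] == pytest.approx(0.0)

    def test_sign_convention_negative_is_closer(self):
        mask = np.zeros((40, 40), bool)
        mask[20, :] = True  # vessel row at y = 10 µm
        f = _field(mask)
        close = _cells([5.0, 6.0], [10.2, 10.3])
        far_null = _cells([5.0, 6.0], [2.0, 18.0])
        res = association_index(close, far_null, f, phenotype="IPC")
        assert res["association_index_um"].iloc[0] < 0

    def test_translation_invariance(self):
        """Rigid translation of coordinates and mask together leaves the
        association index unchanged."""
        rng = np.random.default_rng(6)
        mask = np.zeros((60, 60), bool)
        mask[rng.integers(5, 40, 25), rng.integers(5, 40, 25)] = True
        s = 0.5
        xs, ys = rng.uniform(3, 18, 20), rng.uniform(3, 18, 20)
        nx, ny = rng.uniform(3, 18, 10), rng.uniform(3, 18, 10)
        res1 = association_index(_cells(xs, ys), _cells(nx, ny), _field(mask, s))
        shift_px, shift_um = 20, 20 * s
        mask2 = np.roll(np.roll(mask, shift_px, 0), shift_px, 1)
        res2 = association_index(_cells(xs + shift_um, ys + shift_um),
                                 _cells(nx + shift_um, ny + shift_um),
                                 _field(mask2, s))
        assert res1["association_index_um"].iloc[0] == pytest.approx(
            res2["association_index_um"].iloc[0])

    def test_insufficient_null_samples_dropped(self):
        mask = np.ones((10, 10), bool)
        f = _field(mask)
        with pytest.warns(UserWarning, match="dropped"):
            res = association_index(_cells([1], [1]), _cells([2], [2]), f,
                                    phenotype="IPC")
        assert len(res) == 0


class TestProcessContact:
    def test_process_ending_on_vessel_contacts(self):
        mask = np.zeros((40, 40), bool)
        mask[20, 20] = True  # pixel centre (10.25, 10.25) µm at 0.5 µm/px
        vm = VesselMask(mask, 0.5)
        res = process_contact({"c1": [(2.0, 2.0), (10.25, 10.25)]}, vm)
        assert res["contact"].iloc[0]

    def test_empty_mask_no_contact(self):
        vm = VesselMask(np.zeros((10, 10), bool), 0.5)
        res = process_contact({"c1": [(0, 0), (3, 3)]}, vm)
        assert not res["contact"].any()

    def test_process_with_known_clearance_no_contact(self):
        mask = np.zeros((40, 40), bool)
        mask[30, :] = True  # vessel row at y = 15.25 µm
        vm = VesselMask(mask, 0.5)
        # horizontal process at y = 5 µm: clearance > 10 µm >> tolerance
        res = process_contact({"c1": [(2.0, 5.0), (18.0, 5.0)]}, vm)
        assert not res["contact"].iloc[0]

    def test_needs_two_vertices(self):
        vm = VesselMask(np.ones((5, 5), bool), 1.0)
        with pytest.raises(ValueError):
            process_contact({"c1": [(1.0, 1.0)]}, vm)
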