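"""Generator properties: determinism, offset calibration, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from nichescape import (NicheConfig, generate_attachment_plate, generate_cohort,
                        generate_niche, generate_puncta_image,
                        generate_scratch_series)

from conftest import brute_force_distance_at, small_config


class TestDeterminism:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = small_config(seed=9)
        img1, cells1, *_ = generate_niche(cfg)
        img2, cells2, *_ = generate_niche(small_config(seed=9))
        assert np.array_equal(img1.pixels, img2.pixels)
        pd.testing.assert_frame_equal(cells1, cells2)

    def test_different_seed_differs(self):
        img1, *_ = generate_niche(small_config(seed=1))
        img2, *_ = generate_niche(small_config(seed=2))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_cohort_reproducible_from_master_seed(self):
        cfg = small_config()
        a = generate_cohort(cfg, 2, 0.5, seed=3)
        b = generate_cohort(cfg, 2, 0.5, seed=3)
        assert [x.animal_id for x in a] == [y.animal_id for y in b]
        for x, y in zip(a, b):
            assert x.true_offsets_um == y.true_offsets_um
            pd.testing.assert_frame_equal(x.cells, y.cells)

    def test_puncta_truth_reproducible(self):
        _, _, t1 = generate_puncta_image({"IPC": 10}, {"IPC": 4.0}, seed=5)
        _, _, t2 = generate_puncta_image({"IPC": 10}, {"IPC": 4.0}, seed=5)
        pd.testing.assert_frame_equal(t1.puncta_counts, t2.puncta_counts)


class TestOffsetCalibration:
    def test_zero_offsets_unbiased_over_seeds(self):
        """With all offsets 0 the generator introduces no phenotype-vessel
        association: mean realized offset across 20 seeds within 2 SE."""
        realized = {ph: [] for ph in ("RGL-NSC", "IPC")}
        for seed in range(20):
            *_, truth = generate_niche(small_config(seed=seed))
            for ph in realized:
                realized[ph].append(truth.realized_offsets_um[ph])
        for ph, vals in realized.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 2 * se + 1e-9, (ph, vals.mean(), se)

    def test_negative_ipc_offset_recovered_from_truth(self):
        """IPC offset -3 µm with many IPCs: truth mean minus random-nucleus
        mean lands in [-3.5, -2.5] µm, computed from truth alone."""
        cfg = NicheConfig(n_cells_per_type={"IPC": 500},
                          distance_offset_um={"IPC": -3.0}, seed=17)
        *_, truth = generate_niche(cfg)
        diff = (truth.cells["true_dist_um"].mean()
                - truth.nuclei["true_dist_um"].mean())
        assert -3.5 < diff < -2.5

    def test_infeasible_offset_names_phenotype(self):
        cfg = small_config(distance_offset_um={"IPC": 500.0})
        with pytest.raises(ValueError, match="IPC"):
            generate_niche(cfg)


class TestTruthConsistency:
    def test_truth_distances_match_brute_force_within_half_pixel(self, niche):
        img, cells, midline, regions, truth = niche
        s = img.pixel_size_um
        sub = truth.cells.head(40)
        bf = brute_force_distance_at(truth.vessel_mask,
                                     (sub["y_um"] / s).astype(int),
                                     (sub["x_um"] / s).astype(int), s)
        np.testing.assert_allclose(sub["true_dist_um"].to_numpy(), bf,
                                   atol=0.5 * s)

    def test_cells_unique_and_distances_nonnegative(self, niche):
        *_, truth = niche
        assert truth.cells["cell_id"].is_unique
        assert (truth.cells["true_dist_um"] >= 0).all()

    def test_marker_profiles_recover_truth_phenotypes(self, niche):
        from nichescape import classify_cells
        _, cells, *_ = niche
        out = classify_cells(cells, "reporter")
        match = (out["phenotype"] == out["phenotype_true"]).mean()
        assert match > 0.95


class TestCohort:
    def test_zero_between_animal_sd_shares_offsets(self):
        cfg = small_config(distance_offset_um={"iKD": {"IPC": 2.0}})
        animals = generate_cohort(cfg, 2, between_animal_sd_um=0.0, seed=1)
        for a in animals:
            expect = 2.0 if a.group == "iKD" else 0.0
            assert a.true_offsets_um["IPC"] == pytest.approx(expect)

    def test_group_offset_difference_recovered_in_truth(self):
        """8 animals/group with a 3.565 µm IPC offset difference: the grand
        difference of per-animal true means recovers the configured shift
        within 2 between-animal SEM."""
        sd = 0.8
        cfg = small_config(distance_offset_um={"iKD": {"IPC": 3.565}},
                           n_sections=2)
        animals = generate_cohort(cfg, 8, between_animal_sd_um=sd, seed=2)
        means = {"WT": [], "iKD": []}
        for a in animals:
            per_sec = [s.truth.cells.loc[s.truth.cells.phenotype_true == "IPC",
                                         "true_dist_um"].mean()
                       - s.truth.nuclei["true_dist_um"].mean()
                       for s in a.sections]
            means[a.group].append(np.mean(per_sec))
        diff = np.mean(means["iKD"]) - np.mean(means["WT"])
        sem = np.sqrt(np.var(means["iKD"], ddof=1) / 8
                      + np.var(means["WT"], ddof=1) / 8)
        assert abs(diff - 3.565) < 2 * sem

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            generate_cohort(small_config(), 1, seed=0)


class TestPunctaGenerator:
    def test_zero_rate_zero_truth_counts(self):
        _, _, truth = generate_puncta_image({"NB": 20}, {"NB": 0.0}, seed=0)
        assert (truth.puncta_counts["true_count"] == 0).all()

    def test_rates_reflected_in_truth_means(self):
        _, _, truth = generate_puncta_image(
            {"astrocyte": 150, "RGL-NSC": 150},
            {"astrocyte": 10.0, "RGL-NSC": 10.0 * (1 - 0.6243)}, seed=1)
        m = truth.puncta_counts.groupby("phenotype")["true_count"].mean()
        pct = 100 * (m["astrocyte"] - m["RGL-NSC"]) / m["astrocyte"]
        # Poisson SEM of the percent difference at n=150/phenotype
        assert pct == pytest.approx(62.43, abs=8.0)

    def test_overcrowded_nucleus_warns_and_flags(self):
        with pytest.warns(UserWarning, match="too small"):
            _, _, truth = generate_puncta_image(
                {"IPC": 5}, {"IPC": 40.0}, nucleus_radius_um=1.2,
                pixel_size_um=0.5, seed=2)
        assert truth.puncta_counts["merged"].any()


class TestScratchGenerator:
    def test_zero_rate_no_ingression_even_at_30h(self):
        series, truth = generate_scratch_series(
            1e6, {"quiescent": 0.0}, [0, 1, 4, 8, 30], seed=0)
        tr = truth.scratch_areas
        assert (tr["ingression"] == 0).all()
        assert (tr["area_um2"] == 1e6).all()

    def test_full_closure_by_8h_gives_ingression_one(self):
        _, truth = generate_scratch_series(5e5, {"vehicle": 0.125},
                                           [0, 1, 4, 8], seed=0)
        last = truth.scratch_areas.query("time_h == 8").iloc[0]
        assert last["ingression"] == pytest.approx(1.0)
        assert last["area_um2"] == 0.0

    def test_requires_time_zero(self):
        with pytest.raises(ValueError):
            generate_scratch_series(1e6, {"v": 0.1}, [1, 4], seed=0)


class TestAttachmentGenerator:
    def test_full_retention_post_equals_pre(self):
        wells, _, _ = generate_attachment_plate(
            2, 200, {"vehicle": 1.0, "drug": 1.0}, seed=0, render=False)
        assert (wells["post_count_true"] == wells["pre_count_true"]).all()

    def test_zero_retention_empties_wells(self):
        wells, _, _ = generate_attachment_plate(
            1, 100, {"vehicle": 0.0, "drug": 0.0}, seed=0, render=False)
        assert (wells["post_count_true"] == 0).all()

    def test_truth_reduction_near_configured(self):
        wells, _, _ = generate_attachment_plate(
            12, 1000, {"vehicle": 0.8, "drug": 0.8 * (1 - 0.31)},
            seed=1, render=False)
        ret = wells.groupby("treatment").apply(
            lambda g: g["post_count_true"].sum() / g["pre_count_true"].sum(),
            include_groups=False)
        red = 100 * (1 - ret["drug"] / ret["vehicle"])
        assert red == pytest.approx(31.0, abs=3.0)

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            generate_attachment_plate(1, 10, {"a": 1.2, "b": 0.5}, seed=0)
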