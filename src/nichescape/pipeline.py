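"""End-to-end pipeline: simulate (or load) a cohort, segment, measure, test.

The chain mirrors how the measurements are made on real sections: segment
vessels from the CD31 channel, build the distance field, classify cells
from their marker calls, measure per-cell nearest-vessel distances, draw
the systematic random null along the SGZ midline, aggregate to per-animal
means, and compare groups with the animal as the experimental unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .phenotype import classify_cells
from .proximity import nearest_vessel_distance, sample_random_null
from .stats import StatsResult, compare_groups
from .synthetic import AnimalNiche, NicheConfig, generate_cohort
from .vessels import SegmentationParams, distance_field, segment_vessels

__all__ = ["PipelineResult", "run_proximity_pipeline", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass
class PipelineResult:
    """Bundle of per-cell, per-animal and group-level outputs."""

    per_cell: pd.DataFrame
    per_animal: pd.DataFrame
    group_stats: dict[str, StatsResult]
    group_differences_um: dict[str, float] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out = {"schema_version": SCHEMA_VERSION, "phenotypes": {}}
        for pheno, res in self.group_stats.items():
            out["phenotypes"][pheno] = {
                "test": res.test,
                "statistic": res.statistic,
                "df": list(res.df),
                "p_value": res.p_value,
                "group_difference_um": self.group_differences_um.get(pheno),
            }
        return out


def analyze_animal(animal: AnimalNiche, seg: SegmentationParams,
                   spacing_um: float, phenotypes: list[str],
                   rule_set: str = "reporter",
                   null_seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure one animal: segmentation -> distances -> null -> association.

    Each section is segmented and measured on its own distance field; cell
    and null distances pool across the animal's sections (random distances
    are computed per animal across all its sections).  Returns
    (per-animal association table, per-cell distance table).
    """
    cell_tabs = []
    null_d = []
    for k, sec in enumerate(animal.sections):
        mask = segment_vessels(sec.image, "CD31", seg)
        dfield = distance_field(mask)
        cells = classify_cells(sec.cells, rule_set)
        cells = cells.assign(dist_um=nearest_vessel_distance(cells, dfield))
        cell_tabs.append(cells)
        # the section's Hoechst nuclei are the null candidate population
        null_set = sample_random_null(sec.midline, sec.truth.nuclei,
                                      spacing_um=spacing_um,
                                      seed=null_seed + k)
        null_d.append(nearest_vessel_distance(null_set, dfield).to_numpy())
    cells = pd.concat(cell_tabs, ignore_index=True)
    null_d = np.concatenate(null_d)
    rows = []
    for pheno in phenotypes:
        d = cells.loc[cells["phenotype"] == pheno, "dist_um"]
        if len(d) < 1 or len(null_d) < 2:
            continue
        rows.append({"animal_id": animal.animal_id, "group": animal.group,
                     "phenotype": pheno, "mean_dist_um": float(d.mean()),
                     "null_mean_um": float(null_d.mean()),
                     "association_index_um": float(d.mean() - null_d.mean()),
                     "n_cells": int(len(d)), "n_null": int(len(null_d))})
    per_animal = pd.DataFrame(rows)
    per_cell = cells[["cell_id", "animal_id", "group", "phenotype",
                      "x_um", "y_um", "dist_um"]]
    return per_animal, per_cell


def run_proximity_pipeline(animals: list[AnimalNiche],
                           config: PipelineConfig | None = None) -> PipelineResult:
    """Full proximity analysis over a simulated (or assembled) cohort."""
    config = config or PipelineConfig()
    seg = SegmentationParams(threshold=config.segmentation.threshold,
                             min_area_um2=config.segmentation.min_area_um2,
                             min_elongation=config.segmentation.min_elongation)
    ss = np.random.SeedSequence(config.seed)
    null_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                  ss.spawn(len(animals))]
    per_animal = []
    per_cell = []
    for animal, nseed in zip(animals, null_seeds):
        tab, cell_tab = analyze_animal(animal, seg,
                                       config.null_sampling.spacing_um,
                                       config.stats.phenotypes,
                                       config.stats.rule_set, null_seed=nseed)
        per_animal.append(tab)
        per_cell.append(cell_tab)
    per_animal = pd.concat(per_animal, ignore_index=True)
    per_cell = pd.concat(per_cell, ignore_index=True)

    stats: dict[str, StatsResult] = {}
    diffs: dict[str, float] = {}
    groups = list(pd.unique(per_animal["group"]))
    for pheno in config.stats.phenotypes:
        sub = per_animal[per_animal["phenotype"] == pheno]
        if sub["group"].nunique() < 2:
            continue
        stats[pheno] = compare_groups(sub.rename(columns={"mean_dist_um": "value"}),
                                      value="value", factors="group")
        means = sub.groupby("group", observed=True)["mean_dist_um"].mean()
        if len(groups) == 2:
            # knockdown minus control: positive = farther from vessels
            diffs[pheno] = float(means[groups[1]] - means[groups[0]])
    return PipelineResult(per_cell, per_animal, stats, diffs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Simulate a cohort per the config, run the proximity chain, write results.

    Writes per-cell and per-animal CSVs, a machine-readable summary JSON and
    a resolved copy of the configuration.  Deterministic given the seed.
    """
    sim = config.simulation
    ncfg = NicheConfig(
        image_size_px=tuple(sim.image_size_px),
        n_sections=sim.n_sections,
        pixel_size_um=sim.pixel_size_um,
        band_halfwidth_um=sim.band_halfwidth_um,
        vessel_density_um_per_um2=sim.vessel_density_um_per_um2,
        vessel_radius_um=sim.vessel_radius_um,
        hoechst_density_per_100um=sim.hoechst_density_per_100um,
        distance_offset_um=_tuple_keys(sim.distance_offset_um),
        **({"n_cells_per_type": sim.n_cells_per_type}
           if sim.n_cells_per_type else {}),
        seed=config.seed,
    )
    groups = tuple(sim.n_animals_per_group)
    animals = generate_cohort(ncfg, sim.n_animals_per_group,
                              sim.between_animal_sd_um, seed=config.seed,
                              groups=groups)
    result = run_proximity_pipeline(animals, config)

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_cell.to_csv(out / "per_cell_distances.csv", index=False)
    result.per_animal.to_csv(out / "per_animal_summary.csv", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary_dict(), fh, indent=1)
    config.write_resolved(out / "resolved_config.yaml")
    return result


def _tuple_keys(offsets: dict) -> dict:
    """YAML configs write offsets as {group: {phenotype: µm}}; pass through."""
    return dict(offsets)
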