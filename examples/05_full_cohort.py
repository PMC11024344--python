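"""End-to-end cohort study: simulate, measure, and test group differences.

Generates an 8-vs-8 animal cohort in which the knockdown group's stem and
progenitor cells sit farther from vessels by the configured shifts, then
runs the complete analysis chain and prints the recovered group effects.
"""

import numpy as np

from nichescape import (NicheConfig, PipelineConfig, generate_cohort,
                        run_proximity_pipeline)

offsets = {"RGL-NSC": 3.112, "IPC": 3.565}
config = NicheConfig(distance_offset_um={"iKD": offsets}, seed=1)
animals = generate_cohort(config, 8, between_animal_sd_um=0.8, seed=1)
print(f"{len(animals)} animals x {len(animals[0].sections)} sections each")

result = run_proximity_pipeline(animals, PipelineConfig(seed=1))
for pheno, truth in offsets.items():
    sub = result.per_animal[result.per_animal["phenotype"] == pheno]
    sems = sub.groupby("group")["mean_dist_um"].sem()
    sem_diff = float(np.sqrt((sems ** 2).sum()))
    est = result.group_differences_um[pheno]
    p = result.group_stats[pheno].p_value
    print(f"{pheno:8s} estimated shift {est:+.2f} um "
          f"(truth {truth:+.3f}, SEM {sem_diff:.2f}), Welch t p = {p:.2e}")
# The estimated knockdown-minus-control distance shifts should recover the
# configured offsets within ~2 SEM, with significant group tests.
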