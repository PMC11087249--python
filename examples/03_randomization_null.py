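"""Randomization null for one case.

Re-places each immune class's estimated cell equivalents uniformly over
the tumor-associated stroma and asks whether the observed K17-negative vs
K17-positive score contrast exceeds chance.  With a strong simulated CD8
exclusion the CD8 empirical p hits the add-one minimum 1/(1+reps); the
unmodulated classes stay non-significant.
"""

from immune_topo import (
    Role,
    SyntheticConfig,
    assign_zones,
    compute_zone_scores,
    randomization_null,
    simulate_case,
)

cfg = SyntheticConfig(
    image_hw_px=(700, 700), resolution_um_per_px=1.0,
    n_nests=6, nest_radius_um=(60.0, 12.0),
    base_intensity={Role.CD4: 200.0, Role.CD8: 600.0, Role.CD16: 0.0, Role.CD163: 0.0},
    zone_modulation={Role.CD4: 1.0, Role.CD8: 0.1, Role.CD16: 1.0, Role.CD163: 1.0},
    seed=3,
)
mask, _ = simulate_case(cfg)
zonemap = assign_zones(mask)
scores = compute_zone_scores(mask, zonemap)
result = randomization_null(mask, zonemap, scores, n_reps=199, seed=3)
print("observed |ZS(K17-) - ZS(K17+)| and empirical p per class/compartment:")
print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nminimum attainable p at 199 replicates:", 1 / 200)
print("CD8 hits that floor in both compartments (the simulated exclusion is"
      "\nnon-random). Intra rows can also reject for unmodulated classes: the"
      "\ngenerator concentrates a fraction of cells in the contact shell, which"
      "\nis itself a departure from uniform placement — exactly what this null"
      "\ndetects.  CD4 peri, with no K17 effect, stays non-significant.")
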