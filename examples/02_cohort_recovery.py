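"""Cohort-level recovery of a CD8 exclusion effect.

Simulates a small cohort in which CD8 intensity is 5x lower in
K17-positive than K17-negative peritumoral territory, scores every case,
and summarizes: the fraction of cases with the K17-negative score higher,
and the paired t test on the per-case score pairs.
"""

import pandas as pd

from immune_topo import assign_zones, cohort_summary, compute_zone_scores, normalized_ratios
from immune_topo.experiments import cohort_config
from immune_topo import simulate_cohort

cfg = cohort_config(cd8_modulation=0.2, seed=1)
cases, truth = simulate_cohort(cfg, n_cases=10, seed=1)

frames = []
for case_id, mask in cases:
    zm = assign_zones(mask)
    frames.append(compute_zone_scores(mask, zm, case_id=case_id))
scores = pd.concat(frames, ignore_index=True)
cohort = cohort_summary(normalized_ratios(scores))

print("cohort summary (fraction of cases with ZS higher in K17- territory):")
print(cohort.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nCD8 rows should show fraction near 1 and tiny p; the unmodulated"
      "\nclasses (CD4/CD16/CD163) should hover near 0.5 with large p.")
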