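"""Standard synthetic experiment protocols with fixed study conditions.

These functions bundle the package's canonical validation experiments so
tests, examples and reproduction scripts run the identical protocol:

* dataset patch-tiling arithmetic (ROI -> overlapping patch counts),
* pixel->cell-count calibration on disjoint synthetic disks,
* cohort parameter recovery (does the pipeline's K17-negative vs
  K17-positive contrast recover a generator-imposed CD8 exclusion?),
* randomization-null calibration (are empirical p values uniform when the
  generator has no K17 effect?).

Cohort-scale runs use 1.0 um/px masks of ~1 mm^2 so each case's
peritumoral band carries stable Poisson counts at desk scale; the zone
logic is resolution-agnostic, so this is purely a problem-size choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classes import LabelMask, Role
from .mask_io import tile_patches
from .scoring import CellGeometry, compute_zone_scores, estimate_cell_count, normalized_ratios
from .stats import cohort_summary, randomization_null
from .synthetic import SyntheticConfig, simulate_cohort
from .zones import assign_zones

__all__ = [
    "patch_dataset_sizes",
    "cell_count_calibration",
    "cohort_config",
    "run_parameter_recovery",
    "run_null_calibration",
]


def patch_dataset_sizes() -> dict:
    """Patch counts of the segmentation train/val/test protocol.

    Training and validation ROIs are 1000 x 1000 px tiled into overlapping
    400 x 400 patches at stride 200 (16 per ROI; 57 training and 4
    validation ROIs); the 32 testing ROIs are 400 x 400, one patch each.
    """
    per_roi = tile_patches((1000, 1000), 400, 200).n_patches
    testing_per_roi = tile_patches((400, 400), 400, 400).n_patches
    return {
        "patches_per_roi": per_roi,
        "training_patches": 57 * per_roi,
        "validation_patches": 4 * per_roi,
        "testing_patches": 32 * testing_per_roi,
    }


def cell_count_calibration(
    ks: tuple[int, ...] = (1, 5, 25),
    roles: tuple[Role, ...] = (Role.CD8, Role.CD163),
    resolution_um_per_px: float = 0.346,
) -> pd.DataFrame:
    """Estimated cell count for k disjoint disks of each role's diameter.

    Disks are rasterized on a grid at the given resolution with centers
    far apart; the pixel->area->count conversion should recover k within
    pixelation error.  Returns columns ``class, k, estimated, rel_err``.
    """
    geometry = CellGeometry()
    rows = []
    for role in roles:
        radius_px = (geometry.diameter_um[role] / 2.0) / resolution_um_per_px
        n = int(np.ceil(radius_px))
        pitch = 4 * n
        for k in ks:
            side = int(np.ceil(np.sqrt(k)))
            grid = np.zeros((side * pitch + 2 * n, side * pitch + 2 * n), dtype=bool)
            placed = 0
            for i in range(side):
                for j in range(side):
                    if placed == k:
                        break
                    cy, cx = n + i * pitch + n, n + j * pitch + n
                    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
                    keep = dr * dr + dc * dc <= radius_px * radius_px
                    grid[cy + dr[keep], cx + dc[keep]] = True
                    placed += 1
            est = estimate_cell_count(int(grid.sum()), role, geometry, resolution_um_per_px)
            rows.append(
                {"class": role.value, "k": k, "estimated": est,
                 "rel_err": abs(est - k) / k}
            )
    return pd.DataFrame(rows)


def cohort_config(
    cd8_modulation: float = 0.2,
    seed: int = 0,
    image_px: int = 1200,
    n_nests: int = 10,
) -> SyntheticConfig:
    """Study conditions for cohort-level experiments.

    ~1.2 x 1.2 mm regions at 1.0 um/px with ten tumor nests (radius
    70 +/- 15 um), half the nest area K17-positive, immune intensities of
    a few hundred cells/mm^2 in the K17-negative peritumoral zone and the
    CD8 intensity multiplied by ``cd8_modulation`` in K17-positive
    territory (0.2 models the exclusion effect; 1.0 is the no-effect
    null).
    """
    return SyntheticConfig(
        image_hw_px=(image_px, image_px),
        resolution_um_per_px=1.0,
        n_nests=n_nests,
        nest_radius_um=(70.0, 15.0),
        k17pos_fraction=0.5,
        base_intensity={Role.CD4: 200.0, Role.CD8: 500.0,
                        Role.CD16: 200.0, Role.CD163: 400.0},
        zone_modulation={Role.CD4: 1.0, Role.CD8: cd8_modulation,
                         Role.CD16: 1.0, Role.CD163: 1.0},
        intra_fraction=0.25,
        seed=seed,
    )


def _score_cohort(cases) -> pd.DataFrame:
    frames = []
    for case_id, mask in cases:
        zonemap = assign_zones(mask)
        frames.append(compute_zone_scores(mask, zonemap, case_id=case_id))
    return pd.concat(frames, ignore_index=True)


def run_parameter_recovery(
    n_cases: int = 50,
    seed: int = 0,
    cd8_modulation: float = 0.2,
) -> dict:
    """Recover a generator-imposed CD8 exclusion at cohort level.

    Simulates ``n_cases`` with the given CD8 modulation in K17-positive
    territory, runs the full partition/score pipeline, and summarizes the
    CD8 peritumoral and intratumoral contrasts.  Returns the cohort table
    plus headline numbers for CD8.
    """
    cfg = cohort_config(cd8_modulation=cd8_modulation, seed=seed)
    cases, truth = simulate_cohort(cfg, n_cases, seed=seed)
    scores = _score_cohort(cases)
    ratios = normalized_ratios(scores)
    cohort = cohort_summary(ratios)
    cd8 = cohort[cohort["class"] == "CD8"].set_index("compartment")
    out = {
        "cohort": cohort,
        "ratios": ratios,
        "scores": scores,
        "truth": truth,
        "n_cases": n_cases,
        "fraction_higher_in_neg_peri": float(cd8.loc["peri", "fraction_higher_in_neg"]),
        "fraction_higher_in_neg_intra": float(cd8.loc["intra", "fraction_higher_in_neg"]),
        "paired_t_p_peri": float(cd8.loc["peri", "p_value"]),
        "paired_t_p_intra": float(cd8.loc["intra", "p_value"]),
    }
    return out


def run_null_calibration(
    n_cases: int = 20,
    n_reps: int = 99,
    seed: int = 0,
) -> dict:
    """Calibration of the randomization null under a no-effect generator.

    Simulates cases with modulation 1.0 (immune intensity independent of
    K17 status), runs the randomization null per case, and KS-tests the
    CD8 peritumoral empirical p values against the uniform distribution.
    """
    from dataclasses import replace

    cfg = cohort_config(cd8_modulation=1.0, seed=seed, image_px=700, n_nests=6)
    cfg = replace(cfg, nest_radius_um=(60.0, 12.0))
    cases, _ = simulate_cohort(cfg, n_cases, seed=seed)
    child = np.random.SeedSequence(seed).spawn(n_cases)
    pvals = []
    for i, (case_id, mask) in enumerate(cases):
        zonemap = assign_zones(mask)
        scores = compute_zone_scores(mask, zonemap, case_id=case_id)
        res = randomization_null(
            mask, zonemap, scores, n_reps=n_reps,
            seed=int(child[i].generate_state(1)[0] % (2**31)),
        )
        row = res.summary[
            (res.summary["class"] == "CD8") & (res.summary["compartment"] == "peri")
        ]
        if len(row):
            pvals.append(float(row["p_value"].iloc[0]))
    ks_stat, ks_p = sps.kstest(pvals, "uniform")
    return {"p_values": pvals, "ks_stat": float(ks_stat), "ks_p": float(ks_p),
            "n_cases": n_cases, "n_reps": n_reps}
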