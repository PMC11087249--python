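"""End-to-end cohort orchestration: simulate/load, partition, score, test.

A single config drives the whole run; outputs are tidy CSVs plus a JSON
manifest recording parameters, seeds and versions so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classes import IMMUNE_ROLES, LabelMask, Role
from .mask_io import read_label_mask, write_label_mask
from .scoring import CellGeometry, compute_zone_scores, normalized_ratios
from .stats import cohort_summary, randomization_null
from .synthetic import SyntheticConfig, simulate_cohort
from .zones import assign_zones

__all__ = ["PipelineConfig", "run_cohort"]

log = logging.getLogger("immune_topo")


@dataclass
class PipelineConfig:
    """Configuration of a full cohort run.

    Exactly one of ``synthetic`` (generator config) or ``mask_paths``
    (pre-segmented masks on disk) must be set.
    """

    synthetic: SyntheticConfig | None = None
    mask_paths: list[str] = field(default_factory=list)
    n_cases: int = 10
    effect_prevalence: dict | None = None
    depth_um: float = 25.0
    contact_um: float | None = None
    null_reps: int = 0
    seed: int = 0
    out_dir: str = "immune_topo_out"
    write_zonemaps: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (not self.mask_paths):
            raise ValueError("set exactly one of synthetic config or mask_paths")
        if self.contact_um is not None and not (0 < self.contact_um < self.depth_um):
            raise ValueError("need depth_um > contact_um > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            for key in ("base_intensity", "zone_modulation"):
                if key in syn:
                    syn[key] = {Role(k): float(v) for k, v in syn[key].items()}
            if "image_hw_px" in syn:
                syn["image_hw_px"] = tuple(syn["image_hw_px"])
            if "nest_radius_um" in syn:
                syn["nest_radius_um"] = tuple(syn["nest_radius_um"])
            syn = SyntheticConfig(**syn)
        prev = raw.pop("effect_prevalence", None)
        if prev is not None:
            prev = {Role(k): float(v) for k, v in prev.items()}
        return cls(synthetic=syn, effect_prevalence=prev, **raw)


def _write_zonemap_png(zonemap, path: Path) -> None:
    from PIL import Image

    img = Image.fromarray(zonemap.grid.astype(np.uint8), mode="P")
    # legend colors: tumor red/blue family, contact/peri shades, gray outside
    palette = [0] * 768
    colors = {
        1: (178, 24, 43), 2: (33, 102, 172), 3: (244, 165, 130),
        4: (146, 197, 222), 5: (253, 219, 199), 6: (209, 229, 240),
        7: (240, 240, 240), 8: (80, 80, 80),
    }
    for code, (r, g, b) in colors.items():
        palette[3 * code : 3 * code + 3] = [r, g, b]
    img.putpalette(palette)
    img.save(path)
    legend = {str(k): name for k, name in {
        1: "TUMOR_POS", 2: "TUMOR_NEG", 3: "CONTACT_POS", 4: "CONTACT_NEG",
        5: "PERI_POS", 6: "PERI_NEG", 7: "OUTSIDE_BAND", 8: "EXCLUDED"}.items()}
    path.with_suffix(".json").write_text(json.dumps(legend, indent=1))


def run_cohort(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the output bundle.

    Returns a dict of the in-memory result tables (``scores``, ``ratios``,
    ``cohort``, optionally ``truth`` and ``null``) that were also written
    to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = CellGeometry()

    if config.synthetic is not None:
        cases, truth = simulate_cohort(
            config.synthetic, config.n_cases, seed=config.seed,
            effect_prevalence=config.effect_prevalence,
        )
    else:
        cases = [(Path(p).stem, read_label_mask(p)) for p in config.mask_paths]
        truth = None

    score_frames, null_frames = [], []
    if config.write_zonemaps:
        (out / "zonemaps").mkdir(exist_ok=True)
    for case_index, (case_id, mask) in enumerate(cases):
        try:
            zonemap = assign_zones(mask, depth_um=config.depth_um, contact_um=config.contact_um)
            scores = compute_zone_scores(mask, zonemap, geometry, case_id=case_id)
        except Exception as exc:  # abort with stage and case context
            raise RuntimeError(f"zone scoring failed for {case_id}: {exc}") from exc
        score_frames.append(scores)
        if config.write_zonemaps:
            _write_zonemap_png(zonemap, out / "zonemaps" / f"{case_id}.png")
        if config.null_reps > 0:
            null = randomization_null(
                mask, zonemap, scores, n_reps=config.null_reps,
                seed=int(np.random.SeedSequence([config.seed, case_index]).generate_state(1)[0] % (2**31)),
                geometry=geometry,
            )
            summ = null.summary.copy()
            summ.insert(0, "case_id", case_id)
            null_frames.append(summ)
        log.info("scored %s", case_id)

    scores = pd.concat(score_frames, ignore_index=True)
    ratios = normalized_ratios(scores)
    cohort = cohort_summary(ratios)

    scores.to_csv(out / "scores.csv", index=False)
    ratios.to_csv(out / "ratios.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    result = {"scores": scores, "ratios": ratios, "cohort": cohort}
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
        result["truth"] = truth
    if null_frames:
        nulls = pd.concat(null_frames, ignore_index=True)
        nulls.to_csv(out / "null.csv", index=False)
        result["null"] = nulls

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_cases": len(cases),
        "depth_um": config.depth_um,
        "contact_um": config.contact_um,
        "null_reps": config.null_reps,
        "input": "synthetic" if config.synthetic is not None else "masks",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
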