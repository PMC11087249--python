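"""Synthetic tumor-microenvironment masks with known ground truth.

Emulates the *output* of a multi-class segmentation ensemble on mIHC
regions: tumor nests (unions of random ellipses) whose pixels are split
into contiguous K17-positive and K17-negative subregions, surrounded by a
stromal band in which immune cells appear as filled disks (8 um
lymphocytes, 16 um macrophages) placed by an inhomogeneous Poisson process.
The intensity at a stromal point is ``base_intensity * zone_modulation``
when the *nearest tumor boundary* is K17-positive and ``base_intensity``
otherwise — so a modulation below 1 models immune exclusion from
K17-positive territory.  Intensities are defined on the generator's own
nearest-boundary zones, keeping downstream recovery tests non-circular.

Each simulated case returns the mask plus a truth table of placed-cell
counts and zone areas per (immune class, marker, compartment); cells are
attributed by disk center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import (
    DEFAULT_RESOLUTION_UM_PER_PX,
    IMMUNE_ROLES,
    ClassTable,
    LabelMask,
    Role,
)
from .scoring import CellGeometry
from .zones import TIE_TOL_UM, default_contact_um

__all__ = [
    "SyntheticConfig",
    "simulate_case",
    "simulate_cohort",
    "expected_densities",
]

_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-mask generator.

    Defaults mimic a scanner-resolution mIHC inference patch (580 x 580 px
    at 0.346 um/px) with a few tumor nests and immune intensities in the
    hundreds of cells per mm^2 of tumor-associated stroma, typical of an
    immune-infiltrated carcinoma region.
    """

    image_hw_px: tuple[int, int] = (580, 580)
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    n_nests: int = 3
    nest_radius_um: tuple[float, float] = (40.0, 10.0)  # mean, sd
    k17pos_fraction: float = 0.5
    base_intensity: dict = field(
        default_factory=lambda: {Role.CD4: 200.0, Role.CD8: 500.0,
                                 Role.CD16: 200.0, Role.CD163: 400.0}
    )
    zone_modulation: dict = field(
        default_factory=lambda: {r: 1.0 for r in IMMUNE_ROLES}
    )
    intra_fraction: float = 0.25
    band_depth_um: float = 25.0
    contact_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_intensity.values()):
            raise ValueError("intensities must be >= 0")
        if any(v < 0 for v in self.zone_modulation.values()):
            raise ValueError("zone modulation factors must be >= 0")
        if not (0.0 <= self.k17pos_fraction <= 1.0):
            raise ValueError("k17pos_fraction must lie in [0, 1]")
        if not (0.0 <= self.intra_fraction < 1.0):
            raise ValueError("intra_fraction must lie in [0, 1)")


def expected_densities(config: SyntheticConfig) -> dict:
    """Closed-form expected peritumoral densities (cells/mm^2) per zone.

    Keys are ``(class_name, marker)`` with marker ``"K17+"`` or ``"K17-"``;
    the K17+ value is ``base * modulation``, the K17- value is ``base``.
    """
    out = {}
    for role in IMMUNE_ROLES:
        base = float(config.base_intensity.get(role, 0.0))
        mod = float(config.zone_modulation.get(role, 1.0))
        out[(role.value, "K17+")] = base * mod
        out[(role.value, "K17-")] = base
    return out


def _draw_nests(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_hw_px
    res = cfg.resolution_um_per_px
    mean_r, sd_r = cfg.nest_radius_um
    tumor = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_nests):
        a = max(8.0, rng.normal(mean_r, sd_r)) / res  # semi-axes in px
        b = max(8.0, rng.normal(mean_r, sd_r)) / res
        theta = rng.uniform(0, np.pi)
        m = max(a, b)
        cy = rng.uniform(m, h - m) if h > 2 * m else h / 2
        cx = rng.uniform(m, w - m) if w > 2 * m else w / 2
        dy, dx = rr - cy, cc - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        tumor |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return tumor


def _split_k17(tumor: np.ndarray, frac_pos: float, rng: np.random.Generator) -> np.ndarray:
    """Split each connected nest into contiguous K17+/K17- parts.

    Pixels are ranked by projection onto a random direction; the top
    ``frac_pos`` of each nest becomes K17-positive — a straight-line cut,
    hence contiguous for the convex-ish nest shapes used here.
    """
    k17pos = np.zeros_like(tumor)
    labels, n = ndimage.label(tumor, structure=np.ones((3, 3)))
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i)
        if frac_pos <= 0:
            continue
        if frac_pos >= 1:
            k17pos[tuple(coords.T)] = True
            continue
        ang = rng.uniform(0, 2 * np.pi)
        proj = coords[:, 0] * np.cos(ang) + coords[:, 1] * np.sin(ang)
        thr = np.quantile(proj, 1.0 - frac_pos)
        sel = coords[proj >= thr]
        k17pos[tuple(sel.T)] = True
    return k17pos


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.ceil(radius_px))
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    keep = dr * dr + dc * dc <= radius_px * radius_px
    return dr[keep], dc[keep]


def _weighted_index_sampler(weights: np.ndarray, rng: np.random.Generator):
    cum = np.cumsum(weights)
    total = cum[-1]

    def draw() -> int:
        return int(np.searchsorted(cum, rng.random() * total, side="right"))

    return draw


def simulate_case(
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence | None = None,
    case_id: str = "case0",
) -> tuple[LabelMask, pd.DataFrame]:
    """Simulate one mask and its ground-truth table.

    Returns ``(mask, truth)`` where ``truth`` has one row per
    (class, marker, compartment) with the placed-cell count and the true
    zone area in um^2.  Deterministic for a fixed config and seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.image_hw_px
    res = cfg.resolution_um_per_px
    contact_um = cfg.contact_um if cfg.contact_um is not None else default_contact_um(res)
    geometry = CellGeometry()
    table = ClassTable()

    tumor = _draw_nests(cfg, rng)
    if not tumor.any():
        raise ValueError("no tumor generated; enlarge nests or image")
    k17pos = _split_k17(tumor, cfg.k17pos_fraction, rng)
    k17neg = tumor & ~k17pos

    grid = np.zeros((h, w), dtype=np.uint8)
    grid[k17pos] = table.code(Role.TUMOR_K17POS)
    grid[k17neg] = table.code(Role.TUMOR_K17NEG)

    # generator's own zones: nearest-marker attribution within the band
    def dist(src: np.ndarray) -> np.ndarray:
        if not src.any():
            return np.full((h, w), np.inf)
        return ndimage.distance_transform_edt(~src) * res

    d_pos, d_neg = dist(k17pos), dist(k17neg)
    dmin = np.minimum(d_pos, d_neg)
    pos_side = d_pos <= d_neg + TIE_TOL_UM
    stroma = ~tumor
    contact = stroma & (dmin <= contact_um)
    peri = stroma & (dmin <= cfg.band_depth_um) & ~contact

    px_area_mm2 = (res / 1000.0) ** 2
    zone_areas_um2 = {
        ("K17+", "intra"): float(np.sum(contact & pos_side)) * res * res,
        ("K17-", "intra"): float(np.sum(contact & ~pos_side)) * res * res,
        ("K17+", "peri"): float(np.sum(peri & pos_side)) * res * res,
        ("K17-", "peri"): float(np.sum(peri & ~pos_side)) * res * res,
    }

    peri_idx = np.argwhere(peri)
    contact_idx = np.argwhere(contact)
    peri_pos = pos_side[tuple(peri_idx.T)] if len(peri_idx) else np.zeros(0, bool)
    contact_pos = pos_side[tuple(contact_idx.T)] if len(contact_idx) else np.zeros(0, bool)

    accepted_rc: list[tuple[float, float]] = []
    accepted_r_um: list[float] = []
    counts: dict[tuple[str, str, str], int] = {}
    placements: list[tuple[int, int, Role]] = []

    for role in IMMUNE_ROLES:
        base = float(cfg.base_intensity.get(role, 0.0))
        mod = float(cfg.zone_modulation.get(role, 1.0))
        if base == 0.0 or len(peri_idx) == 0:
            continue
        radius_um = geometry.diameter_um[role] / 2.0
        w_peri = np.where(peri_pos, mod, 1.0)
        e_peri = base * px_area_mm2 * float(np.sum(w_peri))
        n_peri = int(rng.poisson(e_peri))
        n_contact = 0
        w_contact = np.zeros(0)
        if cfg.intra_fraction > 0 and len(contact_idx) > 0:
            e_contact = e_peri * cfg.intra_fraction / (1.0 - cfg.intra_fraction)
            n_contact = int(rng.poisson(e_contact))
            w_contact = np.where(contact_pos, mod, 1.0)

        for n_cells, idx, draw_w in (
            (n_peri, peri_idx, w_peri),
            (n_contact, contact_idx, w_contact),
        ):
            if n_cells == 0:
                continue
            sampler = _weighted_index_sampler(draw_w, rng)
            for _ in range(n_cells):
                for attempt in range(_MAX_ATTEMPTS):
                    r, c = idx[sampler()]
                    if accepted_rc:
                        arr = np.asarray(accepted_rc)
                        d_um = np.hypot(arr[:, 0] - r, arr[:, 1] - c) * res
                        min_d = np.asarray(accepted_r_um) + radius_um
                        if np.any(d_um < min_d):
                            continue
                    break
                else:
                    raise ValueError(
                        "rejection sampling failed to place an immune cell; "
                        "lower base_intensity or enlarge the image"
                    )
                accepted_rc.append((float(r), float(c)))
                accepted_r_um.append(radius_um)
                placements.append((int(r), int(c), role))
                marker = "K17+" if pos_side[r, c] else "K17-"
                compartment = "intra" if contact[r, c] else "peri"
                key = (role.value, marker, compartment)
                counts[key] = counts.get(key, 0) + 1

    # rasterize disks; cells never overwrite tumor (or each other)
    for r, c, role in placements:
        dr, dc = _disk_offsets((geometry.diameter_um[role] / 2.0) / res)
        rr2, cc2 = r + dr, c + dc
        keep = (rr2 >= 0) & (rr2 < h) & (cc2 >= 0) & (cc2 < w)
        rr2, cc2 = rr2[keep], cc2[keep]
        writable = grid[rr2, cc2] == table.code(Role.STROMA)
        grid[rr2[writable], cc2[writable]] = table.code(role)

    rows = []
    for role in IMMUNE_ROLES:
        for marker in ("K17+", "K17-"):
            for compartment in ("intra", "peri"):
                rows.append(
                    {
                        "case_id": case_id,
                        "class": role.value,
                        "marker": marker,
                        "compartment": compartment,
                        "true_count": counts.get((role.value, marker, compartment), 0),
                        "true_zone_area_um2": zone_areas_um2[(marker, compartment)],
                        "base_intensity_per_mm2": float(cfg.base_intensity.get(role, 0.0)),
                        "zone_modulation": float(cfg.zone_modulation.get(role, 1.0)),
                    }
                )
    truth = pd.DataFrame(rows)
    mask = LabelMask(grid, res, table)
    return mask, truth


def simulate_cohort(
    config: SyntheticConfig,
    n_cases: int,
    seed: int | None = None,
    effect_prevalence: dict | None = None,
) -> tuple[list[tuple[str, LabelMask]], pd.DataFrame]:
    """Simulate a cohort of cases with per-case seeds from one master seed.

    ``effect_prevalence`` optionally maps an immune role to the fraction of
    cases carrying the configured ``zone_modulation`` for that role; the
    remaining cases get modulation 1.0.  The truth table records, per case
    and class, whether the effect was applied (``has_effect``).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    case_seeds = master.spawn(n_cases + 1)
    assign_rng = np.random.default_rng(case_seeds[-1])
    effect_prevalence = effect_prevalence or {}

    cases, truths = [], []
    for i in range(n_cases):
        case_id = f"case{i:03d}"
        mod = dict(config.zone_modulation)
        has_effect = {}
        for role in IMMUNE_ROLES:
            if role in effect_prevalence:
                carry = bool(assign_rng.random() < effect_prevalence[role])
                has_effect[role.value] = carry
                if not carry:
                    mod[role] = 1.0
            else:
                has_effect[role.value] = mod.get(role, 1.0) != 1.0
        cfg_i = replace(config, zone_modulation=mod)
        mask, truth = simulate_case(cfg_i, seed=case_seeds[i], case_id=case_id)
        truth["has_effect"] = truth["class"].map(has_effect)
        cases.append((case_id, mask))
        truths.append(truth)
    return cases, pd.concat(truths, ignore_index=True)
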