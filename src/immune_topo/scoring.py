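"""Tumor/Stromal Zone Scores: pixel counts -> cell counts -> densities.

The zone score for immune class ``i_c`` and tumor marker ``M`` (K17+ or
K17-) is the estimated number of cells of that class inside the zone of
influence of ``M``, divided by the zone's area:

    ZS[M, i_c] = CellCount[M, i_c] / ZoneArea[M]

Cell counts are estimated from class pixel counts: pixels are converted to
um^2 and divided by the average single-cell area, approximating lymphocytes
(CD4, CD8) as 8 um diameter circles and macrophages (CD16, CD163) as 16 um
circles.  Scores are reported per mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np
import pandas as pd

from .classes import IMMUNE_ROLES, LabelMask, Role
from .zones import ZoneLabel, ZoneMap

__all__ = [
    "CellGeometry",
    "estimate_cell_count",
    "compute_zone_scores",
    "normalized_ratios",
    "digital_k17_score",
    "K17_HIGH_THRESHOLD_PCT",
]

#: digital K17 score at or above this percent classifies a case as K17-high
K17_HIGH_THRESHOLD_PCT = 10.0

_DEFAULT_DIAMETERS = {
    Role.CD4: 8.0,
    Role.CD8: 8.0,
    Role.CD16: 16.0,
    Role.CD163: 16.0,
}


@dataclass(frozen=True)
class CellGeometry:
    """Average immune-cell dimensions used for pixel->count conversion."""

    diameter_um: dict = field(default_factory=lambda: dict(_DEFAULT_DIAMETERS))

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameter_um.values()):
            raise ValueError("cell diameters must be positive")

    def area_um2(self, role: Role) -> float:
        d = self.diameter_um[role]
        return pi * (d / 2.0) ** 2


def estimate_cell_count(
    immune_pixel_count: int,
    role: Role,
    geometry: CellGeometry | None = None,
    resolution_um_per_px: float = 0.346,
) -> float:
    """Estimated number of cells from a class pixel count.

    ``count = pixels * resolution^2 / single_cell_area``.
    """
    if immune_pixel_count < 0:
        raise ValueError("pixel count must be >= 0")
    geometry = geometry or CellGeometry()
    if role not in geometry.diameter_um:
        raise KeyError(f"no cell geometry for role {role}")
    area_um2 = immune_pixel_count * resolution_um_per_px ** 2
    return area_um2 / geometry.area_um2(role)


_MARKER_ZONES = {
    "K17+": (ZoneLabel.TUMOR_POS, ZoneLabel.CONTACT_POS, ZoneLabel.PERI_POS),
    "K17-": (ZoneLabel.TUMOR_NEG, ZoneLabel.CONTACT_NEG, ZoneLabel.PERI_NEG),
}


def compute_zone_scores(
    mask: LabelMask,
    zonemap: ZoneMap,
    geometry: CellGeometry | None = None,
    case_id: str = "case",
) -> pd.DataFrame:
    """Zone scores for every (immune class, marker, compartment) triple.

    Peritumoral: numerator pixels are immune pixels of the class carrying
    the PERI_M zone label; the denominator is the whole PERI_M band area
    (immune pixels are stromal and stay in the denominator).  Intratumoral:
    numerator pixels carry the CONTACT_M label; the denominator is the
    tumor territory of M plus its contact shell.  Records whose denominator
    is empty are omitted; up to 16 records per case.

    Returns a tidy frame with columns ``case_id, class, marker,
    compartment, pixels, area_um2, cells, zone_area_um2, score_per_mm2``.
    """
    if mask.shape != zonemap.grid.shape:
        raise ValueError("mask and zone map shapes differ")
    geometry = geometry or CellGeometry()
    res2 = mask.pixel_area_um2
    zg = zonemap.grid
    rows = []
    for marker, (tumor_l, contact_l, peri_l) in _MARKER_ZONES.items():
        peri_area = float(np.sum(zg == int(peri_l))) * res2
        intra_area = float(np.sum((zg == int(tumor_l)) | (zg == int(contact_l)))) * res2
        for role in IMMUNE_ROLES:
            cells_px = mask.role_mask(role)
            for compartment, numer_label, denom in (
                ("peri", peri_l, peri_area),
                ("intra", contact_l, intra_area),
            ):
                if denom <= 0:
                    continue
                npx = int(np.sum(cells_px & (zg == int(numer_label))))
                area = npx * res2
                cells = area / geometry.area_um2(role)
                rows.append(
                    {
                        "case_id": case_id,
                        "class": role.value,
                        "marker": marker,
                        "compartment": compartment,
                        "pixels": npx,
                        "area_um2": area,
                        "cells": cells,
                        "zone_area_um2": denom,
                        "score_per_mm2": cells / denom * 1e6,
                    }
                )
    return pd.DataFrame(rows)


def normalized_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Per (case, class, compartment) ratio ZS[K17-] / ZS[K17+].

    A zero K17+ score makes the ratio undefined; such records are kept
    with ``status='undefined_zero_denominator'`` so raw-score statistics
    can still use the case, while ratio plots exclude it.  Missing pairs
    are skipped.
    """
    rows = []
    key = ["case_id", "class", "compartment"]
    for (case, cls, comp), grp in records.groupby(key):
        by_marker = {m: g for m, g in grp.groupby("marker")}
        if "K17+" not in by_marker or "K17-" not in by_marker:
            continue
        zs_pos = float(by_marker["K17+"]["score_per_mm2"].iloc[0])
        zs_neg = float(by_marker["K17-"]["score_per_mm2"].iloc[0])
        if zs_pos == 0.0:
            rows.append(
                {
                    "case_id": case, "class": cls, "compartment": comp,
                    "zs_pos": zs_pos, "zs_neg": zs_neg,
                    "ratio": np.nan, "status": "undefined_zero_denominator",
                }
            )
        else:
            rows.append(
                {
                    "case_id": case, "class": cls, "compartment": comp,
                    "zs_pos": zs_pos, "zs_neg": zs_neg,
                    "ratio": zs_neg / zs_pos, "status": "valid",
                }
            )
    return pd.DataFrame(rows)


def digital_k17_score(mask: LabelMask) -> tuple[float, str]:
    """Percent of tumor pixels that are K17-positive, with high/low call.

    ``high`` when the score is at or above 10% (boundary inclusive).
    """
    pos = int(np.sum(mask.role_mask(Role.TUMOR_K17POS)))
    neg = int(np.sum(mask.role_mask(Role.TUMOR_K17NEG)))
    total = pos + neg
    if total == 0:
        raise ValueError("no tumor pixels; K17 score undefined")
    pct = 100.0 * pos / total
    return pct, ("high" if pct >= K17_HIGH_THRESHOLD_PCT else "low")
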