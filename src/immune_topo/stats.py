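"""Cohort-level statistics and the spatial randomization null.

Paired two-sided t tests compare per-case zone scores between K17-negative
and K17-positive territory; the headline cohort summary is the fraction of
cases in which the K17-negative score strictly exceeds the K17-positive
one.  The randomization null re-places each case's estimated immune-cell
equivalents uniformly over the tumor-associated stroma (contact and
peritumoral pixels of both markers pooled) and asks how often the observed
|ZS(K17-) - ZS(K17+)| is matched by chance; the empirical p uses the
add-one estimator so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classes import IMMUNE_ROLES, LabelMask, Role
from .scoring import CellGeometry
from .zones import ZoneLabel, ZoneMap

__all__ = [
    "TestResult",
    "paired_t_test",
    "fraction_cases_higher",
    "spearman_corr",
    "randomization_null",
    "NullResult",
    "cohort_summary",
]


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def paired_t_test(scores_pos, scores_neg) -> TestResult:
    """Two-sided paired t test on per-case differences (neg - pos).

    Degenerate inputs follow a fixed contract: all differences exactly
    zero -> ``(0, 1, degenerate)``; nonzero but constant differences ->
    ``(signed inf, 0, degenerate)``.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError("paired vectors must have equal length")
    if pos.ndim != 1 or len(pos) < 2:
        raise ValueError("need at least 2 pairs")
    d = neg - pos
    if np.all(d == 0.0):
        return TestResult(0.0, 1.0, True)
    if np.all(d == d[0]):
        return TestResult(float(np.sign(d[0])) * np.inf, 0.0, True)
    t, p = sps.ttest_rel(neg, pos)
    return TestResult(float(t), float(p), False)


def fraction_cases_higher(ratio_records: pd.DataFrame) -> float:
    """Share of cases with ZS(K17-) strictly above ZS(K17+).

    Operates on the output of :func:`immune_topo.scoring.normalized_ratios`
    for one (class, compartment); undefined-ratio cases are excluded from
    numerator and denominator, and exact ties count as not-higher.
    """
    valid = ratio_records[ratio_records["status"] == "valid"]
    if len(valid) == 0:
        raise ValueError("no valid ratio records")
    return float(np.mean(valid["zs_neg"].to_numpy() > valid["zs_pos"].to_numpy()))


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    A constant input vector leaves rho undefined; flagged degenerate with
    NaN statistic rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(float("nan"), float("nan"), True)
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), False)


@dataclass
class NullResult:
    """Outcome of the randomization null for one case."""

    summary: pd.DataFrame     # class, compartment, observed, p, n_reps, seed
    replicates: pd.DataFrame  # rep, class, compartment, stat, n_placed


_ADMISSIBLE = (
    ZoneLabel.CONTACT_POS,
    ZoneLabel.CONTACT_NEG,
    ZoneLabel.PERI_POS,
    ZoneLabel.PERI_NEG,
)

_ZONE_OF = {
    ("K17+", "peri"): ZoneLabel.PERI_POS,
    ("K17-", "peri"): ZoneLabel.PERI_NEG,
    ("K17+", "intra"): ZoneLabel.CONTACT_POS,
    ("K17-", "intra"): ZoneLabel.CONTACT_NEG,
}


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(np.ceil(radius_px))
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    keep = dr * dr + dc * dc <= radius_px * radius_px
    return dr[keep], dc[keep]


def randomization_null(
    mask: LabelMask,
    zonemap: ZoneMap,
    observed_records: pd.DataFrame,
    n_reps: int = 199,
    seed: int | None = 0,
    geometry: CellGeometry | None = None,
) -> NullResult:
    """Empirical null for the K17-negative vs K17-positive score contrast.

    Each replicate redistributes every immune class's estimated cell
    equivalents — as disks of the class geometry — uniformly over the
    pooled admissible stroma (contact and peritumoral pixels of both
    markers), holding the per-case, per-class total fixed, then recomputes
    the zone scores on the fixed zone map.  The statistic per class and
    compartment is |ZS(K17-) - ZS(K17+)|; ``p = (1 + #{null >= observed})
    / (1 + n_reps)``.
    """
    if n_reps < 19:
        raise ValueError("n_reps must be >= 19")
    geometry = geometry or CellGeometry()
    rng = np.random.default_rng(seed)
    res = mask.resolution_um_per_px
    res2 = mask.pixel_area_um2
    zg = zonemap.grid
    h, w = zg.shape

    admissible = np.isin(zg, [int(l) for l in _ADMISSIBLE])
    adm_idx = np.argwhere(admissible)
    if len(adm_idx) == 0:
        raise ValueError("no admissible stromal territory")

    # fixed per-class totals (cell equivalents) from the observed records
    totals: dict[Role, int] = {}
    for role in IMMUNE_ROLES:
        sub = observed_records[observed_records["class"] == role.value]
        totals[role] = int(round(float(sub["cells"].sum())))
    total_cell_area = sum(
        totals[r] * geometry.area_um2(r) for r in IMMUNE_ROLES
    )
    if total_cell_area > len(adm_idx) * res2:
        raise ValueError("admissible territory smaller than total cell area")

    zone_areas = {
        key: float(np.sum(zg == int(lbl))) * res2 for key, lbl in _ZONE_OF.items()
    }
    intra_denoms = {
        "K17+": float(np.sum((zg == int(ZoneLabel.TUMOR_POS)) | (zg == int(ZoneLabel.CONTACT_POS)))) * res2,
        "K17-": float(np.sum((zg == int(ZoneLabel.TUMOR_NEG)) | (zg == int(ZoneLabel.CONTACT_NEG)))) * res2,
    }

    def scores_from_pixels(pix_per_zone: dict, role: Role) -> dict:
        out = {}
        for (marker, compartment), lbl in _ZONE_OF.items():
            denom = (
                intra_denoms[marker] if compartment == "intra"
                else zone_areas[(marker, compartment)]
            )
            if denom <= 0:
                out[(marker, compartment)] = np.nan
                continue
            cells = pix_per_zone.get(int(lbl), 0) * res2 / geometry.area_um2(role)
            out[(marker, compartment)] = cells / denom * 1e6
        return out

    # observed statistics
    obs_stats: dict[tuple[str, str], float] = {}
    for role in IMMUNE_ROLES:
        for compartment in ("peri", "intra"):
            sub = observed_records[
                (observed_records["class"] == role.value)
                & (observed_records["compartment"] == compartment)
            ]
            by = {m: float(g["score_per_mm2"].iloc[0]) for m, g in sub.groupby("marker")}
            if "K17+" in by and "K17-" in by:
                obs_stats[(role.value, compartment)] = abs(by["K17-"] - by["K17+"])

    disk_cache = {r: _disk_offsets((geometry.diameter_um[r] / 2.0) / res) for r in IMMUNE_ROLES}
    rep_rows = []
    for rep in range(n_reps):
        for role in IMMUNE_ROLES:
            n = totals[role]
            pix_per_zone: dict[int, int] = {}
            if n > 0:
                centers = adm_idx[rng.integers(0, len(adm_idx), size=n)]
                dr, dc = disk_cache[role]
                rr = (centers[:, 0][:, None] + dr[None, :]).ravel()
                cc = (centers[:, 1][:, None] + dc[None, :]).ravel()
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                flat = np.unique(rr[keep] * w + cc[keep])  # union of disks
                labels = zg.ravel()[flat]
                # disks never overwrite tumor; pixels on tumor are clipped
                labels = labels[
                    (labels != int(ZoneLabel.TUMOR_POS)) & (labels != int(ZoneLabel.TUMOR_NEG))
                ]
                binc = np.bincount(labels, minlength=16)
                pix_per_zone = {int(l): int(binc[int(l)]) for l in _ADMISSIBLE}
            sc = scores_from_pixels(pix_per_zone, role)
            for compartment in ("peri", "intra"):
                a = sc.get(("K17+", compartment), np.nan)
                b = sc.get(("K17-", compartment), np.nan)
                rep_rows.append(
                    {
                        "rep": rep,
                        "class": role.value,
                        "compartment": compartment,
                        "stat": abs(b - a) if np.isfinite(a) and np.isfinite(b) else np.nan,
                        "n_placed": n,
                    }
                )
    reps = pd.DataFrame(rep_rows)

    sum_rows = []
    for (cls, compartment), obs in obs_stats.items():
        null_stats = reps[
            (reps["class"] == cls) & (reps["compartment"] == compartment)
        ]["stat"].dropna().to_numpy()
        if len(null_stats) == 0:
            continue
        p = (1.0 + float(np.sum(null_stats >= obs))) / (1.0 + n_reps)
        sum_rows.append(
            {
                "class": cls,
                "compartment": compartment,
                "observed": obs,
                "p_value": p,
                "n_reps": n_reps,
                "seed": seed,
            }
        )
    return NullResult(pd.DataFrame(sum_rows), reps)


def cohort_summary(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per (class, compartment) cohort statistics from ratio records.

    Columns: ``class, compartment, n_cases, fraction_higher_in_neg,
    t_statistic, p_value, degenerate``.
    """
    rows = []
    for (cls, comp), grp in ratios.groupby(["class", "compartment"]):
        valid = grp[grp["status"] == "valid"]
        if len(valid) == 0:
            continue
        frac = fraction_cases_higher(grp)
        if len(valid) >= 2:
            t, p, flag = paired_t_test(valid["zs_pos"], valid["zs_neg"])
        else:
            t, p, flag = float("nan"), float("nan"), True
        rows.append(
            {
                "class": cls,
                "compartment": comp,
                "n_cases": int(len(valid)),
                "fraction_higher_in_neg": frac,
                "t_statistic": t,
                "p_value": p,
                "degenerate": flag,
            }
        )
    return pd.DataFrame(rows)
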