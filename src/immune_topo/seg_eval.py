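"""Segmentation evaluation against pathologist dot annotations.

Dots are dilated into fixed-diameter disks (10 um and 5 um by default) and
compared with each class's predicted mask by connected components: a true
positive is a predicted component overlapping any disk; a false positive
is a component overlapping no disk; a false negative is a *dot* whose disk
the prediction misses entirely (disks merged into one blob are still
counted per source dot).  Note the deliberate asymmetry of the component
rule: one predicted component overlapping several disks contributes a
single TP yet clears every one of those dots, so recall can reach 1 with
fewer components than dots.

Counts are aggregated over patches before computing PPV, recall and F1
(micro-averaging), which keeps sparse cell types stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .classes import IMMUNE_ROLES, LabelMask, Role

__all__ = ["dilate_dots", "component_match", "metrics_from_counts", "evaluate"]


def _disk_coords(x: float, y: float, radius_px: int, shape: tuple[int, int]):
    h, w = shape
    n = radius_px
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    keep = dr * dr + dc * dc <= radius_px * radius_px
    rr = (np.rint(y).astype(int) + dr[keep]).astype(int)
    cc = (np.rint(x).astype(int) + dc[keep]).astype(int)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    return rr[ok], cc[ok]


def dilate_dots(
    dots_xy: np.ndarray,
    diameter_um: float,
    resolution_um_per_px: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Union of rasterized disks centered on each dot.

    The pixel radius is the nearest integer to ``(diameter/2)/resolution``;
    a pixel belongs to a disk when its center lies within that radius.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    radius_px = int(round((diameter_um / 2.0) / resolution_um_per_px))
    out = np.zeros(shape, dtype=bool)
    for x, y in np.atleast_2d(np.asarray(dots_xy, dtype=float).reshape(-1, 2)):
        rr, cc = _disk_coords(x, y, radius_px, shape)
        out[rr, cc] = True
    return out


def component_match(
    pred_mask: np.ndarray,
    dots_xy: np.ndarray,
    diameter_um: float,
    resolution_um_per_px: float,
) -> tuple[int, int, int]:
    """TP/FP/FN between a predicted class mask and dilated dot disks.

    Components use 8-connectivity.  FN is counted per source dot: each
    dot's own disk is tested for overlap with the prediction, so disks
    that merge into one blob are still tracked individually.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    dots_xy = np.asarray(dots_xy, dtype=float).reshape(-1, 2)
    disk_union = dilate_dots(dots_xy, diameter_um, resolution_um_per_px, pred_mask.shape) \
        if len(dots_xy) else np.zeros(pred_mask.shape, dtype=bool)

    labels, n_comp = measure.label(pred_mask, connectivity=2, return_num=True)
    if n_comp:
        overlapping = np.unique(labels[disk_union & pred_mask])
        tp = int(np.sum(overlapping > 0))
    else:
        tp = 0
    fp = int(n_comp - tp)

    radius_px = int(round((diameter_um / 2.0) / resolution_um_per_px))
    fn = 0
    for x, y in dots_xy:
        rr, cc = _disk_coords(x, y, radius_px, pred_mask.shape)
        if not pred_mask[rr, cc].any():
            fn += 1
    return tp, fp, fn


def metrics_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """PPV, recall and F1 from aggregated counts.

    Undefined quantities (zero denominators) are NaN; F1 is 0 when either
    PPV or recall is 0, and NaN only when both are undefined.
    """
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    rec = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if np.isnan(ppv) and np.isnan(rec):
        f1 = float("nan")
    elif (not np.isnan(ppv) and ppv == 0.0) or (not np.isnan(rec) and rec == 0.0):
        f1 = 0.0
    elif np.isnan(ppv) or np.isnan(rec):
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * rec / (ppv + rec)
    return ppv, rec, f1


def evaluate(
    pred_masks: list[LabelMask],
    dots_per_patch: list,
    diameters_um: tuple[float, ...] = (10.0, 5.0),
    roles: tuple[Role, ...] = IMMUNE_ROLES,
) -> pd.DataFrame:
    """Micro-averaged detection metrics over a set of test patches.

    ``dots_per_patch`` holds one :class:`~immune_topo.mask_io.DotAnnotationSet`
    per patch (aligned with ``pred_masks``).  TP/FP/FN are summed across
    patches per class and dilation diameter, then PPV/recall/F1 are
    computed once on the sums.
    """
    if len(pred_masks) == 0:
        raise ValueError("need at least one patch")
    if len(pred_masks) != len(dots_per_patch):
        raise ValueError("one dot set per patch required")
    rows = []
    for diameter in diameters_um:
        for role in roles:
            tp = fp = fn = 0
            for mask, dots in zip(pred_masks, dots_per_patch):
                code = mask.class_table.code(role)
                t, f, m = component_match(
                    mask.role_mask(role),
                    dots.for_class(code),
                    diameter,
                    mask.resolution_um_per_px,
                )
                tp, fp, fn = tp + t, fp + f, fn + m
            ppv, rec, f1 = metrics_from_counts(tp, fp, fn)
            rows.append(
                {
                    "class": role.value,
                    "dilation_diameter_um": diameter,
                    "TP": tp, "FP": fp, "FN": fn,
                    "PPV": ppv, "recall": rec, "F1": f1,
                }
            )
    return pd.DataFrame(rows)
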