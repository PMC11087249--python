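"""Reading and writing masks, ROIs and dot annotations; patch tiling.

File conventions
----------------
* Label masks: single-channel indexed PNG or TIFF.  A JSON sidecar
  ``<mask>.json`` carries the class table and the resolution:
  ``{"class_table": {"0": "STROMA", ...}, "resolution_um_per_px": 0.346}``.
* ROIs: GeoJSON FeatureCollection of Polygons in pixel coordinates
  (x = column, y = row, origin top-left), feature property ``case_id``.
* Dot annotations: CSV with columns ``x,y,class,annotator``.

Coordinates are 0-based; a pixel ``(row, col)`` has its center at
``(x, y) = (col, row)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import shape as shapely_shape

from .classes import (
    OUTSIDE_CODE,
    ClassTable,
    LabelMask,
    Role,
)

__all__ = [
    "ROISet",
    "DotAnnotationSet",
    "PatchGrid",
    "read_label_mask",
    "write_label_mask",
    "apply_rois",
    "tile_patches",
    "read_rois",
    "read_dot_annotations",
]


@dataclass
class ROISet:
    """Pathologist-drawn regions of interest as pixel-coordinate polygons."""

    polygons: list  # list of shapely Polygon
    case_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.case_ids):
            raise ValueError("one case_id per polygon required")
        for p in self.polygons:
            if len(p.exterior.coords) < 4:  # closed ring: >=3 distinct vertices
                raise ValueError("ROI polygon needs at least 3 vertices")

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class DotAnnotationSet:
    """Point labels (weak annotations): one dot per cell."""

    points: pd.DataFrame  # columns x, y, class, annotator

    def __post_init__(self) -> None:
        required = {"x", "y", "class", "annotator"}
        if not required <= set(self.points.columns):
            raise ValueError(f"dot annotations need columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.points)

    def for_class(self, code: int) -> np.ndarray:
        """``(N, 2)`` array of (x, y) for one class code."""
        sub = self.points[self.points["class"] == code]
        return sub[["x", "y"]].to_numpy(dtype=float)


@dataclass
class PatchGrid:
    """Offsets of overlapping patches covering an image extent."""

    patch_size_px: int
    stride_px: int
    row_offsets: list[int]
    col_offsets: list[int]

    @property
    def n_patches(self) -> int:
        return len(self.row_offsets) * len(self.col_offsets)

    def offsets(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.row_offsets for c in self.col_offsets]


# ---------------------------------------------------------------------------
# masks

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as single-channel PNG/TIFF plus a JSON sidecar."""
    path = Path(path)
    grid = np.ascontiguousarray(mask.grid.astype(np.uint8))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, grid)
    elif path.suffix.lower() == ".png":
        Image.fromarray(grid, mode="L").save(path)
    else:
        raise ValueError(f"unsupported mask format: {path.suffix!r} (use .png/.tif)")
    sidecar = {
        "class_table": mask.class_table.to_json_dict(),
        "resolution_um_per_px": mask.resolution_um_per_px,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_label_mask(
    path: str | Path,
    class_table: ClassTable | None = None,
    resolution_um_per_px: float | None = None,
) -> LabelMask:
    """Read a mask image, validating codes against the class table.

    Resolution comes from the JSON sidecar when present, otherwise from
    the explicit argument; having neither is an error.  An explicit
    argument always wins over the sidecar.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        grid = tifffile.imread(path)
    else:
        grid = np.asarray(Image.open(path))
    if grid.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel mask, got shape {grid.shape}")

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if class_table is None:
        if "class_table" in meta:
            class_table = ClassTable.from_json_dict(meta["class_table"])
        else:
            class_table = ClassTable()
    if resolution_um_per_px is None:
        resolution_um_per_px = meta.get("resolution_um_per_px")
    if resolution_um_per_px is None:
        raise ValueError(
            f"{path}: resolution unknown — provide resolution_um_per_px or a sidecar"
        )
    return LabelMask(grid.astype(np.uint8), float(resolution_um_per_px), class_table)


# ---------------------------------------------------------------------------
# ROIs

def read_rois(path: str | Path) -> ROISet:
    """Read a GeoJSON FeatureCollection of pixel-coordinate polygons."""
    data = json.loads(Path(path).read_text())
    polys, ids = [], []
    for feat in data.get("features", []):
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"ROI features must be Polygons, got {geom.geom_type}")
        polys.append(geom)
        ids.append(str(feat.get("properties", {}).get("case_id", "")))
    return ROISet(polys, ids)


def apply_rois(
    mask: LabelMask,
    rois: ROISet | None,
    *,
    allow_full_image: bool = False,
) -> LabelMask:
    """Restrict a mask to ROI polygons; outside pixels become the sentinel.

    Pixel membership uses a center-of-pixel test, boundary included, so the
    result is independent of ring orientation.  Passing an empty ROI set is
    an error unless ``allow_full_image=True`` explicitly opts out.
    """
    if rois is None or len(rois) == 0:
        if allow_full_image:
            return mask.copy()
        raise ValueError(
            "empty ROI set: pass allow_full_image=True to process the full image"
        )
    h, w = mask.shape
    inside = np.zeros((h, w), dtype=bool)
    for poly in rois.polygons:
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
        r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
        if c0 > c1 or r0 > r1:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        xx, yy = np.meshgrid(cols, rows)
        shapely.prepare(poly)
        hit = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
        inside[r0 : r1 + 1, c0 : c1 + 1] |= hit
    out = mask.grid.copy()
    out[~inside] = OUTSIDE_CODE
    return LabelMask(out, mask.resolution_um_per_px, mask.class_table)


# ---------------------------------------------------------------------------
# tiling

def _axis_offsets(extent: int, patch: int, stride: int) -> list[int]:
    last = extent - patch
    offs = list(range(0, last + 1, stride))
    if offs[-1] != last:
        offs.append(last)  # flush-end patch so the extent is fully covered
    return offs


def tile_patches(extent_hw: tuple[int, int], patch_size_px: int, stride_px: int) -> PatchGrid:
    """Regular (optionally overlapping) patch grid over an image extent.

    Offsets per axis run 0, stride, 2*stride, ... up to ``extent - patch``;
    a flush-end offset is appended when the extent is not stride-divisible.
    E.g. a 1000x1000 region tiled with 400 px patches at stride 200 yields
    a 4x4 = 16 patch grid.
    """
    h, w = extent_hw
    if patch_size_px > h or patch_size_px > w:
        raise ValueError(f"patch size {patch_size_px} exceeds extent {extent_hw}")
    if stride_px < 1:
        raise ValueError("stride must be >= 1")
    return PatchGrid(
        patch_size_px,
        stride_px,
        _axis_offsets(h, patch_size_px, stride_px),
        _axis_offsets(w, patch_size_px, stride_px),
    )


# ---------------------------------------------------------------------------
# dot annotations

def read_dot_annotations(
    path: str | Path,
    extent_hw: tuple[int, int] | None = None,
    class_table: ClassTable | None = None,
) -> DotAnnotationSet:
    """Read dot annotations (CSV: x,y,class,annotator) with validation.

    Coordinates must be non-negative and, when ``extent_hw`` is given,
    inside the image; violations report the offending CSV row number
    (1-based, header excluded).
    """
    df = pd.read_csv(path)
    dots = DotAnnotationSet(df)
    table = class_table or ClassTable()
    for i, row in df.iterrows():
        rowno = int(i) + 1
        x, y = float(row["x"]), float(row["y"])
        if x < 0 or y < 0:
            raise ValueError(f"row {rowno}: negative coordinate ({x}, {y})")
        if extent_hw is not None:
            h, w = extent_hw
            if x > w - 1 or y > h - 1:
                raise ValueError(f"row {rowno}: point ({x}, {y}) outside extent {extent_hw}")
        if int(row["class"]) not in table.codes:
            raise ValueError(f"row {rowno}: unknown class code {row['class']}")
    return dots
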