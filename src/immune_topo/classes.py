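"""Core label-mask types shared by every pipeline stage.

A mask is a 2-D grid of integer class codes, one code per pixel, produced by
multi-class segmentation of multiplex IHC images.  Seven roles cover the
panel: stroma/background, K17-positive tumor, K17-negative (panCK+) tumor,
and four immune classes (CD4+ and CD8+ T cells, CD16+CD163- and CD16+CD163+
macrophages).  Physical scale is carried per mask as micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Role",
    "ClassTable",
    "LabelMask",
    "DEFAULT_CLASS_TABLE",
    "IMMUNE_ROLES",
    "TUMOR_ROLES",
    "OUTSIDE_CODE",
    "DEFAULT_RESOLUTION_UM_PER_PX",
]

#: scanner resolution of the source whole-slide images (20x), um per pixel
DEFAULT_RESOLUTION_UM_PER_PX = 0.346

#: sentinel code for pixels excluded by ROI restriction; never a class code
OUTSIDE_CODE = 255


class Role(str, Enum):
    """Biological role of a mask class code."""

    STROMA = "STROMA"
    TUMOR_K17POS = "TUMOR_K17POS"
    TUMOR_K17NEG = "TUMOR_K17NEG"
    CD4 = "CD4"
    CD8 = "CD8"
    CD16 = "CD16"   # CD16+ / CD163-  (M1-like macrophage)
    CD163 = "CD163"  # CD16+ / CD163+ (M2-like macrophage)


IMMUNE_ROLES: tuple[Role, ...] = (Role.CD4, Role.CD8, Role.CD16, Role.CD163)
TUMOR_ROLES: tuple[Role, ...] = (Role.TUMOR_K17POS, Role.TUMOR_K17NEG)


@dataclass(frozen=True)
class ClassTable:
    """Bijection between integer class codes and :class:`Role` values.

    Exactly one code per role; codes unique.  Code 0 is stroma by default.
    """

    entries: dict[int, Role] = field(
        default_factory=lambda: dict(_DEFAULT_ENTRIES)
    )

    def __post_init__(self) -> None:
        roles = list(self.entries.values())
        if len(set(roles)) != len(roles):
            raise ValueError("duplicate role in class table")
        if set(roles) != set(Role):
            missing = set(Role) - set(roles)
            raise ValueError(f"class table missing roles: {sorted(r.value for r in missing)}")
        if OUTSIDE_CODE in self.entries:
            raise ValueError(f"code {OUTSIDE_CODE} is reserved for ROI-excluded pixels")

    def code(self, role: Role) -> int:
        for c, r in self.entries.items():
            if r is role:
                return c
        raise KeyError(role)  # pragma: no cover - table always complete

    def role(self, code: int) -> Role:
        return self.entries[code]

    @property
    def codes(self) -> set[int]:
        return set(self.entries)

    def to_json_dict(self) -> dict[str, str]:
        return {str(c): r.value for c, r in sorted(self.entries.items())}

    @classmethod
    def from_json_dict(cls, d: dict[str, str]) -> "ClassTable":
        return cls({int(c): Role(r) for c, r in d.items()})


_DEFAULT_ENTRIES: dict[int, Role] = {
    0: Role.STROMA,
    1: Role.TUMOR_K17POS,
    2: Role.TUMOR_K17NEG,
    3: Role.CD4,
    4: Role.CD8,
    5: Role.CD16,
    6: Role.CD163,
}

DEFAULT_CLASS_TABLE = ClassTable()


@dataclass
class LabelMask:
    """A validated multi-class segmentation mask with physical scale.

    Parameters
    ----------
    grid
        ``(H, W)`` integer array of class codes.  The ROI sentinel
        :data:`OUTSIDE_CODE` may appear after ROI restriction.
    resolution_um_per_px
        Pixel pitch in micrometres; strictly positive.
    class_table
        Code-to-role mapping the grid is validated against.
    """

    grid: np.ndarray
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    class_table: ClassTable = field(default_factory=ClassTable)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("mask grid must hold integer class codes")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive (um/px)")
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.grid)
        allowed = self.class_table.codes | {OUTSIDE_CODE}
        unknown = [int(c) for c in present if int(c) not in allowed]
        if unknown:
            counts = {c: int(np.sum(self.grid == c)) for c in unknown}
            raise ValueError(
                "unknown class codes in mask: "
                + ", ".join(f"code {c} ({n} px)" for c, n in counts.items())
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.resolution_um_per_px ** 2

    def role_mask(self, role: Role) -> np.ndarray:
        """Boolean pixel mask of one role."""
        return self.grid == self.class_table.code(role)

    def copy(self) -> "LabelMask":
        return LabelMask(self.grid.copy(), self.resolution_um_per_px, self.class_table)
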