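"""Shared domain types.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, both 0-based, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["RegionStatus", "Circle", "Region"]


class RegionStatus(IntEnum):
    """Growth status of one foreground region."""

    ISOLATED = 1
    OCCLUDED = 2
    OVERLAPPED = 3


@dataclass(frozen=True)
class Circle:
    """A detection circle: sub-pixel center ``(cx, cy)`` and radius in px."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if not (self.r > 0 and math.isfinite(self.r)):
            raise ValueError(f"circle radius must be positive, got {self.r}")

    @property
    def area(self) -> float:
        return math.pi * self.r * self.r

    def scaled(self, factor: float) -> "Circle":
        return Circle(self.cx * factor, self.cy * factor, self.r * factor)

    def to_dict(self) -> dict:
        return {"cx": float(self.cx), "cy": float(self.cy), "r": float(self.r)}

    @classmethod
    def from_dict(cls, d: dict) -> "Circle":
        return cls(float(d["cx"]), float(d["cy"]), float(d["r"]))


@dataclass
class Region:
    """One 8-connected foreground component.

    The mask is stored cropped to the component's bounding box; ``offset``
    holds the global ``(x0, y0)`` of that box.  ``centroid`` and ``boundary``
    are expressed in global image coordinates.
    """

    label: int
    mask: np.ndarray  # bool, cropped to bbox
    offset: tuple[int, int]  # (x0, y0) of the bbox in the source image
    area: int
    centroid: tuple[float, float]  # (x, y)
    boundary: np.ndarray = field(repr=False)  # (n, 2) float array of (x, y)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), exclusive upper bounds."""
        x0, y0 = self.offset
        h, w = self.mask.shape
        return (x0, y0, x0 + w, y0 + h)

    def contains_point(self, x: float, y: float) -> bool:
        x0, y0 = self.offset
        ix, iy = int(round(x)) - x0, int(round(y)) - y0
        h, w = self.mask.shape
        if 0 <= iy < h and 0 <= ix < w:
            return bool(self.mask[iy, ix])
        return False

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Paint the component back into a full-size boolean image."""
        out = np.zeros(shape, dtype=bool)
        x0, y0 = self.offset
        h, w = self.mask.shape
        out[y0 : y0 + h, x0 : x0 + w] = self.mask
        return out

    def to_dict(self) -> dict:
        return {
            "label": int(self.label),
            "area": int(self.area),
            "centroid": [float(self.centroid[0]), float(self.centroid[1])],
            "bbox": list(self.bbox),
        }
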