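"""Splitting fused fruit clusters with a polar distance profile.

From the region centroid, the distance to the region boundary is sampled
once per integer degree. Local minima of this circular profile sit at the
waists where two fruits meet; local maxima sit at the far pole of each
fruit. Because a waist point lies on both fruit circles and the far pole
lies on one of them, the circle through each consecutive
minimum-maximum-minimum triplet recovers one individual fruit — the
unique circle through three non-collinear points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core import Circle, Region

__all__ = [
    "PolarProfile",
    "Extremum",
    "polar_profile",
    "find_extrema",
    "circumcircle",
    "split_overlapped",
    "CentroidOutsideError",
    "CollinearPointsError",
]

logger = logging.getLogger(__name__)


class CentroidOutsideError(ValueError):
    """Centroid rays failed to hit the region for some degrees."""

    def __init__(self, degrees: list[int]):
        self.degrees = degrees
        super().__init__(
            f"centroid lies outside the region for {len(degrees)} ray(s), "
            f"first offending degrees: {degrees[:10]}"
        )


class CollinearPointsError(ValueError):
    """Three points do not determine a circle."""


@dataclass
class PolarProfile:
    """Per-degree centroid-to-boundary distances of one region.

    ``distances[d]`` is the Euclidean distance from the centroid (the
    profile origin) to the outermost region point along the ray at
    ``d`` degrees, counter-clockwise in the (x, y) frame. Index 359 is
    circularly adjacent to index 0.
    """

    origin: tuple[float, float]
    distances: np.ndarray  # (360,)
    boundary_points: np.ndarray  # (360, 2) of (x, y)

    def __post_init__(self) -> None:
        if self.distances.shape != (360,):
            raise ValueError("profile must hold exactly 360 samples")
        if not np.all(self.distances > 0):
            raise ValueError("all profile distances must be positive")


@dataclass(frozen=True)
class Extremum:
    degree: float
    distance: float
    is_max: bool


def polar_profile(region: Region, step: float = 0.5) -> PolarProfile:
    """Sample centroid-to-boundary distance for every integer degree.

    Each ray is marched outward in ``step``-px increments; the outermost
    in-region sample is taken, which keeps the profile single-valued on
    non-star-shaped regions. Rays that never hit the region (centroid
    outside a strongly non-convex mask) raise :class:`CentroidOutsideError`
    listing the offending degrees.
    """
    ax, ay = region.centroid
    x0, y0 = region.offset
    h, w = region.mask.shape
    max_dist = math.hypot(h, w) + 1.0

    n_steps = int(max_dist / step) + 1
    t = (np.arange(n_steps) + 1) * step  # radii probed along each ray
    theta = np.deg2rad(np.arange(360.0))
    # counter-clockwise in the (x, y) frame
    dx = np.cos(theta)[:, None] * t[None, :]
    dy = np.sin(theta)[:, None] * t[None, :]
    px = np.rint(ax + dx - x0).astype(int)
    py = np.rint(ay + dy - y0).astype(int)
    valid = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    inside = np.zeros_like(valid)
    inside[valid] = region.mask[py[valid], px[valid]]

    distances = np.empty(360, dtype=np.float64)
    points = np.empty((360, 2), dtype=np.float64)
    missing: list[int] = []
    for d in range(360):
        hits = np.flatnonzero(inside[d])
        if hits.size == 0:
            missing.append(d)
            continue
        k = hits[-1]  # outermost in-region sample
        ex, ey = ax + dx[d, k], ay + dy[d, k]
        points[d] = (ex, ey)
        distances[d] = math.hypot(ex - ax, ey - ay)
    if missing:
        raise CentroidOutsideError(missing)
    return PolarProfile(origin=(ax, ay), distances=distances, boundary_points=points)


def _circular_peaks(signal: np.ndarray, prominence: float) -> np.ndarray:
    """Peak indices of a circular signal, found on a tripled copy."""
    n = signal.size
    tiled = np.concatenate([signal, signal, signal])
    idx, _ = find_peaks(tiled, prominence=prominence)
    idx = idx[(idx >= n) & (idx < 2 * n)] - n
    return idx


def find_extrema(
    profile: PolarProfile, smooth_win: int = 9, min_prominence: float = 2.0
) -> list[Extremum]:
    """Alternating minima/maxima of the smoothed circular profile.

    The profile is smoothed with a circular moving average of width
    ``smooth_win`` (odd). Extrema under ``min_prominence`` are discarded;
    plateaus contribute their midpoint. Runs of same-type extrema are
    repaired deterministically: of two adjacent maxima the lower is
    reclassified as a minimum, then any remaining same-type run collapses
    to its most extreme member. The result strictly alternates around the
    circle; a featureless profile yields an empty list.
    """
    if smooth_win < 1 or smooth_win % 2 == 0:
        raise ValueError("smooth_win must be odd and >= 1")
    smooth = uniform_filter1d(profile.distances, size=smooth_win, mode="wrap")

    max_idx = _circular_peaks(smooth, min_prominence)
    min_idx = _circular_peaks(-smooth, min_prominence)
    extrema = sorted(
        [Extremum(float(d), float(smooth[d]), True) for d in max_idx]
        + [Extremum(float(d), float(smooth[d]), False) for d in min_idx],
        key=lambda e: e.degree,
    )
    if len(extrema) < 2:
        return []

    # repair adjacent same-type pairs: lower of two maxima becomes a minimum
    changed = True
    passes = 0
    while changed and passes < 10:
        changed = False
        passes += 1
        out: list[Extremum] = []
        n = len(extrema)
        for i, e in enumerate(extrema):
            nxt = extrema[(i + 1) % n]
            if e.is_max and nxt.is_max:
                lower, _ = (e, nxt) if e.distance <= nxt.distance else (nxt, e)
                if e is lower:
                    out.append(Extremum(e.degree, e.distance, False))
                    changed = True
                    continue
            out.append(e)
        extrema = sorted(out, key=lambda e: e.degree)

    # collapse any remaining same-type run to its most extreme member
    cleaned: list[Extremum] = []
    for e in extrema:
        if cleaned and cleaned[-1].is_max == e.is_max:
            keep_new = (e.distance > cleaned[-1].distance) == e.is_max
            if keep_new:
                cleaned[-1] = e
        else:
            cleaned.append(e)
    if len(cleaned) >= 2 and cleaned[0].is_max == cleaned[-1].is_max:
        first, last = cleaned[0], cleaned[-1]
        keep_first = (first.distance > last.distance) == first.is_max
        if keep_first:
            cleaned.pop()
        else:
            cleaned.pop(0)
    if len(cleaned) < 2:
        return []
    return cleaned


def circumcircle(
    a: tuple[float, float], b: tuple[float, float], c: tuple[float, float]
) -> Circle:
    """The unique circle through three non-collinear points.

    Raises :class:`CollinearPointsError` when twice the signed triangle
    area is below ``1e-12`` of the squared coordinate scale.
    """
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(v) for v in (ax, ay, bx, by, cx, cy)) or 1.0
    if abs(d) < 1e-12 * scale * scale:
        raise CollinearPointsError(f"points {a}, {b}, {c} are collinear")
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return Circle(ux, uy, r)


def _point_at(profile: PolarProfile, degree: float) -> tuple[float, float]:
    ex, ey = profile.boundary_points[int(round(degree)) % 360]
    return float(ex), float(ey)


def split_overlapped(
    region: Region, smooth_win: int = 9, min_prominence: float = 2.0
) -> list[Circle]:
    """Individual fruit circles of a fused (overlapped) region.

    One circle is emitted per minimum-maximum-minimum triplet of the
    alternating extremum sequence, wrapping circularly so the triplet
    spanning 359->0 degrees is formed. Collinear triplets are skipped with
    a log record. With fewer than two minima the region is returned as a
    single circle — its equivalent area circle.
    """
    from .status import equivalent_area_circle  # local import avoids a cycle

    profile = polar_profile(region)
    extrema = find_extrema(profile, smooth_win=smooth_win, min_prominence=min_prominence)
    minima = [e for e in extrema if not e.is_max]
    if len(minima) < 2:
        return [equivalent_area_circle(region)]

    circles: list[Circle] = []
    n = len(extrema)
    for i, e in enumerate(extrema):
        if not e.is_max:
            continue
        prev = extrema[(i - 1) % n]
        nxt = extrema[(i + 1) % n]
        pa = _point_at(profile, prev.degree)
        pb = _point_at(profile, e.degree)
        pc = _point_at(profile, nxt.degree)
        try:
            circles.append(circumcircle(pa, pb, pc))
        except CollinearPointsError:
            logger.info(
                "region %d: collinear extremum triplet at degrees (%s, %s, %s) skipped",
                region.label, prev.degree, e.degree, nxt.degree,
            )
    if not circles:
        return [equivalent_area_circle(region)]
    return circles
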