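"""Region status classification: isolated vs occluded vs overlapped.

Each foreground region is summarized by two kinds of circles:

* the *equivalent area circle* — centered at the region centroid with
  radius ``sqrt(area / pi)``, so its area equals the region's;
* the *Hough circles* — circles voted on the region's boundary by a
  circular Hough transform with a per-region radius window.

The relation between the strongest Hough radius ``Rh``, the area radius
``Ra`` and the total Hough circle area decides the three-way status:
a single Hough circle matching ``Ra`` means an isolated fruit; a Hough
circle much larger than ``Ra`` means a mostly hidden (occluded) fruit
whose visible arc implies a bigger circle; several Hough circles whose
summed area exceeds the region area mean fused (overlapped) fruits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle, hough_circle_peaks

from .core import Circle, Region, RegionStatus

__all__ = [
    "StatusThresholds",
    "equivalent_area_circle",
    "hough_circles",
    "classify_status",
    "classify_region",
]


@dataclass(frozen=True)
class StatusThresholds:
    """Numeric form of the qualitative circle relations.

    approx_tol
        relative tolerance for "Rh approximately equals Ra".
    dominance_ratio
        ratio for "much greater / much smaller than".
    hough_vote_frac
        fraction of a candidate circle's perimeter that must vote for it.
    rel_vote_frac
        circles are also pruned relative to the strongest peak: anything
        below ``rel_vote_frac * best_vote`` is discarded, suppressing the
        spurious small inscribed circles a noisy boundary always votes up.
    r_min_frac, r_max_frac
        Hough radius search window as fractions of Ra.
    overlap_area_frac
        margin on the summed-Hough-area vs region-area comparison; counters
        the systematic radius underestimation of discrete Hough voting.
    """

    approx_tol: float = 0.2
    dominance_ratio: float = 1.25
    hough_vote_frac: float = 0.3
    rel_vote_frac: float = 0.55
    r_min_frac: float = 0.4
    r_max_frac: float = 2.0
    min_radius_px: float = 8.0
    overlap_area_frac: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.approx_tol < 1.0):
            raise ValueError("approx_tol must be in (0, 1)")
        if self.dominance_ratio <= 1.0:
            raise ValueError("dominance_ratio must be > 1")
        if not (0.0 < self.r_min_frac < self.r_max_frac):
            raise ValueError("need 0 < r_min_frac < r_max_frac")


def equivalent_area_circle(region: Region) -> Circle:
    """Circle at the region centroid whose area equals the region area."""
    if region.area <= 0:
        raise ValueError("region has zero area")
    cx, cy = region.centroid
    return Circle(cx, cy, math.sqrt(region.area / math.pi))


def _merge_circles(
    circles: list[tuple[Circle, float]], approx_tol: float
) -> list[tuple[Circle, float]]:
    """Drop near-duplicates, keeping the higher-vote circle of each pair."""
    kept: list[tuple[Circle, float]] = []
    for cand, vote in circles:
        dup = False
        for ref, _ in kept:
            dist = math.hypot(cand.cx - ref.cx, cand.cy - ref.cy)
            ratio = abs(cand.r - ref.r) / max(cand.r, ref.r)
            if dist < 0.5 * min(cand.r, ref.r) and ratio < approx_tol:
                dup = True
                break
        if not dup:
            kept.append((cand, vote))
    return kept


def hough_circles(
    region: Region, thr: StatusThresholds | None = None, max_peaks: int = 8
) -> list[Circle]:
    """Circles voted by the Hough transform on the region's boundary.

    The radius window is tied to the region's equivalent-area radius,
    ``[r_min_frac * Ra, r_max_frac * Ra]``. Accumulator values are
    normalized by circle perimeter, so ``hough_vote_frac`` is the fraction
    of a circle's circumference that must be present as edge evidence.
    Near-duplicate circles are merged keeping the higher vote. Returns
    circles sorted by vote count descending; too little boundary yields
    an empty list.
    """
    if thr is None:
        thr = StatusThresholds()
    if region.boundary.shape[0] < 3:
        return []
    ra = equivalent_area_circle(region).r
    # absolute floor: radii of a few px fit inside the thickened edge band
    # and saturate their votes regardless of shape
    r_lo = max(int(thr.min_radius_px), int(math.floor(thr.r_min_frac * ra)))
    r_hi = max(r_lo + 1, int(math.ceil(thr.r_max_frac * ra)))
    radii = np.arange(r_lo, r_hi + 1)

    # edge of the component, thickened by one dilation so the discrete
    # Hough templates match it reliably; padded so circles whose centers
    # fall outside the bbox still accumulate votes
    pad = r_hi
    edge = region.mask & ~ndimage.binary_erosion(region.mask)
    edge = ndimage.binary_dilation(edge)
    edge = np.pad(edge, pad)

    # normalize=True divides votes by the circle template size, so peak
    # values read directly as the fraction of perimeter present
    acc = hough_circle(edge, radii, normalize=True)
    votes, cxs, cys, rads = hough_circle_peaks(
        acc,
        radii,
        min_xdistance=max(2, int(0.3 * ra)),
        min_ydistance=max(2, int(0.3 * ra)),
        threshold=thr.hough_vote_frac,
        num_peaks=max_peaks * 4,
        total_num_peaks=max_peaks,
    )

    x0, y0 = region.offset
    found = [
        (Circle(cx - pad + x0, cy - pad + y0, float(r)), float(v))
        for v, cx, cy, r in zip(votes, cxs, cys, rads)
        if v >= thr.hough_vote_frac
    ]
    found.sort(key=lambda cv: -cv[1])
    if found:
        floor = thr.rel_vote_frac * found[0][1]
        found = [cv for cv in found if cv[1] >= floor]
    return [c for c, _ in _merge_circles(found, thr.approx_tol)]


def classify_status(
    houghs: list[Circle], area_circle: Circle, thr: StatusThresholds | None = None
) -> RegionStatus:
    """Three-way status from the Hough circles and the equivalent area circle.

    Deterministic decision ladder (scale-invariant — every test is a ratio):

    1. exactly one Hough circle with ``|Rh - Ra| <= approx_tol * Ra``
       -> ISOLATED;
    2. ``Rh* >= dominance_ratio * Ra`` (visible arc implies a much larger
       hidden circle) -> OCCLUDED;
    3. several Hough circles whose summed area reaches
       ``overlap_area_frac * pi * Ra**2`` -> OVERLAPPED;
    4. several Hough circles failing that area test -> OCCLUDED;
    5. anything else (including no Hough circle at all) -> ISOLATED.
    """
    if thr is None:
        thr = StatusThresholds()
    ra = area_circle.r
    if not houghs:
        return RegionStatus.ISOLATED
    rh_max = max(c.r for c in houghs)
    total_area = sum(c.area for c in houghs)

    if len(houghs) == 1 and abs(rh_max - ra) <= thr.approx_tol * ra:
        return RegionStatus.ISOLATED
    if rh_max >= thr.dominance_ratio * ra:
        return RegionStatus.OCCLUDED
    if len(houghs) >= 2:
        if total_area >= thr.overlap_area_frac * area_circle.area:
            return RegionStatus.OVERLAPPED
        return RegionStatus.OCCLUDED
    return RegionStatus.ISOLATED


def classify_region(
    region: Region, thr: StatusThresholds | None = None
) -> tuple[RegionStatus, Circle, list[Circle]]:
    """Convenience wrapper: returns (status, area_circle, hough_circles)."""
    if thr is None:
        thr = StatusThresholds()
    area_circle = equivalent_area_circle(region)
    houghs = hough_circles(region, thr)
    return classify_status(houghs, area_circle, thr), area_circle, houghs
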