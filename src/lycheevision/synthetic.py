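"""Seeded generator of orchard-like scenes with exact ground truth.

Scenes contain near-circular "fruit" discs with red-dominant color and
bumpy high-frequency rind texture, on a green/brown textured background
with low red-blue contrast. Fruits are rendered isolated, partially
covered by elongated leaf-green occluder strips, or fused in compact
clusters of 2-4. Optional "chaff" distractors — smooth reddish blobs —
segment as foreground but carry non-fruit texture, giving the texture
filter real false positives to remove. Three illumination regimes are
applied as global gains (weak 0.4, well 1.0, overexposed 1.8 with
clipping).

Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw

from .core import Circle, RegionStatus

__all__ = [
    "SceneSpec",
    "FruitGT",
    "GroundTruth",
    "generate_scene",
    "render_training_patches",
    "make_cluster",
    "cluster_mask",
    "status_region_mask",
    "PlacementError",
]

ILLUMINATION_GAINS = {"weak": 0.4, "well": 1.0, "overexposed": 1.8}

FRUIT_COLOR = np.array([185.0, 70.0, 45.0])
OCCLUDER_COLOR = np.array([60.0, 110.0, 70.0])
DISTRACTOR_COLOR = np.array([150.0, 80.0, 50.0])
BACKGROUND_COLOR = np.array([70.0, 95.0, 65.0])


class PlacementError(RuntimeError):
    """Raised when fruits cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; the seed fully determines it."""

    width: int = 320
    height: int = 240
    n_fruits: int = 6
    radius_range: tuple[float, float] = (16.0, 23.0)
    cluster_prob: float = 0.3
    occluder_prob: float = 0.2
    n_distractors: int = 0
    illumination: str = "well"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination not in ILLUMINATION_GAINS:
            raise ValueError(f"unknown illumination regime {self.illumination!r}")
        if self.radius_range[0] > self.radius_range[1] or self.radius_range[0] <= 0:
            raise ValueError("invalid radius_range")


@dataclass(frozen=True)
class FruitGT:
    circle: Circle
    status: RegionStatus


@dataclass
class GroundTruth:
    fruits: list[FruitGT]
    occluder_mask: np.ndarray
    distractors: list[Circle] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers (shared with the module-level test suites)

def make_cluster(
    k: int,
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (15.0, 25.0),
    spacing_range: tuple[float, float] = (1.2, 1.6),
) -> list[Circle]:
    """Compact cluster of ``k`` mutually fused discs around the origin.

    For k = 2 the discs sit on a segment; for k = 3 or 4 on a jittered
    ring, so every fruit keeps a far pole visible from the cluster
    centroid (real fruit clusters are compact, not collinear). Adjacent
    center spacing is ``spacing * mean radius`` with spacing drawn from
    ``spacing_range``.
    """
    if k < 2:
        raise ValueError("a cluster needs at least 2 fruits")
    base_r = rng.uniform(*radius_range)
    radii = base_r * rng.uniform(0.9, 1.1, size=k)
    spacing = rng.uniform(*spacing_range) * float(np.mean(radii))
    phase = rng.uniform(0, 2 * math.pi)
    if k == 2:
        offsets = [(-spacing / 2, 0.0), (spacing / 2, 0.0)]
        ang = [phase, phase]
        pts = [
            (
                o[0] * math.cos(a) - o[1] * math.sin(a),
                o[0] * math.sin(a) + o[1] * math.cos(a),
            )
            for o, a in zip(offsets, ang)
        ]
    else:
        # ring radius chosen so adjacent spacing on the ring equals `spacing`
        ring = spacing / (2 * math.sin(math.pi / k))
        jitter = rng.uniform(-0.15, 0.15, size=k)
        pts = [
            (
                ring * math.cos(phase + 2 * math.pi * i / k + jitter[i]),
                ring * math.sin(phase + 2 * math.pi * i / k + jitter[i]),
            )
            for i in range(k)
        ]
    return [Circle(x, y, float(r)) for (x, y), r in zip(pts, radii)]


def _paint_discs(mask: np.ndarray, circles: list[Circle]) -> None:
    for c in circles:
        rr, cc = draw.disk((c.cy, c.cx), c.r, shape=mask.shape)
        mask[rr, cc] = True


def cluster_mask(
    k: int,
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (15.0, 25.0),
    spacing_range: tuple[float, float] = (1.2, 1.6),
) -> tuple[np.ndarray, list[Circle]]:
    """Rasterized compact cluster, centered on a canvas that fits it."""
    circles = make_cluster(k, rng, radius_range, spacing_range)
    extent = max(math.hypot(c.cx, c.cy) + c.r for c in circles)
    half = int(math.ceil(extent)) + 4
    size = 2 * half + 1
    shifted = [Circle(c.cx + half, c.cy + half, c.r) for c in circles]
    mask = np.zeros((size, size), dtype=bool)
    _paint_discs(mask, shifted)
    return mask, shifted


def _chord_offset_for_kept_fraction(kept: float) -> float:
    """Signed chord distance tau (in radii) keeping `kept` of a disc's area."""
    lo, hi = -1.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        frac = (math.acos(-mid) + mid * math.sqrt(max(1 - mid * mid, 0.0))) / math.pi
        if frac < kept:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def status_region_mask(
    kind: RegionStatus, rng: np.random.Generator
) -> tuple[np.ndarray, RegionStatus]:
    """One labeled region mask for the status-classifier test suite.

    ISOLATED: a plain disc. OCCLUDED: a disc with 55-70% of its area cut
    off by a straight occluder edge (a severe foliage crescent).
    OVERLAPPED: a compact cluster of 2-3 fused discs.
    """
    if kind == RegionStatus.OVERLAPPED:
        k = int(rng.integers(2, 4))
        mask, _ = cluster_mask(k, rng, radius_range=(15.0, 25.0))
        return mask, kind
    r = float(rng.uniform(15, 25))
    half = int(math.ceil(r)) + 4
    size = 2 * half + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((half, half), r, shape=mask.shape)
    mask[rr, cc] = True
    if kind == RegionStatus.ISOLATED:
        return mask, kind
    # occluded: keep 30-45% of the disc beyond a straight cut
    kept = float(rng.uniform(0.30, 0.45))
    tau = _chord_offset_for_kept_fraction(kept)
    angle = rng.uniform(0, 2 * math.pi)
    ux, uy = math.cos(angle), math.sin(angle)
    ys, xs = np.mgrid[0:size, 0:size]
    proj = (xs - half) * ux + (ys - half) * uy
    mask &= proj <= tau * r
    return mask, RegionStatus.OCCLUDED


# ---------------------------------------------------------------------------
# scene rendering

def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal(shape), sigma)
    return noise / (np.abs(noise).max() + 1e-12)

def _strip_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    angle: float,
    width: float,
    length: float,
) -> np.ndarray:
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    tx, ty = math.cos(angle), math.sin(angle)
    along = (xs - cx) * tx + (ys - cy) * ty
    across = -(xs - cx) * ty + (ys - cy) * tx
    return (np.abs(across) <= width / 2) & (np.abs(along) <= length / 2)


def _partition_cluster_sizes(n: int, rng: np.random.Generator) -> list[int]:
    """Partition n >= 2 into cluster sizes from {2, 3, 4} (no leftover 1)."""
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        options = [s for s in (2, 3, 4) if s <= remaining and remaining - s != 1]
        if not options:  # remaining == 1; merge into the previous cluster
            sizes[-1] += 1
            break
        sizes.append(int(rng.choice(options)))
        remaining -= sizes[-1]
    return sizes


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns (H x W x 3 uint8 image, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.radius_range

    # -- decide layout -------------------------------------------------------
    n_clustered = int(round(spec.cluster_prob * spec.n_fruits))
    if n_clustered == 1:
        n_clustered = 2 if spec.n_fruits >= 2 else 0
    cluster_sizes = _partition_cluster_sizes(n_clustered, rng) if n_clustered >= 2 else []
    n_isolated = spec.n_fruits - sum(cluster_sizes)

    units: list[dict] = []  # {"circles": [...], "clustered": bool}
    for k in cluster_sizes:
        circles = make_cluster(k, rng, radius_range=(r_lo, r_hi))
        units.append({"circles": circles, "clustered": True})
    for _ in range(n_isolated):
        r = float(rng.uniform(r_lo, r_hi))
        units.append({"circles": [Circle(0.0, 0.0, r)], "clustered": False})

    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    margin = 8.0
    for unit in units:
        bound = max(math.hypot(c.cx, c.cy) + c.r for c in unit["circles"])
        ok = False
        for _ in range(300):
            ux = rng.uniform(bound + 2, w - bound - 2)
            uy = rng.uniform(bound + 2, h - bound - 2)
            if all(
                math.hypot(ux - px, uy - py) >= bound + pb + margin
                for px, py, pb in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a unit of bounding radius {bound:.1f} in a "
                f"{w}x{h} scene with {len(placed)} units already present"
            )
        placed.append((ux, uy, bound))
        unit["circles"] = [Circle(c.cx + ux, c.cy + uy, c.r) for c in unit["circles"]]

    fruits: list[Circle] = [c for u in units for c in u["circles"]]
    clustered_flags = [u["clustered"] for u in units for _ in u["circles"]]

    # distractors: smooth chaff blobs placed clear of fruit
    distractors: list[Circle] = []
    for _ in range(spec.n_distractors):
        r = float(rng.uniform(r_lo, r_hi * 0.95))
        for _ in range(300):
            dx = rng.uniform(r + 2, w - r - 2)
            dy = rng.uniform(r + 2, h - r - 2)
            clear = all(
                math.hypot(dx - px, dy - py) >= r + pb + margin for px, py, pb in placed
            )
            if clear:
                placed.append((dx, dy, r))
                distractors.append(Circle(dx, dy, r))
                break
        else:
            raise PlacementError("could not place a distractor blob")

    # -- paint ---------------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.float64)
    bg_mod = _smooth_noise(rng, (h, w), 6.0)
    bg_fine = _smooth_noise(rng, (h, w), 2.0)
    for ch in range(3):
        img[..., ch] = BACKGROUND_COLOR[ch] * (1 + 0.22 * bg_mod + 0.05 * bg_fine)

    bump = _smooth_noise(rng, (h, w), 2.0)  # coarse rind bumps, a few px across
    shade = _smooth_noise(rng, (h, w), 5.0)
    fruit_field = (1 + 0.35 * bump + 0.10 * shade)

    for c in fruits:
        rr, cc = draw.disk((c.cy, c.cx), c.r, shape=(h, w))
        tint = 1 + 0.08 * rng.normal()
        for ch in range(3):
            img[rr, cc, ch] = FRUIT_COLOR[ch] * tint * fruit_field[rr, cc]

    smooth_field = 1 + 0.10 * shade
    for c in distractors:
        rr, cc = draw.disk((c.cy, c.cx), c.r, shape=(h, w))
        for ch in range(3):
            img[rr, cc, ch] = DISTRACTOR_COLOR[ch] * smooth_field[rr, cc]

    # -- occluders -----------------------------------------------------------
    occluder_mask = np.zeros((h, w), dtype=bool)
    n_occluded = int(round(spec.occluder_prob * len(fruits)))
    isolated_idx = [i for i, fl in enumerate(clustered_flags) if not fl]
    occlude_idx = isolated_idx[:n_occluded]
    leaf_field = 1 + 0.12 * bg_mod
    for i in occlude_idx:
        c = fruits[i]
        angle = rng.uniform(0, 2 * math.pi)
        offset = rng.uniform(0.55, 0.8) * c.r
        scx = c.cx + offset * math.cos(angle)
        scy = c.cy + offset * math.sin(angle)
        strip = _strip_mask(
            (h, w), scx, scy, angle + math.pi / 2, rng.uniform(0.6, 0.9) * c.r, 4 * c.r
        )
        occluder_mask |= strip
        for ch in range(3):
            img[strip, ch] = OCCLUDER_COLOR[ch] * leaf_field[strip]

    # -- status labels from rendered geometry --------------------------------
    records: list[FruitGT] = []
    for i, c in enumerate(fruits):
        overlapped = any(
            j != i
            and math.hypot(c.cx - o.cx, c.cy - o.cy) < c.r + o.r
            for j, o in enumerate(fruits)
        )
        rr, cc = draw.disk((c.cy, c.cx), c.r, shape=(h, w))
        covered = float(occluder_mask[rr, cc].mean()) if rr.size else 0.0
        if overlapped:
            status = RegionStatus.OVERLAPPED
        elif covered >= 0.2:
            status = RegionStatus.OCCLUDED
        else:
            status = RegionStatus.ISOLATED
        records.append(FruitGT(c, status))

    # -- illumination --------------------------------------------------------
    gain = ILLUMINATION_GAINS[spec.illumination]
    img = img * gain + rng.normal(0.0, 1.0, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, GroundTruth(records, occluder_mask, distractors)


def render_training_patches(
    spec: SceneSpec, n_pos: int, n_neg: int, patch_size: int = 32
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Labeled grayscale training patches from a stream of seeded scenes.

    Positives are fruit-centered patches; negatives are patches whose
    sampling circle intersects no fruit disc (they may contain occluder
    or chaff pixels — that is the background class). Scenes are drawn
    from ``spec`` with consecutive seeds until enough patches exist.
    """
    from .texture_filter import extract_patch  # local import avoids a cycle

    if n_pos < 1 or n_neg < 1:
        raise ValueError("patch counts must be >= 1")
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []
    scene_seed = spec.seed
    guard = 0
    while len(pos) < n_pos or len(neg) < n_neg:
        guard += 1
        if guard > 50 + (n_pos + n_neg):
            raise PlacementError("insufficient scene area to harvest patches")
        sub = replace(spec, seed=scene_seed)
        scene_seed += 1
        img, gt = generate_scene(sub)
        rng = np.random.default_rng(sub.seed + 1_000_003)
        for fruit in gt.fruits:
            if len(pos) < n_pos:
                pos.append(extract_patch(img, fruit.circle, patch_size))
        h, w = sub.height, sub.width
        attempts = 0
        while len(neg) < n_neg and attempts < 200:
            attempts += 1
            r = float(rng.uniform(*sub.radius_range))
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            if any(
                math.hypot(cx - f.circle.cx, cy - f.circle.cy) < r + f.circle.r
                for f in gt.fruits
            ):
                continue
            neg.append(extract_patch(img, Circle(cx, cy, r), patch_size))
    return pos[:n_pos], neg[:n_neg]
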