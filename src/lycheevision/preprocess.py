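"""Illumination compensation via CLAHE on the HSV value channel.

Contrast-limited adaptive histogram equalization is applied to
``V = max(R, G, B)`` only; hue and saturation are preserved exactly by
rescaling each pixel's RGB triple by ``V'/V``. The clip limit is a
fraction of the tile pixel count and clipped excess is redistributed
uniformly over all 256 gray bins. Tile mappings are blended with
bilinear interpolation; images whose side is not divisible by the tile
grid are edge-padded and cropped back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import segment_image

__all__ = [
    "CLAHEParams",
    "clahe_compensate",
    "overlap_rate",
    "parameter_grid_search",
    "clip_histogram",
    "EmptyUnionError",
]


class EmptyUnionError(ValueError):
    """Raised when the overlap rate of two empty masks is requested."""


@dataclass(frozen=True)
class CLAHEParams:
    """Tile grid dimension (``blocks`` x ``blocks``) and normalized clip limit."""

    blocks: int = 10
    clip_limit: float = 0.015

    def __post_init__(self) -> None:
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError("clip_limit must be in (0, 1]")


def clip_histogram(hist: np.ndarray, clip_count: float) -> np.ndarray:
    """Clip histogram bins at ``clip_count`` and redistribute the excess evenly.

    After redistribution no bin exceeds ``clip_count + excess / nbins``.
    """
    hist = np.asarray(hist, dtype=np.float64)
    excess = np.maximum(hist - clip_count, 0.0).sum()
    clipped = np.minimum(hist, clip_count)
    return clipped + excess / hist.size


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """256-entry gray-level mapping for one tile (midpoint-CDF convention)."""
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    hist = clip_histogram(hist, clip_limit * tile.size)
    total = hist.sum()
    cum = np.cumsum(hist)
    # midpoint CDF: mass strictly below the level plus half the level's own
    cdf = (cum - hist / 2.0) / total
    return np.clip(np.round(cdf * 255.0), 0, 255).astype(np.float64)


def _clahe_channel(v: np.ndarray, params: CLAHEParams) -> np.ndarray:
    """CLAHE on a single uint8 channel; returns float64 in [0, 255]."""
    b = params.blocks
    h, w = v.shape
    th = -(-h // b)  # ceil
    tw = -(-w // b)
    pad_h, pad_w = th * b - h, tw * b - w
    vp = np.pad(v, ((0, pad_h), (0, pad_w)), mode="edge")

    luts = np.empty((b, b, 256), dtype=np.float64)
    for i in range(b):
        for j in range(b):
            tile = vp[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_lut(tile, params.clip_limit)

    hp, wp = vp.shape
    ty = np.clip((np.arange(hp) + 0.5) / th - 0.5, 0.0, b - 1.0)
    tx = np.clip((np.arange(wp) + 0.5) / tw - 0.5, 0.0, b - 1.0)
    y0 = np.minimum(ty.astype(int), b - 2) if b > 1 else np.zeros(hp, int)
    x0 = np.minimum(tx.astype(int), b - 2) if b > 1 else np.zeros(wp, int)
    wy = (ty - y0)[:, None] if b > 1 else np.zeros((hp, 1))
    wx = (tx - x0)[None, :] if b > 1 else np.zeros((1, wp))
    y1 = np.minimum(y0 + 1, b - 1)
    x1 = np.minimum(x0 + 1, b - 1)

    vv = vp.astype(int)
    g00 = luts[y0[:, None], x0[None, :], vv]
    g01 = luts[y0[:, None], x1[None, :], vv]
    g10 = luts[y1[:, None], x0[None, :], vv]
    g11 = luts[y1[:, None], x1[None, :], vv]
    out = (1 - wy) * ((1 - wx) * g00 + wx * g01) + wy * ((1 - wx) * g10 + wx * g11)
    return out[:h, :w]


def clahe_compensate(img: np.ndarray, params: CLAHEParams | None = None) -> np.ndarray:
    """Equalize the value channel of an RGB image, preserving hue/saturation.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
    params : CLAHEParams, optional
        Defaults to ``blocks=10, clip_limit=0.015``.

    Returns
    -------
    (H, W, 3) uint8 array of the same shape.
    """
    if params is None:
        params = CLAHEParams()
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected non-degenerate H x W x 3 image, got {img.shape}")
    img = img.astype(np.uint8)

    v_old = img.max(axis=2)
    v_new = _clahe_channel(v_old, params)

    scale = np.where(v_old > 0, v_new / np.maximum(v_old, 1), 0.0)
    out = img.astype(np.float64) * scale[..., None]
    # black pixels carry no hue: lift them to the mapped gray level
    black = v_old == 0
    out[black] = v_new[black, None]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def overlap_rate(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap |A n B| / |A u B| of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    bm = np.asarray(mask_b, dtype=bool)
    if a.shape != bm.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {bm.shape}")
    union = int(np.logical_or(a, bm).sum())
    if union == 0:
        raise EmptyUnionError("both masks are empty; overlap rate undefined")
    inter = int(np.logical_and(a, bm).sum())
    return inter / union


def parameter_grid_search(
    images: list[np.ndarray],
    refs: list[np.ndarray],
    grid: list[CLAHEParams],
    erode_r: int = 3,
    dilate_r: int = 3,
) -> tuple[list[tuple[CLAHEParams, float]], CLAHEParams]:
    """Mean segmentation overlap against reference masks for each parameter set.

    For every candidate: CLAHE -> chromatic segmentation -> mean overlap
    rate over the paired reference masks. Returns the full table and the
    argmax; ties break toward smaller ``blocks`` then smaller
    ``clip_limit``.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    if len(images) != len(refs):
        raise ValueError("images and reference masks must be paired")
    table: list[tuple[CLAHEParams, float]] = []
    for params in grid:
        rates = []
        for img, ref in zip(images, refs):
            mask = segment_image(clahe_compensate(img, params), erode_r, dilate_r)
            rates.append(overlap_rate(mask, ref))
        table.append((params, float(np.mean(rates))))
    best = max(table, key=lambda row: (row[1], -row[0].blocks, -row[0].clip_limit))[0]
    return table, best
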