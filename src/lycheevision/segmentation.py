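"""Foreground extraction by relative red-blue chromatic mapping.

The pipeline is: per-pixel ``(R - B) / B`` map -> Otsu threshold on the
256-bin quantized map -> morphological cleanup (erosion, dilation, hole
filling) -> 8-connected component labeling into :class:`~lycheevision.core.Region`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import Region

__all__ = [
    "chromatic_map",
    "otsu_threshold",
    "morph_clean",
    "extract_regions",
    "segment_image",
    "ConstantMapError",
]


class ConstantMapError(ValueError):
    """Raised when a map has no contrast to threshold."""


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    return img


def chromatic_map(img: np.ndarray) -> np.ndarray:
    """Relative red-blue chroma ``(R - B) / max(B, 1)`` per pixel.

    The ``max(B, 1)`` guard keeps the ratio finite at zero blue. Negative
    values (blue-dominant pixels) are preserved.
    """
    img = _check_image(img)
    r = img[..., 0].astype(np.float64)
    b = img[..., 2].astype(np.float64)
    return (r - b) / np.maximum(b, 1.0)


def otsu_threshold(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold of a real-valued map, quantized to 256 equal bins.

    Returns ``(threshold, mask)`` where the threshold maximizes the
    between-class variance of the quantized histogram and
    ``mask = values > threshold``. A constant map raises
    :class:`ConstantMapError`.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax <= vmin:
        raise ConstantMapError("map is constant; no threshold exists")

    nbins = 256
    width = (vmax - vmin) / nbins
    quant = np.minimum(((values - vmin) / width).astype(np.int64), nbins - 1)
    hist = np.bincount(quant.ravel(), minlength=nbins).astype(np.float64)

    # Between-class variance for every cut t: classes are bins <= t vs > t.
    p = hist / hist.sum()
    omega0 = np.cumsum(p)
    mu = np.cumsum(p * np.arange(nbins))
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    t_idx = int(np.argmax(sigma_b[:-1]))  # cut after bin t_idx

    threshold = vmin + (t_idx + 1) * width
    mask = quant > t_idx
    return threshold, mask


def morph_clean(mask: np.ndarray, erode_r: int = 3, dilate_r: int = 3) -> np.ndarray:
    """Erosion then dilation with disk elements, then hole filling.

    Hole filling uses 4-connected background so diagonal leaks do not
    empty a hole; every component of the result is simply connected.
    """
    if erode_r < 0 or dilate_r < 0:
        raise ValueError("structuring element radii must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if erode_r > 0:
        out = ndimage.binary_erosion(out, structure=morphology.disk(erode_r))
    if dilate_r > 0:
        out = ndimage.binary_dilation(out, structure=morphology.disk(dilate_r))
    out = ndimage.binary_fill_holes(out, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return out


def _trace_boundary(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Outer boundary of a cropped component as a closed (n, 2) (x, y) array."""
    x0, y0 = offset
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2), dtype=np.float64)
    outer = max(contours, key=len)  # outer contour encloses the rest
    # find_contours yields (row, col) in the padded frame
    xy = np.stack([outer[:, 1] - 1 + x0, outer[:, 0] - 1 + y0], axis=1)
    return xy


def extract_regions(mask: np.ndarray) -> list[Region]:
    """8-connected components of a binary mask as Region records.

    Components touching the image border are retained. An empty mask
    yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    regions: list[Region] = []
    for props in measure.regionprops(labels):
        r0, c0, r1, c1 = props.bbox
        sub = labels[r0:r1, c0:c1] == props.label
        cy, cx = props.centroid
        boundary = _trace_boundary(sub, (c0, r0))
        regions.append(
            Region(
                label=int(props.label),
                mask=sub,
                offset=(c0, r0),
                area=int(props.area),
                centroid=(float(cx), float(cy)),
                boundary=boundary,
            )
        )
    return regions


def segment_image(
    img: np.ndarray, erode_r: int = 3, dilate_r: int = 3
) -> np.ndarray:
    """Full chromatic segmentation: map -> Otsu -> morphology.

    Returns the cleaned binary mask. A chroma map without contrast (e.g. a
    blank image) yields an all-background mask rather than an error.
    """
    cmap = chromatic_map(img)
    try:
        _, mask = otsu_threshold(cmap)
    except ConstantMapError:
        return np.zeros(cmap.shape, dtype=bool)
    return morph_clean(mask, erode_r=erode_r, dilate_r=dilate_r)
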