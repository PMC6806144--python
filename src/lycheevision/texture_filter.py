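"""False-positive filtering with uniform LBP texture and an HIK SVM.

Candidate circles are cut out as grayscale patches, described by a 59-bin
uniform local-binary-pattern histogram (8 neighbors, radius 1: 58 uniform
codes plus one pooled bin for the rest) and classified by a soft-margin
SVM over the histogram intersection kernel
``K(F1, F2) = sum_l min(F1(l), F2(l))``.

The LBP convention here: a neighbor contributes bit 1 iff it is strictly
greater than the center pixel, bits read circularly around the 3x3
neighborhood; a code is uniform when its circular bit string has at most
two 0-1 transitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2gray
from skimage.transform import resize
from sklearn.svm import SVC

from .core import Circle, Region

__all__ = [
    "LBPFeature",
    "TrainedClassifier",
    "extract_patch",
    "uniform_lbp",
    "hik",
    "hik_gram",
    "size_gate",
    "train",
    "filter_detections",
    "uniform_code_table",
    "N_BINS",
]

N_BINS = 59

# offsets of the 8 neighbors in circular order around the center
_NEIGHBOR_OFFSETS = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
]


def _transitions(code: int) -> int:
    bits = [(code >> k) & 1 for k in range(8)]
    return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))


def uniform_code_table() -> np.ndarray:
    """Map each of the 256 LBP codes to a histogram bin.

    Uniform codes (<= 2 circular transitions) get bins 0..57 in ascending
    code order; all other codes share bin 58.
    """
    uniform = [c for c in range(256) if _transitions(c) <= 2]
    table = np.full(256, N_BINS - 1, dtype=np.int64)
    for bin_id, code in enumerate(uniform):
        table[code] = bin_id
    return table


_CODE_TABLE = uniform_code_table()


@dataclass
class LBPFeature:
    """59-bin uniform-LBP histogram."""

    histogram: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.float64)
        if self.histogram.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.histogram.shape}")
        if np.any(self.histogram < 0):
            raise ValueError("histogram bins must be non-negative")


def extract_patch(img: np.ndarray, circle: Circle, out_size: int = 32) -> np.ndarray:
    """Grayscale patch of the circle's bounding square, resampled square.

    The bounding square is clamped to the image; a circle fully outside
    the image raises ``ValueError``. Returns a float64 array in [0, 1].
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    x0 = int(math.floor(circle.cx - circle.r))
    x1 = int(math.ceil(circle.cx + circle.r)) + 1
    y0 = int(math.floor(circle.cy - circle.r))
    y1 = int(math.ceil(circle.cy + circle.r)) + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError(f"circle {circle} lies fully outside the {h}x{w} image")
    patch = img[y0c:y1c, x0c:x1c]
    if patch.ndim == 3:
        patch = rgb2gray(patch)
    else:
        patch = patch.astype(np.float64) / 255.0 if patch.dtype == np.uint8 else patch
    patch = resize(patch, (out_size, out_size), anti_aliasing=True)
    # light prefilter, then quantize back to 8-bit gray levels: LBP bits
    # compare neighbors strictly, so sub-level float noise in flat areas
    # would otherwise produce random codes
    return np.round(gaussian_filter(patch, 0.8) * 255.0)


def uniform_lbp(patch: np.ndarray) -> LBPFeature:
    """Uniform LBP histogram (8 neighbors, radius 1) over interior pixels."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be 2-D and at least 3x3")
    center = patch[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS):
        neighbor = patch[1 + dy : patch.shape[0] - 1 + dy, 1 + dx : patch.shape[1] - 1 + dx]
        codes |= (neighbor > center).astype(np.int64) << bit
    bins = _CODE_TABLE[codes.ravel()]
    hist = np.bincount(bins, minlength=N_BINS).astype(np.float64)
    return LBPFeature(hist / hist.sum(), normalized=True)


def hik(f1: LBPFeature, f2: LBPFeature) -> float:
    """Histogram intersection kernel: sum of elementwise bin minima."""
    if f1.histogram.shape != f2.histogram.shape:
        raise ValueError("feature lengths differ")
    if f1.normalized != f2.normalized:
        raise ValueError("features have mismatched normalization state")
    return float(np.minimum(f1.histogram, f2.histogram).sum())


def hik_gram(feats_a: list[LBPFeature], feats_b: list[LBPFeature]) -> np.ndarray:
    """HIK Gram matrix between two feature lists, shape (len_a, len_b)."""
    a = np.stack([f.histogram for f in feats_a])
    b = np.stack([f.histogram for f in feats_b])
    return np.minimum(a[:, None, :], b[None, :, :]).sum(axis=2)


def size_gate(regions: list[Region], lo: int = 800, hi: int = 1700) -> list[Region]:
    """Keep regions with ``lo <= area <= hi`` (both bounds inclusive)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    return [r for r in regions if lo <= r.area <= hi]


class TrainedClassifier:
    """HIK-SVM over LBP features with bit-exact JSON persistence.

    The decision function is evaluated directly from the stored support
    vectors, dual coefficients and bias, so a saved and reloaded model
    reproduces scores exactly.
    """

    def __init__(
        self,
        support_vectors: np.ndarray,
        dual_coef: np.ndarray,
        intercept: float,
        lbp_bins: int = N_BINS,
    ):
        self.support_vectors = np.asarray(support_vectors, dtype=np.float64)
        self.dual_coef = np.asarray(dual_coef, dtype=np.float64)
        self.intercept = float(intercept)
        self.lbp_bins = int(lbp_bins)

    def decision(self, feat: LBPFeature) -> float:
        """Signed score; >= 0 means fruit."""
        k = np.minimum(self.support_vectors, feat.histogram[None, :]).sum(axis=1)
        return float(self.dual_coef @ k + self.intercept)

    def predict(self, feat: LBPFeature) -> int:
        return 1 if self.decision(feat) >= 0 else -1

    def save(self, path: str | Path) -> None:
        payload = {
            "kernel": "hik",
            "lbp_bins": self.lbp_bins,
            "support_vectors": [[v.hex() for v in row] for row in self.support_vectors],
            "dual_coef": [v.hex() for v in self.dual_coef],
            "intercept": self.intercept.hex(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("kernel") != "hik":
            raise ValueError("not an HIK classifier file")
        sv = np.array(
            [[float.fromhex(v) for v in row] for row in payload["support_vectors"]],
            dtype=np.float64,
        )
        dual = np.array([float.fromhex(v) for v in payload["dual_coef"]], dtype=np.float64)
        return cls(sv, dual, float.fromhex(payload["intercept"]), payload["lbp_bins"])


def train(
    pos: list[LBPFeature], neg: list[LBPFeature], C: float = 1.0
) -> TrainedClassifier:
    """Fit the HIK SVM on fruit (+1) vs background (-1) features.

    Deterministic for a fixed input order. Raises on single-class input.
    """
    if not pos or not neg:
        raise ValueError("both classes must be nonempty")
    feats = pos + neg
    x = np.stack([f.histogram for f in feats])
    y = np.array([1] * len(pos) + [-1] * len(neg))
    gram = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(gram, y)
    sv = x[svc.support_]
    # sklearn orients the decision so positive scores favor classes_[1] = +1
    return TrainedClassifier(sv, svc.dual_coef_[0], float(svc.intercept_[0]))


def filter_detections(
    dets: list[Circle],
    img: np.ndarray,
    clf: TrainedClassifier,
    patch_size: int = 32,
) -> tuple[list[tuple[Circle, float]], list[tuple[Circle, float]]]:
    """Split detections into (accepted, rejected) lists with scores.

    A detection is accepted iff its patch's LBP feature scores >= 0
    (ties accepted). Scores are returned for auditability.
    """
    accepted: list[tuple[Circle, float]] = []
    rejected: list[tuple[Circle, float]] = []
    for det in dets:
        feat = uniform_lbp(extract_patch(img, det, patch_size))
        score = clf.decision(feat)
        (accepted if score >= 0 else rejected).append((det, score))
    return accepted, rejected
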