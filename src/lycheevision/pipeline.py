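"""End-to-end detection: preprocess -> segment -> status -> split -> gate -> filter.

Every extracted region is routed by its status: isolated regions yield
their equivalent area circle, occluded regions the largest Hough circle
(the arc-completion circle of the hidden fruit), overlapped regions the
polar-profile split circles. Candidates then pass the pixel-size gate
and, optionally, the LBP-SVM texture filter. Each region leaves a
structured log record per stage so nothing is dropped silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .core import Circle, RegionStatus
from .metrics import MetricsReport, compute_report, match_detections
from .polar_split import CentroidOutsideError, split_overlapped
from .preprocess import CLAHEParams, clahe_compensate
from .segmentation import extract_regions, morph_clean, otsu_threshold, chromatic_map, ConstantMapError
from .status import classify_region
from .texture_filter import TrainedClassifier, extract_patch, uniform_lbp

logger = logging.getLogger(__name__)

__all__ = ["Detection", "detect", "batch_evaluate", "load_ground_truth_circles"]


@dataclass
class Detection:
    circle: Circle
    source_status: RegionStatus
    region_label: int
    classifier_score: float | None = None
    accepted: bool = True

    def to_dict(self) -> dict:
        return {
            "cx": float(self.circle.cx),
            "cy": float(self.circle.cy),
            "r": float(self.circle.r),
            "status": int(self.source_status),
            "score": None if self.classifier_score is None else float(self.classifier_score),
            "accepted": bool(self.accepted),
        }


def detect(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    model: TrainedClassifier | None = None,
    return_rejected: bool = False,
) -> list[Detection]:
    """Run the full detection pipeline on one RGB image.

    Returns accepted detections (also the gated/rejected ones when
    ``return_rejected`` is set). An image with no foreground content
    yields an empty list.
    """
    if cfg is None:
        cfg = PipelineConfig()

    work = img
    if cfg.clahe.enabled:
        work = clahe_compensate(img, CLAHEParams(cfg.clahe.blocks, cfg.clahe.clip_limit))

    cmap = chromatic_map(work)
    try:
        _, raw_mask = otsu_threshold(cmap)
    except ConstantMapError:
        return []
    mask = morph_clean(raw_mask, cfg.morph.erode_r, cfg.morph.dilate_r)
    regions = extract_regions(mask)

    candidates: list[Detection] = []
    for region in regions:
        status, area_circle, houghs = classify_region(region, cfg.status)
        if status == RegionStatus.ISOLATED:
            circles = [area_circle]
        elif status == RegionStatus.OCCLUDED:
            circles = [max(houghs, key=lambda c: c.r)] if houghs else [area_circle]
        else:
            try:
                circles = split_overlapped(
                    region, cfg.split.smooth_win, cfg.split.min_prominence
                )
            except CentroidOutsideError as err:
                logger.info("region %d: %s; using area circle", region.label, err)
                circles = [area_circle]
        logger.debug(
            "region %d: status=%s area=%d -> %d candidate circle(s)",
            region.label, status.name, region.area, len(circles),
        )
        for c in circles:
            candidates.append(Detection(c, status, region.label))

    # pixel-size gate on candidate circle area
    kept: list[Detection] = []
    for det in candidates:
        area = det.circle.area
        if cfg.gate.lo <= area <= cfg.gate.hi:
            kept.append(det)
        else:
            det.accepted = False
            logger.debug(
                "candidate at (%.1f, %.1f) r=%.1f gated out (area %.0f px, status %s)",
                det.circle.cx, det.circle.cy, det.circle.r, area,
                det.source_status.name,
            )

    if model is not None:
        for det in kept:
            feat = uniform_lbp(extract_patch(img, det.circle))
            det.classifier_score = model.decision(feat)
            det.accepted = det.classifier_score >= 0
    accepted = [d for d in kept if d.accepted]
    if return_rejected:
        rejected = [d for d in candidates if not d.accepted]
        return accepted + rejected
    return accepted


def load_ground_truth_circles(path: str | Path) -> list[Circle]:
    """Read a ground-truth JSON file: a list of {cx, cy, r, ...} records."""
    data = json.loads(Path(path).read_text())
    records = data["fruits"] if isinstance(data, dict) else data
    return [Circle.from_dict(rec) for rec in records]


def batch_evaluate(
    scene_dir: str | Path,
    cfg: PipelineConfig | None = None,
    model: TrainedClassifier | None = None,
) -> tuple[MetricsReport, dict[str, MetricsReport]]:
    """Evaluate every (image, ground-truth) pair in a directory.

    Pairs are ``<stem>.png`` + ``<stem>.json``. Returns the pooled report
    (counts summed over scenes) and the per-scene reports. Unpaired files
    raise with the offending names listed.
    """
    import imageio.v3 as iio

    if cfg is None:
        cfg = PipelineConfig()
    scene_dir = Path(scene_dir)
    images = sorted(scene_dir.glob("*.png"))
    truths = sorted(scene_dir.glob("*.json"))
    img_stems = {p.stem for p in images}
    json_stems = {p.stem for p in truths}
    unpaired = sorted(img_stems ^ json_stems)
    if unpaired:
        raise ValueError(f"unpaired scene files: {unpaired}")
    if not images:
        raise ValueError(f"no scene pairs found in {scene_dir}")

    per_scene: dict[str, MetricsReport] = {}
    tp = fn = fp = 0
    for img_path in images:
        img = iio.imread(img_path)
        truth = load_ground_truth_circles(img_path.with_suffix(".json"))
        dets = [d.circle for d in detect(img, cfg, model)]
        s_tp, s_fn, s_fp, _ = match_detections(dets, truth, cfg.eval.iou)
        tp, fn, fp = tp + s_tp, fn + s_fn, fp + s_fp
        if s_tp + s_fp > 0 and s_tp + s_fn > 0:
            per_scene[img_path.stem] = compute_report(s_tp, s_fn, s_fp)
    pooled = compute_report(tp, fn, fp)
    return pooled, per_scene
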