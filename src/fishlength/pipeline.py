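"""End-to-end measurement: segment, classify, (straighten,) back-project.

``run_measure`` mirrors the measurement software's flow: GrabCut
segmentation inside the operator's rectangle, mask cleanup, bounding-box
geometry and bend classification, the straight or bent measurement path,
refraction-corrected back-projection, and a JSON-serializable report.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import MeasureConfig
from .errors import FishLengthError
from .measurement import (
    classify_pose,
    clean_mask,
    fill_holes,
    fish_geometry,
    measure_length,
    straight_points,
    straighten,
)
from .segmentation import contrast_adapt, grabcut
from .skeleton import extract_midline

__all__ = ["run_measure", "StageError"]

log = logging.getLogger("fishlength")


class StageError(FishLengthError):
    """Wraps an error with the pipeline stage where it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except FishLengthError as exc:
                raise StageError(name, exc) from exc
            log.debug("stage %s: %.1f ms", name, 1e3 * (time.perf_counter() - t0))
            return out

        return wrapped

    return deco


def run_measure(
    cfg: MeasureConfig,
    rgb: np.ndarray,
    depth: np.ndarray,
    roi: tuple[int, int, int, int],
    *,
    ignore_refraction: bool = False,
    debug_dir: str | Path | None = None,
) -> dict:
    """Measure the fish inside ``roi`` and return the measurement report.

    The report carries the pose, bend angle, the 2D measurement points with
    their sampled depths, the corrected and uncorrected lengths in
    millimetres, and any warnings.  With no refraction section in the config
    (or ``ignore_refraction=True``) the corrected length equals the
    uncorrected one.
    """
    cam = cfg.camera_model()
    rm = None if ignore_refraction else cfg.refraction_model()
    seg_cfg = cfg.segmentation.to_model()

    adapted = _stage("contrast")(contrast_adapt)(rgb, seg_cfg)
    mask, energy = _stage("segment")(grabcut)(adapted, roi, seg_cfg)
    mask = _stage("clean")(lambda m: fill_holes(clean_mask(m)))(mask)
    geom = _stage("geometry")(fish_geometry)(mask)
    # depth is sampled on an eroded mask: boundary pixels mix fish and
    # background readings (the bottom is a valid depth too)
    depth_mask = ndimage.binary_erosion(mask, np.ones((3, 3), bool), iterations=2)
    if not depth_mask.any():
        depth_mask = mask
    pose = classify_pose(geom.theta_bend, cfg.measurement.theta_threshold_deg)
    if pose == "straight":
        points = _stage("points")(straight_points)(geom, depth, depth_mask)
    else:
        midline = _stage("skeleton")(extract_midline)(mask, cfg.skeleton.max_deletions)
        points = _stage("points")(straighten)(geom, midline, depth, depth_mask)
    result = _stage("measure")(measure_length)(points, cam, rm, geom.theta_bend)

    if debug_dir is not None:
        _write_debug(Path(debug_dir), adapted, mask, pose, locals())

    warnings = list(points.warnings)
    if not energy:
        warnings.append("segmentation collapsed before any energy evaluation")
    return {
        "pose": pose,
        "theta_deg": round(geom.theta_bend, 3),
        "head_px": [round(points.head.u, 2), round(points.head.v, 2)],
        "tail_px": [round(points.tail.u, 2), round(points.tail.v, 2)],
        "head_depth_mm": round(points.head_depth_mm, 2),
        "tail_depth_mm": round(points.tail_depth_mm, 2),
        "length_mm": round(result.length_mm, 2),
        "length_mm_uncorrected": round(result.length_mm_uncorrected, 2),
        "arc_length_px": (
            round(points.arc_length_px, 2) if points.arc_length_px is not None else None
        ),
        "refraction_applied": rm is not None,
        "warnings": warnings,
    }


def _write_debug(debug_dir: Path, adapted, mask, pose, ns) -> None:
    from .io import write_mask, write_rgb

    debug_dir.mkdir(parents=True, exist_ok=True)
    write_rgb(debug_dir / "contrast_adapted.png", adapted)
    write_mask(debug_dir / "mask.png", mask)
    if pose == "bent" and "midline" in ns:
        overlay = adapted.copy()
        overlay[ns["midline"].image] = (255, 0, 0)
        write_rgb(debug_dir / "skeleton_overlay.png", overlay)
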