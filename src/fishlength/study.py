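"""Synthetic measurement study: the in-silico analogue of the bucket
experiment (water depth 500 mm; camera 250 / 350 / 450 mm above the surface).

Each trial renders one free-swimming fish (length 250-320 mm; straight fish
carry a small random pitch, bent fish bend in the horizontal plane), runs
the full measurement pipeline on the rendered RGB-D pair, and records the
corrected and uncorrected length estimates against the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .camera import CameraModel, Point3D
from .config import (
    CameraSection,
    MeasureConfig,
    MeasurementSection,
    RefractionSection,
    SegmentationSection,
    SkeletonSection,
)
from .measurement import evaluate
from .pipeline import run_measure
from .refraction import RefractionModel
from .synthetic import FishSpec, SceneSpec, default_camera, refract_project, render_scene

__all__ = ["Trial", "sample_fish", "build_scene", "measure_scene", "run_study", "summarize"]

WATER_DEPTH_MM = 500.0
CAMERA_HEIGHTS_MM = (250.0, 350.0, 450.0)


@dataclass
class Trial:
    height_mm: float
    seed: int
    pose_true: str
    true_length_mm: float
    est_corrected_mm: float
    est_uncorrected_mm: float
    pose_measured: str
    theta_deg: float


def _camera_section(cam: CameraModel) -> CameraSection:
    return CameraSection(
        fx=cam.fx,
        fy=cam.fy,
        cx=cam.u0,
        cy=cam.v0,
        baseline_mm=cam.baseline_mm,
        width=cam.resolution[0],
        height=cam.resolution[1],
    )


def study_config(height_mm: float, seg_seed: int = 0) -> MeasureConfig:
    cam = default_camera()
    return MeasureConfig(
        camera=_camera_section(cam),
        refraction=RefractionSection(
            camera_placement_mm=height_mm + WATER_DEPTH_MM, water_depth_mm=WATER_DEPTH_MM
        ),
        segmentation=SegmentationSection(rng_seed=seg_seed),
        skeleton=SkeletonSection(),
        measurement=MeasurementSection(),
    )


def sample_fish(
    rng: np.random.Generator,
    rm: RefractionModel,
    cam: CameraModel,
    *,
    bent: bool,
) -> FishSpec:
    """Draw a fish that fits fully inside the camera frame.

    Lengths are uniform on 250-320 mm, widths about a fifth of the length,
    depths in the middle of the water column; straight fish pitch by a small
    random angle.  Placement is rejection-sampled against the refracted
    silhouette of the spine.
    """
    W, H = cam.resolution
    for attempt in range(60):
        length = float(rng.uniform(250.0, 320.0))
        width = length * float(rng.uniform(0.18, 0.24))
        depth = float(rng.uniform(150.0, 400.0))
        shrink = 0.85**attempt
        offset = tuple(rng.uniform(-40.0, 40.0, size=2) * shrink)
        if bent:
            curv = math.radians(float(rng.uniform(40.0, 110.0))) / length
            curv *= float(rng.choice([-1.0, 1.0]))
            pitch = 0.0
        else:
            curv = 0.0
            pitch = float(np.clip(rng.normal(0.0, 8.0), -20.0, 20.0))
        spec = FishSpec(
            true_length_mm=length,
            max_width_mm=width,
            depth_below_surface_mm=depth,
            position_xy_mm=offset,
            orientation_deg=float(rng.uniform(0.0, 360.0)),
            curvature_per_mm=curv,
            pitch_deg=pitch,
            body_gray=int(rng.integers(55, 90)),
        )
        spine = spec.spine_points(80) + np.array(
            [offset[0], offset[1], rm.camera_height_mm + depth]
        )
        margin = width * 0.7 * cam.fx / (rm.camera_height_mm + depth * 0.75)
        ok = True
        for p in spine[::8]:
            u, v = refract_project(Point3D(*p), cam, rm)
            if not (margin + 2 <= u < W - margin - 2 and margin + 2 <= v < H - margin - 2):
                ok = False
                break
        if ok:
            return spec
    raise RuntimeError("could not place a fish inside the frame")


def build_scene(height_mm: float, seed: int, *, bent: bool) -> SceneSpec:
    cam = default_camera()
    rm = RefractionModel(camera_height_mm=height_mm)
    rng = np.random.default_rng(seed)
    fish = sample_fish(rng, rm, cam, bent=bent)
    return SceneSpec(
        camera=cam,
        refraction=rm,
        water_depth_mm=WATER_DEPTH_MM,
        fish=(fish,),
        seed=seed,
    )


def measure_scene(scene: SceneSpec, *, roi_pad: int = 12) -> list[Trial]:
    """Render a scene and measure every fish with the default pipeline config."""
    rgb, depth, truth = render_scene(scene)
    height = scene.refraction.camera_height_mm
    cfg = study_config(height, seg_seed=scene.seed)
    W, H = scene.camera.resolution
    out = []
    for i, roi in enumerate(truth.rois):
        x, y, w, h = roi
        x0, y0 = max(x - roi_pad, 0), max(y - roi_pad, 0)
        x1, y1 = min(x + w + roi_pad, W), min(y + h + roi_pad, H)
        report = run_measure(cfg, rgb, depth, (x0, y0, x1 - x0, y1 - y0))
        out.append(
            Trial(
                height_mm=height,
                seed=scene.seed,
                pose_true=truth.poses[i],
                true_length_mm=truth.true_lengths_mm[i],
                est_corrected_mm=report["length_mm"],
                est_uncorrected_mm=report["length_mm_uncorrected"],
                pose_measured=report["pose"],
                theta_deg=report["theta_deg"],
            )
        )
    return out


def run_study(
    heights=CAMERA_HEIGHTS_MM,
    n_fish: int = 10,
    seeds=(0, 1, 2),
    base_seed: int = 0,
) -> list[Trial]:
    """The full study grid: ``heights x n_fish x seeds`` single-fish scenes.

    Half of the fish in each replicate are bent (alternating), matching the
    mix of poses a stirred bucket produces.
    """
    trials: list[Trial] = []
    for hi, height in enumerate(heights):
        for si, seed in enumerate(seeds):
            for fi in range(n_fish):
                scene_seed = (base_seed % 1000) * 1_000_000 + hi * 100_000 + si * 10_000 + fi
                scene = build_scene(height, scene_seed, bent=(fi % 2 == 1))
                trials.extend(measure_scene(scene))
    return trials


def summarize(trials: list[Trial]) -> dict:
    """Per-height corrected / uncorrected MRPE (percent)."""
    out: dict = {}
    for height in sorted({t.height_mm for t in trials}):
        sel = [t for t in trials if t.height_mm == height]
        est_c = [t.est_corrected_mm for t in sel]
        est_u = [t.est_uncorrected_mm for t in sel]
        tru = [t.true_length_mm for t in sel]
        out[height] = {
            "n": len(sel),
            "mrpe_corrected_pct": evaluate(est_c, tru).mrpe_percent,
            "mrpe_uncorrected_pct": evaluate(est_u, tru).mrpe_percent,
        }
    return out
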