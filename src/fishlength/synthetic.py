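"""Ground-truthed synthetic RGB-D scenes of submerged fish.

The generator is the physics oracle for the measurement pipeline: it renders
top-view fish silhouettes below a flat air-water interface by *exact* Snell
ray tracing (no small-angle approximation) and fills the depth channel with
the reading an ideal stereo camera would produce for the refracted scene -
i.e. with the refraction-distorted apparent depth, not the true depth.

Geometry: the world frame is the reference camera frame (origin at the
optical centre, Z down); the water surface is the plane ``Z = h``; the two
stereo pinholes sit at ``(+-B/2, 0, 0)``.  A fish is a teardrop-profile body
swept along a circular-arc spine (curvature 0 = straight); straight fish may
pitch out of the horizontal plane, which spreads head and tail over depth
exactly as a tilted live fish does.

Everything is deterministic under the scene seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .camera import CameraModel, PixelPoint, Point3D, plane_to_pixel
from .errors import InvalidArgumentError, ProjectionFailureError
from .refraction import RefractionModel

__all__ = [
    "FishSpec",
    "SceneSpec",
    "SceneTruth",
    "default_camera",
    "make_fish_mask",
    "refract_project",
    "apparent_depth",
    "render_scene",
]


def default_camera() -> CameraModel:
    """640x480 stereo RGB-D camera with a 50 mm baseline (RealSense-like)."""
    return CameraModel(
        focal_length_px_x=600.0,
        focal_length_px_y=600.0,
        principal_point=(320.0, 240.0),
        baseline_mm=50.0,
        resolution=(640, 480),
    )


@dataclass(frozen=True)
class FishSpec:
    """One synthetic fish.

    ``curvature_per_mm`` is the signed spine curvature (0 = straight); a
    bent fish bends in the horizontal plane.  ``pitch_deg`` tilts a straight
    fish's spine out of the horizontal plane (head up / down), which is what
    free-swimming fish do; it is ignored for bent fish.
    """

    true_length_mm: float
    max_width_mm: float
    depth_below_surface_mm: float
    position_xy_mm: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0
    curvature_per_mm: float = 0.0
    pitch_deg: float = 0.0
    body_gray: int = 70

    def __post_init__(self) -> None:
        if not (self.true_length_mm > self.max_width_mm > 0):
            raise InvalidArgumentError("need true_length > max_width > 0")
        if self.depth_below_surface_mm <= 0:
            raise InvalidArgumentError("fish must be below the surface")

    def spine_points(self, n: int = 400) -> np.ndarray:
        """(n, 3) spine polyline in fish-local mm: arc in the XY plane,
        pitched along Z for straight fish, centred at the origin."""
        s = np.linspace(0.0, self.true_length_mm, n)
        k = self.curvature_per_mm
        if abs(k) < 1e-12:
            # s is 3D arc length: the pitched spine keeps its total length
            c = s - self.true_length_mm / 2.0
            x = math.cos(math.radians(self.pitch_deg)) * c
            y = np.zeros_like(s)
            z = math.sin(math.radians(self.pitch_deg)) * c
        else:
            # circular arc, re-centred so the chord midpoint sits at the origin
            x = np.sin(k * s) / k
            y = (1.0 - np.cos(k * s)) / k
            x -= (x[0] + x[-1]) / 2.0
            y -= (y[0] + y[-1]) / 2.0
            z = np.zeros_like(s)
        a = math.radians(self.orientation_deg)
        xr = x * math.cos(a) - y * math.sin(a)
        yr = x * math.sin(a) + y * math.cos(a)
        return np.stack([xr, yr, z], axis=1)

    def half_width(self, t: np.ndarray) -> np.ndarray:
        """Fusiform half-width profile vs normalized arc position t in [0, 1].

        The sqrt-of-sine profile gives the blunt, rounded snout and tail of a
        real fish body; the half-width reaches pixel scale within <0.1% of
        the length from either end, so the rasterized silhouette preserves
        the nominal tip-to-tip length.
        """
        return 0.5 * self.max_width_mm * np.sin(np.pi * np.clip(t, 0.0, 1.0)) ** 0.5


@dataclass(frozen=True)
class SceneSpec:
    """A full RGB-D scene: camera, interface, bucket and fish."""

    camera: CameraModel
    refraction: RefractionModel
    water_depth_mm: float
    fish: tuple[FishSpec, ...]
    rgb_noise_sigma: float = 4.0
    depth_noise_sigma_mm: float = 2.0
    psf_sigma_px: float = 0.8
    background_gray: int = 170
    seed: int = 0

    def __post_init__(self) -> None:
        if self.water_depth_mm <= 0:
            raise InvalidArgumentError("water depth must be positive")
        for f in self.fish:
            if f.depth_below_surface_mm > self.water_depth_mm:
                raise InvalidArgumentError("fish deeper than the water column")


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene."""

    true_lengths_mm: list[float]
    masks: list[np.ndarray]
    spines_world: list[np.ndarray]
    rois: list[tuple[int, int, int, int]]
    poses: list[str]
    overlap_warning: bool = False


# ---------------------------------------------------------------------------
# Forward Snell ray tracing
# ---------------------------------------------------------------------------

def _solve_crossing(R, Zt, h, na, nw, iters: int = 52):
    """Radius s on the surface where the camera->point ray crosses, solving
    na*sin(atan(s/h)) = nw*sin(atan((R-s)/(Zt-h))) by bisection on [0, R].

    Vectorized; unconditionally convergent because the residual is strictly
    increasing in s on the bracket.
    """
    R = np.asarray(R, dtype=np.float64)
    Zt = np.asarray(Zt, dtype=np.float64)
    lo = np.zeros_like(R)
    hi = R.copy()
    t = Zt - h
    for _ in range(iters):
        s = 0.5 * (lo + hi)
        f = na * s / np.hypot(s, h) - nw * (R - s) / np.hypot(R - s, t)
        neg = f < 0
        lo = np.where(neg, s, lo)
        hi = np.where(neg, hi, s)
    return 0.5 * (lo + hi)


def _plane_coords(points: np.ndarray, cam_x: float, rm: RefractionModel):
    """Normalized image-plane coordinates of submerged 3D points as seen by a
    pinhole at (cam_x, 0, 0) through the interface."""
    h = rm.camera_height_mm
    rel = points[:, :2] - np.array([cam_x, 0.0])
    R = np.hypot(rel[:, 0], rel[:, 1])
    Z = points[:, 2]
    if rm.n_water == rm.n_air:
        s_over_R = np.where(R > 0, h / Z, 0.0)
    else:
        s = _solve_crossing(R, Z, h, rm.n_air, rm.n_water)
        s_over_R = np.where(R > 0, s / np.maximum(R, 1e-300), 0.0)
    return rel * (s_over_R / h)[:, None]


def refract_project(P: Point3D, cam: CameraModel, rm: RefractionModel) -> PixelPoint:
    """Pixel where a submerged point images through the flat interface.

    Exact forward model (bisection tolerance far below a micro-pixel); with
    ``n_water == n_air`` it reduces to the ideal pinhole projection.
    """
    if P.Z <= rm.camera_height_mm:
        raise ProjectionFailureError(
            f"point depth {P.Z} mm is above the water surface "
            f"(h={rm.camera_height_mm} mm)"
        )
    q = _plane_coords(np.array([P], dtype=float), 0.0, rm)[0]
    return plane_to_pixel((float(q[0]), float(q[1])), cam)


def apparent_depth(P: Point3D, cam: CameraModel, rm: RefractionModel) -> float:
    """Depth a naive stereo camera reports for a submerged point.

    The point is refract-projected through both stereo pinholes at
    ``(+-B/2, 0, 0)``; the disparity is converted back through ``Z = B f / d``.
    Smaller than the true depth whenever ``n_water > n_air``.
    """
    return float(_apparent_depth_arr(np.array([P], dtype=float), cam, rm)[0])


def _apparent_depth_arr(points: np.ndarray, cam: CameraModel, rm: RefractionModel) -> np.ndarray:
    B = cam.baseline_mm
    xl = _plane_coords(points, -B / 2.0, rm)[:, 0]
    xr = _plane_coords(points, +B / 2.0, rm)[:, 0]
    d = xl - xr
    if np.any(d <= 0):
        raise ProjectionFailureError("non-positive stereo disparity (grazing geometry)")
    return B / d


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _membership(xy: np.ndarray, spine: np.ndarray, spec: FishSpec):
    """Distance test of planar points against the swept-profile body.

    Returns (inside, t, dist) with t the normalized arc position of the
    nearest spine sample.
    """
    tree = cKDTree(spine[:, :2])
    dist, idx = tree.query(xy, workers=1)
    t = idx / (len(spine) - 1.0)
    return dist <= spec.half_width(t), t, dist


def make_fish_mask(spec: FishSpec, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic rasterization of a fish at ``scale`` px per mm.

    Returns the binary mask and the ground-truth spine polyline in pixel
    coordinates ``(u, v)``; the polyline's arc length equals
    ``true_length_mm * scale`` to well under 0.5%.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    spine = spec.spine_points()
    margin = spec.max_width_mm
    lo = spine[:, :2].min(axis=0) - margin
    hi = spine[:, :2].max(axis=0) + margin
    size = np.ceil((hi - lo) * scale).astype(int) + 1
    if size.max() > 20000:
        raise InvalidArgumentError("fish exceeds a sane canvas at this scale")
    w, h = int(size[0]), int(size[1])
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    xy = np.stack([uu.ravel() / scale + lo[0], vv.ravel() / scale + lo[1]], axis=1)
    inside, _, _ = _membership(xy, spine, spec)
    mask = inside.reshape(h, w)
    spine_px = (spine[:, :2] - lo) * scale
    return mask, spine_px


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render the refraction-distorted RGB and depth images plus ground truth.

    The RGB canvas holds each fish's *refracted* silhouette (dark body on a
    lighter background with additive Gaussian noise); the 16-bit depth image
    holds the stereo apparent depth of each visible surface point in
    millimetres.  Both are deterministic under ``spec.seed``.
    """
    cam = spec.camera
    rm = spec.refraction
    h = rm.camera_height_mm
    W, H = cam.resolution
    rng = np.random.default_rng(spec.seed)

    uu, vv = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    px = (uu - cam.u0) / cam.fx
    py = (vv - cam.v0) / cam.fy
    r = np.hypot(px, py)
    sin_a = r / np.hypot(r, 1.0)
    sin_b = (rm.n_air / rm.n_water) * sin_a
    tan_b = sin_b / np.sqrt(1.0 - sin_b**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, px / r, 0.0)
        uy = np.where(r > 0, py / r, 0.0)
    surf_x, surf_y = px * h, py * h

    def world_at_depth(Z):
        """Lateral world position where each pixel's water-side ray reaches depth Z."""
        reach = (Z - h) * tan_b
        return surf_x + reach * ux, surf_y + reach * uy

    gray = np.full((H, W), float(spec.background_gray))
    Z_bot = h + spec.water_depth_mm
    bx, by = world_at_depth(Z_bot)
    bottom_pts = np.stack([bx.ravel(), by.ravel(), np.full(bx.size, Z_bot)], axis=1)
    depth = _apparent_depth_arr(bottom_pts, cam, rm).reshape(H, W)

    truth = SceneTruth([], [], [], [], [])
    occupancy = np.zeros((H, W), dtype=bool)
    for fish in spec.fish:
        z0 = h + fish.depth_below_surface_mm
        spine = fish.spine_points()
        spine_world = spine + np.array([fish.position_xy_mm[0], fish.position_xy_mm[1], z0])
        # bounding box of the refracted silhouette, with a width margin
        proj = np.array(
            [refract_project(Point3D(*p), cam, rm) for p in spine_world[:: len(spine_world) // 40]]
        )
        pad_px = fish.max_width_mm * cam.fx / (z0 - (z0 - h) * (1 - rm.n_air / rm.n_water))
        u0b = max(int(proj[:, 0].min() - pad_px), 0)
        u1b = min(int(proj[:, 0].max() + pad_px) + 1, W)
        v0b = max(int(proj[:, 1].min() - pad_px), 0)
        v1b = min(int(proj[:, 1].max() + pad_px) + 1, H)
        if u1b <= u0b or v1b <= v0b:
            truth.true_lengths_mm.append(fish.true_length_mm)
            truth.masks.append(np.zeros((H, W), dtype=bool))
            truth.spines_world.append(spine_world)
            truth.rois.append((0, 0, 0, 0))
            truth.poses.append("bent" if abs(fish.curvature_per_mm) > 1e-12 else "straight")
            continue
        sl = (slice(v0b, v1b), slice(u0b, u1b))
        tree_xy = spine_world[:, :2]
        # iterate pixel depth against the (possibly pitched) fish plane
        Zf = np.full((v1b - v0b, u1b - u0b), z0)
        tree = cKDTree(tree_xy)
        for _ in range(3):
            fx_, fy_ = (
                surf_x[sl] + (Zf - h) * tan_b[sl] * ux[sl],
                surf_y[sl] + (Zf - h) * tan_b[sl] * uy[sl],
            )
            pts = np.stack([fx_.ravel(), fy_.ravel()], axis=1)
            dist, idx = tree.query(pts, workers=1)
            Zf = spine_world[idx, 2].reshape(Zf.shape)
        t = idx / (len(spine_world) - 1.0)
        inside = (dist <= fish.half_width(t)).reshape(Zf.shape)
        mask = np.zeros((H, W), dtype=bool)
        mask[sl] = inside
        if (mask & occupancy).any():
            truth.overlap_warning = True
        occupancy |= mask
        gray[mask] = float(fish.body_gray)
        fish_pts = np.stack(
            [fx_.ravel()[inside.ravel()], fy_.ravel()[inside.ravel()], Zf.ravel()[inside.ravel()]],
            axis=1,
        )
        depth[mask] = _apparent_depth_arr(fish_pts, cam, rm)

        rr, cc = np.nonzero(mask)
        roi = (
            int(cc.min()),
            int(rr.min()),
            int(cc.max() - cc.min() + 1),
            int(rr.max() - rr.min() + 1),
        )
        truth.true_lengths_mm.append(fish.true_length_mm)
        truth.masks.append(mask)
        truth.spines_world.append(spine_world)
        truth.rois.append(roi)
        truth.poses.append("bent" if abs(fish.curvature_per_mm) > 1e-12 else "straight")

    if spec.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        gray = gaussian_filter(gray, spec.psf_sigma_px)  # optical point-spread
    rgb = gray[:, :, None] + rng.normal(0.0, spec.rgb_noise_sigma, (H, W, 3))
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    depth = depth + rng.normal(0.0, spec.depth_noise_sigma_mm, (H, W))
    depth = np.clip(np.rint(depth), 0, 65535).astype(np.uint16)
    return rgb, depth, truth
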