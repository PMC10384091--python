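import math

import numpy as np
import pytest

from fishlength.camera import CameraModel, Point3D
from fishlength.refraction import RefractionModel
from fishlength.synthetic import FishSpec, SceneSpec, default_camera, render_scene


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    return default_camera()


@pytest.fixture(scope="session")
def rm250() -> RefractionModel:
    return RefractionModel(camera_height_mm=250.0)


@pytest.fixture(scope="session")
def straight_scene(cam):
    """One rendered straight-fish scene at 350 mm camera height (cached)."""
    rm = RefractionModel(camera_height_mm=350.0)
    fish = FishSpec(
        true_length_mm=300.0,
        max_width_mm=62.0,
        depth_below_surface_mm=260.0,
        position_xy_mm=(8.0, -12.0),
        orientation_deg=15.0,
        pitch_deg=6.0,
    )
    scene = SceneSpec(camera=cam, refraction=rm, water_depth_mm=500.0, fish=(fish,), seed=42)
    rgb, depth, truth = render_scene(scene)
    return scene, rgb, depth, truth


@pytest.fixture(scope="session")
def bent_scene(cam):
    """One rendered bent-fish scene (quarter-turn arc) at 350 mm height."""
    rm = RefractionModel(camera_height_mm=350.0)
    L = 280.0
    fish = FishSpec(
        true_length_mm=L,
        max_width_mm=58.0,
        depth_below_surface_mm=240.0,
        orientation_deg=-30.0,
        curvature_per_mm=math.radians(80.0) / L,
    )
    scene = SceneSpec(camera=cam, refraction=rm, water_depth_mm=500.0, fish=(fish,), seed=43)
    rgb, depth, truth = render_scene(scene)
    return scene, rgb, depth, truth


def random_blob(rng: np.random.Generator, size: int = 80) -> np.ndarray:
    """An elongated multi-ellipse blob (single filled component)."""
    from scipy import ndimage

    img = np.zeros((size, size), dtype=bool)
    cx = rng.integers(20, size - 20)
    cy = rng.integers(20, size - 20)
    ang0 = rng.uniform(0, np.pi)
    yy, xx = np.ogrid[:size, :size]
    for j in range(int(rng.integers(2, 5))):
        a = rng.integers(12, 26)
        b = rng.integers(3, 9)
        ang = ang0 + rng.normal(0.0, 0.5)
        r0 = cy + rng.integers(-8, 9)
        c0 = cx + rng.integers(-8, 9)
        X = (xx - c0) * np.cos(ang) + (yy - r0) * np.sin(ang)
        Y = -(xx - c0) * np.sin(ang) + (yy - r0) * np.cos(ang)
        img |= (X / a) ** 2 + (Y / b) ** 2 <= 1
    labels, n = ndimage.label(img, np.ones((3, 3)))
    sizes = ndimage.sum(img, labels, range(1, n + 1))
    img = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(img)


def submerged_point(rng, rm: RefractionModel, max_angle_deg: float, max_depth: float) -> Point3D:
    """A random underwater point whose air-side ray is within max_angle_deg."""
    h = rm.camera_height_mm
    mu = rm.n_air / rm.n_water
    t = rng.uniform(20.0, max_depth)
    a = math.radians(rng.uniform(0.0, max_angle_deg))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    sb = mu * math.sin(a)
    tb = sb / math.sqrt(1.0 - sb * sb)
    R = h * math.tan(a) + t * tb
    return Point3D(R * math.cos(phi), R * math.sin(phi), h + t)
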