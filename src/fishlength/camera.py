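"""Pinhole / stereo camera model and coordinate conversions.

Conventions
-----------
* Pixel coordinates ``(u, v)`` are 0-based ``(column, row)`` with the origin at
  the top-left corner; sub-pixel values are allowed.
* Image-plane coordinates are *pixel-normalized*: ``x = (u - u0) / fx``,
  ``y = (v - v0) / fy``.  In these units the focal length is 1, which is the
  standard intrinsics parameterization and what the refraction model assumes.
* 3D points live in the camera frame, millimetres, ``Z`` along the optical
  axis pointing down at the water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InvalidArgumentError

__all__ = [
    "CameraModel",
    "PixelPoint",
    "PlanePoint",
    "Point3D",
    "pixel_to_plane",
    "plane_to_pixel",
    "depth_from_disparity",
    "backproject",
    "euclidean_length",
]


class PixelPoint(NamedTuple):
    u: float
    v: float


class PlanePoint(NamedTuple):
    x: float
    y: float


class Point3D(NamedTuple):
    X: float
    Y: float
    Z: float


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics plus the stereo baseline.

    Parameters
    ----------
    focal_length_px_x, focal_length_px_y
        Focal length expressed in pixels (``f/dx``, ``f/dy``).  Square pixels
        (``fx == fy``) are the default in shipped configs, but anisotropic
        values are supported.
    principal_point
        ``(u0, v0)`` in pixels; must lie inside the image bounds.
    baseline_mm
        Stereo baseline ``B`` in millimetres.
    resolution
        ``(width, height)`` in pixels.
    """

    focal_length_px_x: float
    focal_length_px_y: float
    principal_point: tuple[float, float]
    baseline_mm: float
    resolution: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.focal_length_px_x > 0 and self.focal_length_px_y > 0):
            raise InvalidArgumentError("focal lengths must be positive")
        if self.baseline_mm <= 0:
            raise InvalidArgumentError("stereo baseline must be positive")
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise InvalidArgumentError("resolution must be positive")
        u0, v0 = self.principal_point
        if not (0 <= u0 <= w and 0 <= v0 <= h):
            raise InvalidArgumentError("principal point must lie inside the image")

    @property
    def fx(self) -> float:
        return self.focal_length_px_x

    @property
    def fy(self) -> float:
        return self.focal_length_px_y

    @property
    def u0(self) -> float:
        return self.principal_point[0]

    @property
    def v0(self) -> float:
        return self.principal_point[1]


def _require_finite(*values: float) -> None:
    for value in values:
        if not math.isfinite(value):
            raise InvalidArgumentError(f"non-finite coordinate: {value!r}")


def pixel_to_plane(p: PixelPoint, cam: CameraModel) -> PlanePoint:
    """Map a pixel to normalized image-plane coordinates.

    ``(u0, v0)`` maps to the plane origin; one focal length of pixel offset
    maps to a unit plane coordinate.
    """
    u, v = p
    _require_finite(u, v)
    return PlanePoint((u - cam.u0) / cam.fx, (v - cam.v0) / cam.fy)


def plane_to_pixel(q: PlanePoint, cam: CameraModel) -> PixelPoint:
    """Exact inverse of :func:`pixel_to_plane`."""
    x, y = q
    _require_finite(x, y)
    return PixelPoint(x * cam.fx + cam.u0, y * cam.fy + cam.v0)


def depth_from_disparity(d: float, cam: CameraModel) -> float:
    """Depth ``Z = B * f / d`` from a stereo disparity in pixels.

    Uses the horizontal focal length, matching a horizontal baseline.
    """
    _require_finite(d)
    if d <= 0:
        raise InvalidArgumentError(f"disparity must be positive, got {d}")
    return cam.baseline_mm * cam.fx / d


def backproject(p: PixelPoint, Z: float, cam: CameraModel) -> Point3D:
    """Back-project a pixel at depth ``Z`` through an ideal pinhole (no water)."""
    _require_finite(Z)
    if Z <= 0:
        raise InvalidArgumentError(f"depth must be positive, got {Z}")
    x, y = pixel_to_plane(p, cam)
    return Point3D(x * Z, y * Z, Z)


def euclidean_length(E: Point3D, F: Point3D) -> float:
    """Euclidean distance between two 3D points in millimetres."""
    return math.dist(E, F)
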