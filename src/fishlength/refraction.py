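"""Flat air-water interface refraction model.

A camera looks straight down at water from height ``h`` above a flat surface.
A submerged point images at a larger radial offset than it would in air
(apparent magnification), and a naive stereo reading of its distance is
shallower than the true distance.  The model relates the unrefracted and
refracted image positions of a point through a radial scale factor

    K = h/Z + (1 - h/Z) * tan(beta) / tan(alpha),        0 < K <= 1,

where ``alpha`` is the air-side ray angle (from the image-plane radius),
``beta`` the water-side angle from Snell's law, and ``Z`` the stereo-measured
distance.  Because refraction inflates stereo disparity by the same factor,
the corrected distance is ``Z' = Z / K``, and the corrected 3D coordinates are
``(Kw * x * Z', Kw * y * Z', Z')``.

``K`` is applied isotropically to the radial image offset: both plane
coordinates are scaled equally, which is exact when the measured point and
the refraction plane share an azimuth and a good approximation otherwise.

Two self-consistent evaluation modes are provided (see
:func:`corrected_backproject`); both reduce bit-identically to the ideal
pinhole when ``n_water == n_air``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .camera import CameraModel, PixelPoint, PlanePoint, Point3D, pixel_to_plane
from .errors import InvalidArgumentError, RefractionNotApplicableError

__all__ = [
    "RefractionModel",
    "RefractionCorrection",
    "sin_alpha",
    "snell_sin_beta",
    "k_factor",
    "correct_depth",
    "corrected_backproject",
]

#: below this sine the on-axis analytic limit tan(b)/tan(a) -> n_air/n_water is used
_AXIS_EPS = 1e-9


@dataclass(frozen=True)
class RefractionModel:
    """Interface geometry and refractive indices.

    Parameters
    ----------
    camera_height_mm
        Distance ``h`` from the camera optical centre to the water surface.
    n_air, n_water
        Refractive indices (defaults 1.0 and 1.333).
    """

    camera_height_mm: float
    n_air: float = 1.0
    n_water: float = 1.333

    def __post_init__(self) -> None:
        if self.camera_height_mm <= 0:
            raise InvalidArgumentError("camera height must be positive")
        if not (self.n_water >= self.n_air >= 1.0):
            raise InvalidArgumentError("require n_water >= n_air >= 1")


@dataclass(frozen=True)
class RefractionCorrection:
    """Bookkeeping for one corrected point (diagnostic record)."""

    sin_alpha: float
    sin_beta: float
    K: float
    Z_measured_mm: float
    Z_corrected_mm: float
    Kw: float


def sin_alpha(q: PlanePoint) -> float:
    """Sine of the air-side ray angle for a normalized image-plane point.

    With the focal length equal to 1 in normalized units this is
    ``r / sqrt(r^2 + 1)`` for radius ``r = sqrt(x^2 + y^2)``; the result lies
    in ``[0, 1)`` and increases monotonically with ``r``.
    """
    x, y = q
    if not (math.isfinite(x) and math.isfinite(y)):
        raise InvalidArgumentError("non-finite plane point")
    r = math.hypot(x, y)
    return r / math.hypot(r, 1.0)


def snell_sin_beta(sin_a: float, rm: RefractionModel) -> float:
    """Water-side sine via Snell's law: ``sin(beta) = (n_air/n_water) sin(alpha)``."""
    if not (0.0 <= sin_a < 1.0):
        raise InvalidArgumentError(f"sin_alpha must be in [0, 1), got {sin_a}")
    return (rm.n_air / rm.n_water) * sin_a


def _tan_ratio(sin_a: float, rm: RefractionModel) -> float:
    """tan(beta)/tan(alpha) for the given air-side sine, with the on-axis limit."""
    if rm.n_water == rm.n_air:
        return 1.0
    if sin_a < _AXIS_EPS:
        return rm.n_air / rm.n_water
    sin_b = snell_sin_beta(sin_a, rm)
    tan_a = sin_a / math.sqrt(1.0 - sin_a * sin_a)
    tan_b = sin_b / math.sqrt(1.0 - sin_b * sin_b)
    return tan_b / tan_a


def k_factor(q: PlanePoint, Z_measured: float, rm: RefractionModel) -> float:
    """Radial scale factor ``K`` relating unrefracted to refracted image points.

    Requires the point to be under water (``Z_measured > h``); equals 1 when
    there is no interface (``n_water == n_air``) or the point sits exactly on
    the surface.
    """
    h = rm.camera_height_mm
    if Z_measured < h:
        raise RefractionNotApplicableError(
            f"measured depth {Z_measured} mm is above the water surface (h={h} mm)"
        )
    ratio = _tan_ratio(sin_alpha(q), rm)
    if ratio == 1.0:
        return 1.0
    hz = h / Z_measured
    return hz + (1.0 - hz) * ratio


def correct_depth(Z_measured: float, K: float) -> float:
    """Refraction-corrected distance ``Z' = Z / K`` (``Z' >= Z`` for ``K <= 1``).

    Refraction inflates the stereo disparity by the factor ``K`` (both image
    points scale radially), so the camera reads a distance smaller than the
    true one; dividing by ``K`` undoes this.
    """
    if K <= 0:
        raise InvalidArgumentError(f"K must be positive, got {K}")
    if Z_measured <= 0:
        raise InvalidArgumentError(f"measured depth must be positive, got {Z_measured}")
    return Z_measured / K


def corrected_backproject(
    p: PixelPoint,
    Z_measured: float,
    cam: CameraModel,
    rm: RefractionModel,
    *,
    kw_mode: str = "measured",
    iterate: bool = False,
    return_correction: bool = False,
) -> Point3D | tuple[Point3D, RefractionCorrection]:
    """Back-project a pixel with its measured depth through the refraction model.

    The corrected depth is ``Z' = Z / K``; the lateral coordinates are
    ``Kw * (u-u0)/fx * Z'`` and ``Kw * (v-v0)/fy * Z'``.

    Parameters
    ----------
    kw_mode
        Where ``Kw`` is evaluated: ``"measured"`` (default) uses the measured
        depth, which makes the lateral coordinates exactly self-consistent
        (``X = x * Z_measured`` after cancellation) in a single pass;
        ``"corrected"`` re-evaluates ``K`` at the corrected depth.
    iterate
        If true, solve the fixed point ``Z' = Z / K(Z')`` (tolerance 1e-6 mm,
        at most 20 iterations) instead of a single division.  The fixed point
        inverts the paraxial forward model exactly and pairs naturally with
        ``kw_mode="corrected"``.
    """
    if kw_mode not in ("measured", "corrected"):
        raise InvalidArgumentError(f"unknown kw_mode {kw_mode!r}")
    q = pixel_to_plane(p, cam)
    K = k_factor(q, Z_measured, rm)
    if iterate:
        Zc = Z_measured / K
        for _ in range(20):
            Zc_next = Z_measured / k_factor(q, Zc, rm)
            if abs(Zc_next - Zc) < 1e-6:
                Zc = Zc_next
                break
            Zc = Zc_next
    else:
        Zc = correct_depth(Z_measured, K)
    Kw = K if kw_mode == "measured" else k_factor(q, Zc, rm)
    point = Point3D(Kw * q.x * Zc, Kw * q.y * Zc, Zc)
    if not return_correction:
        return point
    sa = sin_alpha(q)
    corr = RefractionCorrection(
        sin_alpha=sa,
        sin_beta=snell_sin_beta(sa, rm),
        K=K,
        Z_measured_mm=Z_measured,
        Z_corrected_mm=Zc,
        Kw=Kw,
    )
    return point, corr
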