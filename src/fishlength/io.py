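"""Image I/O: 8-bit RGB and 16-bit millimetre depth PNGs.

Depth follows the RealSense convention: 16-bit grayscale PNG, integer
millimetres, with 0 marking an invalid reading.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError

__all__ = ["read_rgbd", "write_rgb", "write_depth", "write_mask"]


def read_rgbd(rgb_path: str | Path, depth_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load an aligned RGB / depth image pair.

    The RGB image must be 8-bit 3-channel (an alpha channel is dropped); the
    depth image must be 16-bit single-channel in millimetres; both must have
    identical dimensions.
    """
    try:
        rgb = iio.imread(rgb_path)
        depth = iio.imread(depth_path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image pair: {exc}") from exc
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[:, :, :3]
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise InputError(f"{rgb_path}: expected an 8-bit 3-channel RGB image")
    if depth.ndim != 2 or depth.dtype != np.uint16:
        raise InputError(f"{depth_path}: expected a 16-bit single-channel depth image")
    if rgb.shape[:2] != depth.shape:
        raise InputError(
            f"dimension mismatch: rgb {rgb.shape[:2]} vs depth {depth.shape}"
        )
    return rgb, depth


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


def write_depth(path: str | Path, depth_mm: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(depth_mm, dtype=np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask as an 8-bit 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
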