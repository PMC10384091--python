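"""Midline extraction: Zhang-Suen thinning plus corner removal and deburring.

The fish midline is obtained by thinning the binary body mask to a 1-pixel
skeleton and then cleaning it until it is a single open curve:

1. remove *corner points* (single-pixel protrusions in four directions, see
   :func:`is_corner`), which lowers the node count without breaking
   connectivity;
2. while more than two endpoints remain, treat the endpoint pair with the
   largest mutual distance as the main skeleton and erode every other branch
   (a *burr*) endpoint by endpoint;
3. if pruning ever disconnects the skeleton, reconnect the closest endpoints
   with a straight discrete line.

Neighbour indexing: ``P1..P8`` run clockwise from the top-left, so
``P1=NW, P2=N, P3=NE, P4=E, P5=SE, P6=S, P7=SW, P8=W``.  All corner
conditions are written against this one convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label

from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "Neighborhood8",
    "SkeletonImage",
    "classify_pixel",
    "zhang_suen_thin",
    "is_corner",
    "remove_corners",
    "prune_burrs",
    "connect_breaks",
    "extract_midline",
]

# (row, col) offsets for P1..P8, clockwise from NW.
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]

_KERNEL8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass(frozen=True)
class Neighborhood8:
    """The 8 binary neighbours of a pixel, P1=NW clockwise through P8=W."""

    P1: int
    P2: int
    P3: int
    P4: int
    P5: int
    P6: int
    P7: int
    P8: int

    @property
    def N(self) -> int:
        return self.P1 + self.P2 + self.P3 + self.P4 + self.P5 + self.P6 + self.P7 + self.P8

    @classmethod
    def at(cls, img: np.ndarray, r: int, c: int) -> "Neighborhood8":
        h, w = img.shape
        vals = []
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            vals.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
        return cls(*vals)


def classify_pixel(nb: Neighborhood8) -> Literal["isolated", "endpoint", "skeleton-point", "node"]:
    """Classify a skeleton pixel by its neighbour count N."""
    n = nb.N
    if n == 0:
        return "isolated"
    if n == 1:
        return "endpoint"
    if n == 2:
        return "skeleton-point"
    return "node"


def _neighbor_counts(img: np.ndarray) -> np.ndarray:
    return ndimage.convolve(img.astype(np.uint8), _KERNEL8, mode="constant")


@dataclass
class SkeletonImage:
    """A binary skeleton raster with endpoint/node bookkeeping."""

    image: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=bool)

    def _counts(self) -> np.ndarray:
        return _neighbor_counts(self.image)

    @property
    def endpoints(self) -> list[tuple[int, int]]:
        counts = self._counts()
        rr, cc = np.nonzero(self.image & (counts == 1))
        return list(zip(rr.tolist(), cc.tolist()))

    @property
    def nodes(self) -> list[tuple[int, int]]:
        counts = self._counts()
        rr, cc = np.nonzero(self.image & (counts >= 3))
        return list(zip(rr.tolist(), cc.tolist()))

    @property
    def n_components(self) -> int:
        if not self.image.any():
            return 0
        return int(cc_label(self.image, connectivity=2).max())

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def copy(self) -> "SkeletonImage":
        return SkeletonImage(self.image.copy())


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _zs_neighbors(img: np.ndarray) -> list[np.ndarray]:
    """P2..P9 in the classic Zhang-Suen order (N, NE, E, SE, S, SW, W, NW)."""
    order = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    padded = np.pad(img, 1)
    h, w = img.shape
    return [padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in order]


def zhang_suen_thin(mask: np.ndarray) -> SkeletonImage:
    """Two-subiteration Zhang-Suen thinning, run to a fixed point.

    The result is a 1-pixel-wide skeleton with the same number of connected
    components as the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        raise InvalidArgumentError("mask is empty")
    img = mask.astype(np.uint8)
    while True:
        changed = False
        for phase in (0, 1):
            P = _zs_neighbors(img)
            B = sum(P)
            seq = P + [P[0]]
            A = sum(((seq[i] == 0) & (seq[i + 1] == 1)) for i in range(8))
            cond = (img == 1) & (B >= 2) & (B <= 6) & (A == 1)
            if phase == 0:
                cond &= (P[0] * P[2] * P[4] == 0) & (P[2] * P[4] * P[6] == 0)
            else:
                cond &= (P[0] * P[2] * P[6] == 0) & (P[0] * P[4] * P[6] == 0)
            if cond.any():
                img[cond] = 0
                changed = True
        if not changed:
            break
    return SkeletonImage(img.astype(bool))


# ---------------------------------------------------------------------------
# Corner removal
# ---------------------------------------------------------------------------

def is_corner(nb: Neighborhood8) -> bool:
    """True if the neighbourhood matches one of the four protrusion patterns.

    A corner is a stair-step pixel whose two supporting neighbours are joined
    diagonally, so deleting it cannot disconnect the skeleton:

    * ``P2=P8=1`` and ``P4=P5=P6=0``  (supports N and W, open to the SE)
    * ``P2=P4=1`` and ``P6=P7=P8=0``
    * ``P4=P6=1`` and ``P1=P2=P8=0``
    * ``P6=P8=1`` and ``P2=P3=P4=0``
    """
    if nb.P2 and nb.P8 and not (nb.P4 or nb.P5 or nb.P6):
        return True
    if nb.P2 and nb.P4 and not (nb.P6 or nb.P7 or nb.P8):
        return True
    if nb.P4 and nb.P6 and not (nb.P1 or nb.P2 or nb.P8):
        return True
    if nb.P6 and nb.P8 and not (nb.P2 or nb.P3 or nb.P4):
        return True
    return False


def remove_corners(sk: SkeletonImage) -> SkeletonImage:
    """Delete corner pixels in sequential row-major sweeps until stable.

    Deletion takes immediate effect, so each pixel is judged against the
    current raster; simultaneous removal could disconnect staircases.
    """
    img = sk.image.copy()
    while True:
        deleted = False
        rr, cc = np.nonzero(img)
        for r, c in zip(rr.tolist(), cc.tolist()):
            if img[r, c] and is_corner(Neighborhood8.at(img, r, c)):
                img[r, c] = False
                deleted = True
        if not deleted:
            break
    return SkeletonImage(img)


# ---------------------------------------------------------------------------
# Burr pruning and break repair
# ---------------------------------------------------------------------------

def _fg_neighbors(img: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    h, w = img.shape
    out = []
    for dr, dc in _OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and img[rr, cc]:
            out.append((rr, cc))
    return out


def default_max_deletions(sk: SkeletonImage) -> int:
    """Default burr-length threshold: 15% of the skeleton pixel count."""
    return max(1, int(0.15 * int(sk.image.sum())))


def prune_burrs(sk: SkeletonImage, max_deletions: int | None = None) -> SkeletonImage:
    """Erode every branch that does not end at the two farthest endpoints.

    The endpoint pair with the maximum mutual Euclidean distance defines the
    main skeleton; each remaining endpoint is deleted and its unique
    neighbour promoted, repeatedly, until a node is reached or
    ``max_deletions`` steps have been taken on that branch.  If a deleted
    endpoint exposes more than one neighbour the walk stops (conservative).
    """
    if not sk.is_connected:
        raise InvalidStateError("prune_burrs requires a single-component skeleton")
    if max_deletions is None:
        max_deletions = default_max_deletions(sk)
    endpoints = sk.endpoints
    if len(endpoints) <= 2:
        return sk.copy()
    pts = np.asarray(endpoints, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    keep = {endpoints[i], endpoints[j]}
    img = sk.image.copy()
    for ep in endpoints:
        if ep in keep:
            continue
        cur = ep
        for _ in range(max_deletions):
            nbrs = _fg_neighbors(img, *cur)
            if len(nbrs) != 1:
                break  # isolated pixel or diagonal ambiguity: stop conservatively
            nxt = nbrs[0]
            img[cur] = False
            if len(_fg_neighbors(img, *nxt)) >= 2:
                break  # reached the main line / a node
            cur = nxt
    return SkeletonImage(img)


def connect_breaks(sk: SkeletonImage) -> SkeletonImage:
    """Join split components with straight discrete lines between the closest pixels."""
    img = sk.image.copy()
    while True:
        labels = cc_label(img, connectivity=2)
        n = int(labels.max())
        if n <= 1:
            return SkeletonImage(img)
        counts = _neighbor_counts(img)
        best = None
        # prefer endpoints as attachment sites; fall back to all pixels
        comp_pts = []
        for k in range(1, n + 1):
            sel = (labels == k) & img
            ep = sel & (counts == 1)
            pts = np.argwhere(ep if ep.any() else sel)
            comp_pts.append(pts)
        for a in range(n):
            for b in range(a + 1, n):
                pa, pb = comp_pts[a], comp_pts[b]
                d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
                ia, ib = np.unravel_index(int(np.argmin(d2)), d2.shape)
                cand = (float(d2[ia, ib]), tuple(pa[ia]), tuple(pb[ib]))
                if best is None or cand[0] < best[0]:
                    best = cand
        _, p, q = best
        rr, cc = draw_line(int(p[0]), int(p[1]), int(q[0]), int(q[1]))
        img[rr, cc] = True


def extract_midline(mask: np.ndarray, max_deletions: int | None = None) -> SkeletonImage:
    """Thin a body mask to a single open curve with exactly two endpoints.

    Composition: Zhang-Suen thinning, corner removal, then alternating burr
    pruning and break repair until the contract (one component, two
    endpoints, no nodes) holds.
    """
    sk = remove_corners(zhang_suen_thin(mask))
    if int(sk.image.sum()) == 1:
        raise InvalidArgumentError("mask thinned to a single pixel; no midline")
    for _ in range(12):
        sk = connect_breaks(sk)
        sk = prune_burrs(sk, max_deletions)
        sk = connect_breaks(sk)
        # re-thin and de-corner: pruning can expose residual thick spots
        # (pixels with three path neighbours) that are not true branches
        sk = remove_corners(zhang_suen_thin(sk.image))
        if len(sk.endpoints) == 2 and not sk.nodes and sk.is_connected:
            return sk
    raise InvalidStateError(
        f"midline contract not reached: {len(sk.endpoints)} endpoints, "
        f"{len(sk.nodes)} nodes, {sk.n_components} components"
    )
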