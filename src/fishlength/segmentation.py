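"""Contrast-adaptive GrabCut segmentation.

The fish is cut out of the RGB frame by minimizing the Gibbs energy

    E(alpha, k, theta, z) = U + V

where ``U`` sums per-pixel Gaussian-mixture penalties
``D = -log P(z | alpha, k, theta) - log pi(alpha, k)`` under separate
foreground and background GMMs, and ``V`` is the contrast-weighted boundary
term ``gamma * sum_{(m,n) in C, labels differ} exp(-beta ||zm - zn||^2)``
over 8-connected neighbour pairs, with ``beta = 1 / (2 <||zm - zn||^2>)``.

Minimization alternates (a) assigning each pixel to its best mixture
component, (b) refitting the two GMMs, and (c) an exact min-cut on the pixel
graph, seeded from a user rectangle: pixels outside the rectangle are fixed
background, pixels inside start as probable foreground.

Low-contrast underwater frames are first normalized by a grayscale linear
percentile stretch (replicated into all three channels) so the fish/background
mixtures separate; see :func:`contrast_adapt`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.cluster import KMeans

from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "SegConfig",
    "Trimap",
    "GmmModel",
    "EnergyReport",
    "contrast_adapt",
    "compute_beta",
    "boundary_term",
    "data_term",
    "grabcut",
    "segment_fish",
]

# trimap labels
SURE_BG, PROB_BG, PROB_FG, SURE_FG = 0, 1, 2, 3

# pair offsets for 8-connectivity, each unordered pair counted once:
# east, south-west, south, south-east neighbours of every pixel
_PAIR_OFFSETS = [(0, 1), (1, -1), (1, 0), (1, 1)]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SegConfig:
    """GrabCut and preprocessing parameters.

    ``gmm_components`` and ``gamma`` default to the standard GrabCut settings
    (5 components per class, boundary weight 50).  The stretch percentiles
    and brightness offset drive :func:`contrast_adapt`.
    """

    gmm_components: int = 5
    gamma: float = 50.0
    n_iterations: int = 5
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    brightness_offset: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gmm_components < 1:
            raise InvalidArgumentError("gmm_components must be >= 1")
        if self.gamma <= 0:
            raise InvalidArgumentError("gamma must be positive")
        if self.n_iterations < 1:
            raise InvalidArgumentError("n_iterations must be >= 1")
        if not (0 <= self.stretch_low_pct < self.stretch_high_pct <= 100):
            raise InvalidArgumentError("stretch percentiles must satisfy 0 <= low < high <= 100")


@dataclass
class Trimap:
    """Per-pixel 4-way label raster seeded from a rectangle."""

    labels: np.ndarray  # uint8 in {SURE_BG, PROB_BG, PROB_FG, SURE_FG}

    @classmethod
    def from_roi(cls, shape: tuple[int, int], roi: tuple[int, int, int, int]) -> "Trimap":
        """Initialize from a half-open rectangle ``(x, y, w, h)`` (0-based)."""
        x, y, w, h = roi
        H, W = shape
        if w <= 0 or h <= 0:
            raise InvalidArgumentError("ROI must have positive area")
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise InvalidArgumentError("ROI must lie inside the image")
        labels = np.full(shape, SURE_BG, dtype=np.uint8)
        labels[y : y + h, x : x + w] = PROB_FG
        return cls(labels)

    @property
    def fg_mask(self) -> np.ndarray:
        return (self.labels == PROB_FG) | (self.labels == SURE_FG)


@dataclass
class EnergyReport:
    """Region term U, boundary term V and total Gibbs energy per iteration."""

    U: float
    V: float
    beta_smooth: float

    @property
    def E(self) -> float:
        return self.U + self.V


def contrast_adapt(rgb: np.ndarray, cfg: SegConfig = SegConfig()) -> np.ndarray:
    """Grayscale percentile stretch replicated into three channels.

    The RGB frame is converted to a single luminance channel, intensities
    between the configured percentiles are stretched linearly to the full
    8-bit range, a brightness offset is added with saturation, and the result
    is copied into all three output channels (the GrabCut input stays
    3-channel).  A constant image passes through unchanged.
    """
    rgb = np.asarray(rgb)
    if rgb.size == 0:
        raise InvalidArgumentError("empty image")
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise InvalidArgumentError("expected an 8-bit 3-channel image")
    gray = rgb.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    lo, hi = np.percentile(gray, [cfg.stretch_low_pct, cfg.stretch_high_pct])
    if hi > lo:
        gray = (gray - lo) * (255.0 / (hi - lo))
    gray = np.clip(gray + cfg.brightness_offset, 0.0, 255.0)
    out = np.rint(gray).astype(np.uint8)
    return np.repeat(out[:, :, None], 3, axis=2)


def _pair_diffs(img: np.ndarray):
    """Squared colour differences for each 8-neighbour pair (counted once)."""
    z = np.asarray(img, dtype=np.float64)
    for dr, dc in _PAIR_OFFSETS:
        h, w = z.shape[:2]
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        a = z[r0:r1, c0:c1]
        b = z[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        yield (dr, dc), ((a - b) ** 2).sum(axis=-1)


def compute_beta(img: np.ndarray) -> float:
    """Contrast scale ``beta = 1 / (2 <||zm - zn||^2>)`` over 8-neighbour pairs.

    A constant image has zero mean squared difference; a guarded large finite
    value is returned so that any label boundary is maximally penalized.
    """
    img = np.asarray(img)
    if img.size < 2:
        raise InvalidArgumentError("image must have at least 2 pixels")
    total = 0.0
    count = 0
    for _, d2 in _pair_diffs(img):
        total += float(d2.sum())
        count += d2.size
    mean = total / count
    if mean <= 0:
        return 1e8
    return 1.0 / (2.0 * mean)


def boundary_term(labels: np.ndarray, img: np.ndarray, beta: float, gamma: float) -> float:
    """Boundary energy V over 8-neighbour pairs with unequal binary labels."""
    labels = np.asarray(labels).astype(bool)
    img = np.asarray(img)
    if labels.shape != img.shape[:2]:
        raise InvalidArgumentError("labels / image shape mismatch")
    V = 0.0
    for (dr, dc), d2 in _pair_diffs(img):
        h, w = labels.shape
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        differ = labels[r0:r1, c0:c1] != labels[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        V += float(np.exp(-beta * d2[differ]).sum())
    return gamma * V


class GmmModel:
    """Full-covariance Gaussian mixture over 3-channel pixel values.

    Fitted by hard assignment: each pixel belongs to one component ``k_n``
    and the penalty of a pixel is ``-log pi_k - log N(z; mu_k, Sigma_k)``.
    Near-singular covariances are regularized by adding ``0.01 I``.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components
        self.weights = np.full(n_components, 1.0 / n_components)
        self.means = np.zeros((n_components, 3))
        self.covs = np.stack([np.eye(3)] * n_components)
        self.fitted = False
        self._update_cached()

    def _update_cached(self) -> None:
        self._prec = np.zeros_like(self.covs)
        self._logdet = np.zeros(self.n_components)
        for k in range(self.n_components):
            cov = self.covs[k]
            if np.linalg.eigvalsh(cov).min() < 1e-4:
                cov = cov + 0.01 * np.eye(3)
                self.covs[k] = cov
            self._prec[k] = np.linalg.inv(cov)
            sign, logdet = np.linalg.slogdet(cov)
            self._logdet[k] = logdet

    def init_kmeans(self, pixels: np.ndarray, seed: int) -> np.ndarray:
        """K-means initialization; returns the component assignment."""
        pixels = np.asarray(pixels, dtype=np.float64)
        n_comp = min(self.n_components, len(np.unique(pixels, axis=0)))
        n_comp = max(1, n_comp)
        km = KMeans(n_clusters=n_comp, n_init=1, random_state=seed)
        assign = km.fit_predict(pixels)
        self.fit(pixels, assign)
        return assign

    def fit(self, pixels: np.ndarray, assignments: np.ndarray) -> None:
        """Refit weights / means / covariances from a hard assignment."""
        pixels = np.asarray(pixels, dtype=np.float64)
        n = len(pixels)
        for k in range(self.n_components):
            sel = assignments == k
            cnt = int(sel.sum())
            if cnt == 0:
                self.weights[k] = 0.0
                continue
            self.weights[k] = cnt / n
            self.means[k] = pixels[sel].mean(axis=0)
            if cnt >= 2:
                self.covs[k] = np.cov(pixels[sel].T, bias=False)
            else:
                self.covs[k] = np.eye(3)
        total = self.weights.sum()
        if total <= 0:
            raise InvalidStateError("all mixture components are empty")
        self.weights /= total
        self._update_cached()
        self.fitted = True

    def component_penalties(self, pixels: np.ndarray) -> np.ndarray:
        """(n, K) matrix of D values, one per pixel and component."""
        if not self.fitted:
            raise InvalidStateError("GMM is not fitted")
        pixels = np.asarray(pixels, dtype=np.float64)
        out = np.full((len(pixels), self.n_components), np.inf)
        for k in range(self.n_components):
            if self.weights[k] <= 0:
                continue
            d = pixels - self.means[k]
            maha = np.einsum("ni,ij,nj->n", d, self._prec[k], d)
            out[:, k] = (
                -np.log(self.weights[k])
                + 0.5 * (3 * _LOG_2PI + self._logdet[k])
                + 0.5 * maha
            )
        return out

    def assign(self, pixels: np.ndarray) -> np.ndarray:
        return np.argmin(self.component_penalties(pixels), axis=1)

    def penalty(self, pixels: np.ndarray, assignments: np.ndarray | None = None) -> np.ndarray:
        """Per-pixel D; best component if no assignment is given."""
        pen = self.component_penalties(pixels)
        if assignments is None:
            return pen.min(axis=1)
        return pen[np.arange(len(pen)), assignments]


def data_term(
    labels: np.ndarray,
    gmm_fg: GmmModel,
    gmm_bg: GmmModel,
    img: np.ndarray,
    assignments_fg: np.ndarray | None = None,
    assignments_bg: np.ndarray | None = None,
) -> float:
    """Region energy U: the sum of GMM penalties under the given labelling.

    ``labels`` is the binary foreground mask.  If component assignments are
    omitted each pixel uses its best component, which is the assignment the
    alternating minimization would choose anyway.
    """
    labels = np.asarray(labels).astype(bool).ravel()
    pixels = np.asarray(img, dtype=np.float64).reshape(-1, 3)
    U = 0.0
    if labels.any():
        U += float(gmm_fg.penalty(pixels[labels], assignments_fg).sum())
    if (~labels).any():
        U += float(gmm_bg.penalty(pixels[~labels], assignments_bg).sum())
    return U


def _pair_weights(img: np.ndarray, beta: float, gamma: float):
    """Edge weights gamma*exp(-beta*||dz||^2) for each pair offset."""
    for off, d2 in _pair_diffs(img):
        yield off, gamma * np.exp(-beta * d2)


def _min_cut(
    n_nodes: int,
    t_source: np.ndarray,
    t_sink: np.ndarray,
    edges: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Exact s-t min cut; returns True for nodes on the source (foreground) side.

    Capacities are scaled to integers for scipy's max-flow solver; the
    partition is read from residual-graph reachability.
    """
    scale = 1000.0
    cap_max = 2_000_000_000
    s, t = n_nodes, n_nodes + 1
    rows = [np.full(n_nodes, s), np.arange(n_nodes)]
    cols = [np.arange(n_nodes), np.full(n_nodes, t)]
    caps = [t_source, t_sink]
    if len(edges):
        rows += [edges[:, 0], edges[:, 1]]
        cols += [edges[:, 1], edges[:, 0]]
        caps += [weights, weights]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps)
    caps = np.minimum(np.rint(caps * scale), cap_max).astype(np.int32)
    graph = csr_matrix((caps, (rows, cols)), shape=(n_nodes + 2, n_nodes + 2))
    result = maximum_flow(graph, s, t)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    side = np.zeros(n_nodes + 2, dtype=bool)
    side[reach] = True
    return side[:n_nodes]


def grabcut(
    img: np.ndarray,
    roi: tuple[int, int, int, int],
    cfg: SegConfig = SegConfig(),
) -> tuple[np.ndarray, list[EnergyReport]]:
    """Iterative GrabCut driven by a rectangle.

    Returns the binary foreground mask (fish = True) and the per-iteration
    energy history.  Energy is evaluated over the whole frame after each
    outer iteration and is non-increasing up to capacity quantization.
    A collapse to an all-background ROI is flagged by an empty mask rather
    than an error.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidArgumentError("expected a 3-channel image")
    H, W = img.shape[:2]
    trimap = Trimap.from_roi((H, W), roi)
    labels = trimap.labels
    pixels = img.reshape(-1, 3).astype(np.float64)
    beta = compute_beta(img)

    rng = np.random.default_rng(cfg.rng_seed)
    fg_idx0 = np.flatnonzero(labels.ravel() >= PROB_FG)
    bg_idx0 = np.flatnonzero(labels.ravel() <= PROB_BG)
    # k-means init; background sampled for speed on large frames
    bg_sample = bg_idx0
    if len(bg_sample) > 20000:
        bg_sample = rng.choice(bg_sample, 20000, replace=False)
    gmm_fg = GmmModel(cfg.gmm_components)
    gmm_bg = GmmModel(cfg.gmm_components)
    gmm_fg.init_kmeans(pixels[fg_idx0], cfg.rng_seed)
    gmm_bg.init_kmeans(pixels[bg_sample], cfg.rng_seed + 1)

    # the cut only runs over the free (probable) pixels: everything outside
    # the rectangle is clamped to background
    free = np.flatnonzero((labels.ravel() == PROB_FG) | (labels.ravel() == PROB_BG))
    free_pos = np.full(H * W, -1, dtype=np.int64)
    free_pos[free] = np.arange(len(free))
    free_pix = pixels[free]

    # neighbour structure restricted to the free set, plus boundary leakage
    # to the clamped background (adds to the sink t-link)
    inner_edges = []
    inner_w = []
    sink_extra = np.zeros(len(free))
    for (dr, dc), wmat in _pair_weights(img, beta, cfg.gamma):
        hgt, wid = wmat.shape
        r0, r1 = max(dr, 0), H + min(dr, 0)
        c0, c1 = max(dc, 0), W + min(dc, 0)
        a_lin = (np.arange(r0, r1)[:, None] * W + np.arange(c0, c1)[None, :]).ravel()
        b_lin = a_lin - dr * W - dc
        wflat = wmat.ravel()
        pa, pb = free_pos[a_lin], free_pos[b_lin]
        both = (pa >= 0) & (pb >= 0)
        inner_edges.append(np.stack([pa[both], pb[both]], axis=1))
        inner_w.append(wflat[both])
        a_only = (pa >= 0) & (pb < 0)
        np.add.at(sink_extra, pa[a_only], wflat[a_only])
        b_only = (pb >= 0) & (pa < 0)
        np.add.at(sink_extra, pb[b_only], wflat[b_only])
    inner_edges = np.concatenate(inner_edges) if inner_edges else np.empty((0, 2), int)
    inner_w = np.concatenate(inner_w) if inner_w else np.empty(0)

    history: list[EnergyReport] = []
    for _ in range(cfg.n_iterations):
        # (a) component assignment + (b) GMM refit on current labels
        fg_idx = np.flatnonzero((labels.ravel() == PROB_FG) | (labels.ravel() == SURE_FG))
        bg_idx = np.flatnonzero((labels.ravel() == PROB_BG) | (labels.ravel() == SURE_BG))
        if len(fg_idx) == 0 or len(bg_idx) == 0:
            break  # collapsed; flagged by the mask itself
        bg_fit = bg_idx
        if len(bg_fit) > 20000:
            bg_fit = rng.choice(bg_fit, 20000, replace=False)
        gmm_fg.fit(pixels[fg_idx], gmm_fg.assign(pixels[fg_idx]))
        gmm_bg.fit(pixels[bg_fit], gmm_bg.assign(pixels[bg_fit]))

        # (c) exact min-cut over the free pixels
        d_fg = gmm_fg.penalty(free_pix)
        d_bg = gmm_bg.penalty(free_pix)
        d_fg = np.minimum(d_fg, 1e5)
        d_bg = np.minimum(d_bg, 1e5)
        fg_side = _min_cut(len(free), d_bg, d_fg + sink_extra, inner_edges, inner_w)
        new_free = np.where(fg_side, PROB_FG, PROB_BG).astype(np.uint8)
        flat = labels.ravel()
        flat[free] = new_free
        labels = flat.reshape(H, W)

        fg_mask = (labels == PROB_FG) | (labels == SURE_FG)
        U = data_term(fg_mask, gmm_fg, gmm_bg, img)
        V = boundary_term(fg_mask, img, beta, cfg.gamma)
        history.append(EnergyReport(U=U, V=V, beta_smooth=beta))

    mask = (labels == PROB_FG) | (labels == SURE_FG)
    return mask, history


def segment_fish(
    rgb: np.ndarray,
    roi: tuple[int, int, int, int],
    cfg: SegConfig = SegConfig(),
) -> np.ndarray:
    """Pipeline entry point: contrast adaptation followed by GrabCut.

    Re-runnable with a new rectangle if the first segmentation is
    unsatisfactory.
    """
    adapted = contrast_adapt(rgb, cfg)
    mask, _ = grabcut(adapted, roi, cfg)
    return mask
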