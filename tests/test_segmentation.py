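import numpy as np
import pytest

from fishlength.errors import InvalidArgumentError
from fishlength.segmentation import (
    GmmModel,
    SegConfig,
    boundary_term,
    compute_beta,
    contrast_adapt,
    data_term,
    grabcut,
    segment_fish,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


def _ellipse(H=120, W=160, c=(80, 60), ax=(45, 18)):
    yy, xx = np.ogrid[:H, :W]
    return ((xx - c[0]) / ax[0]) ** 2 + ((yy - c[1]) / ax[1]) ** 2 <= 1


def _fish_image(seed=3, fg=65, bg=175, noise=5):
    rng = np.random.default_rng(seed)
    ell = _ellipse()
    img = np.full(ell.shape + (3,), float(bg))
    img[ell] = fg
    img += rng.normal(0, noise, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), ell


ROI = (25, 30, 110, 60)


# ---------------------------------------------------------------------------
# contrast adaptation
# ---------------------------------------------------------------------------

def test_contrast_adapt_constant_image_unchanged():
    img = np.full((10, 10, 3), 77, dtype=np.uint8)
    out = contrast_adapt(img)
    assert (out == 77).all()


def test_contrast_adapt_two_level_stretch():
    cfg = SegConfig(stretch_low_pct=0.0, stretch_high_pct=100.0)
    img = np.full((10, 10, 3), 50, dtype=np.uint8)
    img[5:] = 200
    out = contrast_adapt(img, cfg)
    assert set(np.unique(out)) == {0, 255}


def test_contrast_adapt_output_channels_equal():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (20, 30, 3), dtype=np.uint8)
    out = contrast_adapt(img)
    assert out.dtype == np.uint8
    assert (out[:, :, 0] == out[:, :, 1]).all() and (out[:, :, 1] == out[:, :, 2]).all()


def test_contrast_adapt_rejects_empty_and_gray():
    with pytest.raises(InvalidArgumentError):
        contrast_adapt(np.zeros((0, 0, 3), dtype=np.uint8))
    with pytest.raises(InvalidArgumentError):
        contrast_adapt(np.zeros((5, 5), dtype=np.uint8))


# ---------------------------------------------------------------------------
# beta / boundary / data terms, against brute-force pair enumeration
# ---------------------------------------------------------------------------

def _pairs(H, W):
    for r in range(H):
        for c in range(W):
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    yield (r, c), (rr, cc)


def brute_beta(img):
    img = img.astype(float)
    d2 = [((img[a] - img[b]) ** 2).sum() for a, b in _pairs(*img.shape[:2])]
    mean = np.mean(d2)
    return 1e8 if mean == 0 else 1.0 / (2.0 * mean)


def brute_boundary(labels, img, beta, gamma):
    img = img.astype(float)
    V = 0.0
    for a, b in _pairs(*img.shape[:2]):
        if labels[a] != labels[b]:
            V += np.exp(-beta * ((img[a] - img[b]) ** 2).sum())
    return gamma * V


def test_compute_beta_constant_image_guard():
    img = np.full((6, 6, 3), 100, dtype=np.uint8)
    assert compute_beta(img) == 1e8


def test_compute_beta_checkerboard_matches_enumeration():
    yy, xx = np.ogrid[:6, :6]
    img = (((yy + xx) % 2) * 255).astype(np.uint8)[:, :, None].repeat(3, axis=2)
    assert compute_beta(img) == pytest.approx(brute_beta(img), rel=1e-12)


def test_compute_beta_quarters_under_contrast_doubling():
    rng = np.random.default_rng(1)
    img = rng.integers(20, 80, (8, 8, 3)).astype(np.uint8)
    beta1 = compute_beta(img)
    beta2 = compute_beta((img.astype(int) * 2).astype(np.uint8))
    assert beta2 == pytest.approx(beta1 / 4.0, rel=1e-9)


def test_boundary_term_against_enumeration():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 255, (7, 9, 3)).astype(np.uint8)
    labels = rng.random((7, 9)) > 0.5
    beta = compute_beta(img)
    assert boundary_term(labels, img, beta, 50.0) == pytest.approx(
        brute_boundary(labels, img, beta, 50.0), rel=1e-9
    )


def test_boundary_term_uniform_labels_zero():
    img = np.zeros((5, 5, 3), dtype=np.uint8)
    assert boundary_term(np.ones((5, 5), bool), img, 1.0, 50.0) == 0.0


def test_boundary_term_single_fg_pixel_constant_image():
    img = np.full((5, 5, 3), 10, dtype=np.uint8)
    labels = np.zeros((5, 5), bool)
    labels[2, 2] = True
    # 8 cut pairs, zero colour difference -> V = gamma * 8
    assert boundary_term(labels, img, compute_beta(img), 50.0) == pytest.approx(400.0)


def test_gmm_penalty_closed_form_at_mean():
    gmm = GmmModel(2)
    pixels = np.vstack([np.full((40, 3), 10.0), np.full((40, 3), 200.0)])
    pixels += np.random.default_rng(3).normal(0, 1, pixels.shape)
    gmm.fit(pixels, (np.arange(80) >= 40).astype(int))
    gmm.means[0] = 10.0
    gmm.covs[0] = np.eye(3)
    gmm._update_cached()
    pen = gmm.penalty(np.array([[10.0, 10.0, 10.0]]), np.array([0]))[0]
    assert pen == pytest.approx(-np.log(gmm.weights[0]) + 1.5 * _LOG_2PI, abs=1e-9)


def test_gmm_penalty_monotone_in_mahalanobis():
    gmm = GmmModel(1)
    rng = np.random.default_rng(4)
    gmm.fit(rng.normal(50, 5, (200, 3)), np.zeros(200, int))
    base = gmm.means[0].copy()
    pens = [gmm.penalty(np.array([base + d]))[0] for d in (0.0, 2.0, 5.0, 11.0)]
    assert all(b > a for a, b in zip(pens, pens[1:]))


def test_data_term_matches_naive_double_loop():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 255, (5, 5, 3)).astype(np.uint8)
    labels = rng.random((5, 5)) > 0.5
    fg = GmmModel(2)
    bg = GmmModel(2)
    fg.fit(rng.normal(80, 10, (60, 3)), rng.integers(0, 2, 60))
    bg.fit(rng.normal(180, 12, (60, 3)), rng.integers(0, 2, 60))
    U = data_term(labels, fg, bg, img)
    brute = 0.0
    for r in range(5):
        for c in range(5):
            model = fg if labels[r, c] else bg
            brute += model.penalty(img[r, c][None].astype(float)).item()
    assert U == pytest.approx(brute, rel=1e-9)


# ---------------------------------------------------------------------------
# grabcut
# ---------------------------------------------------------------------------

def test_grabcut_high_contrast_fish_iou(cam=None):
    img, truth = _fish_image()
    mask, history = grabcut(img, ROI)
    iou = (mask & truth).sum() / (mask | truth).sum()
    assert iou >= 0.95
    assert history, "expected at least one energy evaluation"


def test_grabcut_energy_non_increasing():
    img, _ = _fish_image(seed=9)
    _, history = grabcut(img, ROI)
    energies = [h.E for h in history]
    for a, b in zip(energies, energies[1:]):
        assert b <= a + 1e-6 * max(1.0, abs(a))
    for h in history:
        assert h.E == h.U + h.V and h.V >= 0


def test_grabcut_mask_confined_to_roi():
    img, _ = _fish_image(seed=10)
    mask, _ = grabcut(img, ROI)
    outside = np.ones(mask.shape, bool)
    x, y, w, h = ROI
    outside[y : y + h, x : x + w] = False
    assert not mask[outside].any()


def test_grabcut_background_roi_yields_empty_mask():
    rng = np.random.default_rng(6)
    img = np.full((120, 160, 3), 170.0)
    img[:, :40] = 60.0
    img += rng.normal(0, 4, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    mask, _ = grabcut(img, (70, 30, 60, 60))
    assert mask.sum() <= 10


def test_grabcut_deterministic_under_seed():
    img, _ = _fish_image(seed=11)
    m1, _ = grabcut(img, ROI, SegConfig(rng_seed=7))
    m2, _ = grabcut(img, ROI, SegConfig(rng_seed=7))
    assert (m1 == m2).all()


def test_grabcut_rejects_bad_roi():
    img, _ = _fish_image()
    with pytest.raises(InvalidArgumentError):
        grabcut(img, (0, 0, 0, 10))
    with pytest.raises(InvalidArgumentError):
        grabcut(img, (150, 0, 40, 40))


def test_segment_fish_does_not_hurt_high_contrast():
    img, truth = _fish_image(seed=12)
    raw, _ = grabcut(img, ROI)
    adapted = segment_fish(img, ROI)
    iou_raw = (raw & truth).sum() / (raw | truth).sum()
    iou_ad = (adapted & truth).sum() / (adapted | truth).sum()
    assert iou_ad >= 0.95
    assert iou_ad >= iou_raw - 0.01


def test_segment_fish_rescues_chromatic_clutter():
    """Grayscale adaptation collapses chromatic background clutter that the
    raw colour GMMs must otherwise model, improving the cut."""
    rng = np.random.default_rng(5)
    ell = _ellipse()
    img = 170.0 + rng.normal(0, 25, ell.shape + (3,))
    img[ell] = 130.0 + rng.normal(0, 4, (int(ell.sum()), 3))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    raw, _ = grabcut(img, ROI)
    adapted = segment_fish(img, ROI)
    iou_raw = (raw & ell).sum() / max((raw | ell).sum(), 1)
    iou_ad = (adapted & ell).sum() / max((adapted | ell).sum(), 1)
    assert iou_ad > iou_raw


def test_segment_fish_selects_only_roi_fish():
    rng = np.random.default_rng(7)
    H, W = 120, 160
    yy, xx = np.ogrid[:H, :W]
    f1 = ((xx - 45) / 25.0) ** 2 + ((yy - 40) / 10.0) ** 2 <= 1
    f2 = ((xx - 115) / 25.0) ** 2 + ((yy - 85) / 10.0) ** 2 <= 1
    img = np.full((H, W, 3), 175.0)
    img[f1] = 70.0
    img[f2] = 80.0
    img += rng.normal(0, 4, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    mask = segment_fish(img, (15, 25, 62, 32))
    assert (mask & f1).sum() / f1.sum() > 0.9
    assert (mask & f2).sum() == 0


def test_gmm_weights_normalized_and_covs_spd():
    rng = np.random.default_rng(8)
    gmm = GmmModel(5)
    pixels = rng.normal(100, 30, (500, 3))
    assign = gmm.init_kmeans(pixels, seed=0)
    gmm.fit(pixels, assign)
    assert gmm.weights.sum() == pytest.approx(1.0)
    for k in range(5):
        if gmm.weights[k] > 0:
            assert np.linalg.eigvalsh(gmm.covs[k]).min() > 0
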