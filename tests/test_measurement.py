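import math

import numpy as np
import pytest
from skimage.draw import line as draw_line

from fishlength.camera import PixelPoint
from fishlength.errors import InvalidArgumentError, MissingDepthError, NoFishError
from fishlength.measurement import (
    MeasurementPoints,
    arc_length,
    classify_pose,
    clean_mask,
    evaluate,
    fill_holes,
    fish_geometry,
    measure_length,
    sample_depth,
    straight_points,
    straighten,
)
from fishlength.refraction import RefractionModel
from fishlength.skeleton import SkeletonImage
from fishlength.synthetic import default_camera


# ---------------------------------------------------------------------------
# mask cleanup
# ---------------------------------------------------------------------------

def test_clean_mask_removes_specks_keeps_blobs():
    mask = np.zeros((40, 40), bool)
    mask[20, 5] = True                       # isolated speck
    mask[10:30, 15:35] = True                # solid blob
    out = clean_mask(mask)
    assert not out[20, 5]
    area_before = 20 * 20
    assert abs(int(out[10:30, 15:35].sum()) - area_before) / area_before < 0.02


def test_clean_mask_idempotent():
    rng = np.random.default_rng(0)
    mask = rng.random((50, 50)) > 0.4
    once = clean_mask(mask)
    assert (clean_mask(once) == once).all()


def test_fill_holes():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    mask[9:11, 9:11] = False
    assert fill_holes(mask)[9:11, 9:11].all()


# ---------------------------------------------------------------------------
# geometry and pose
# ---------------------------------------------------------------------------

def test_fish_geometry_axis_aligned_rectangle():
    mask = np.zeros((100, 260), bool)
    mask[30:70, 30:230] = True
    geom = fish_geometry(mask)
    # e, f sit at the midpoints of the short sides; theta is (numerically) 0
    pts = sorted([geom.e, geom.f], key=lambda p: p.u)
    assert pts[0].u == pytest.approx(29.5, abs=1.0)
    assert pts[1].u == pytest.approx(229.5, abs=1.0)
    assert pts[0].v == pytest.approx(49.5, abs=1.5)
    assert geom.theta_bend == pytest.approx(0.0, abs=0.5)


def test_fish_geometry_requires_fish():
    with pytest.raises(NoFishError):
        fish_geometry(np.zeros((10, 10), bool))
    tiny = np.zeros((10, 10), bool)
    tiny[4, 4] = True
    with pytest.raises(NoFishError):
        fish_geometry(tiny)


def test_fish_geometry_picks_largest_component():
    mask = np.zeros((60, 200), bool)
    mask[10:20, 5:25] = True        # small fragment
    mask[30:50, 40:190] = True      # the fish
    geom = fish_geometry(mask)
    assert geom.e.u > 30 and geom.f.u > 30


def test_bend_angle_supplement_examples():
    from fishlength.measurement import _angle_at

    # collinear e-o-f: angle 180, supplement 0
    assert 180.0 - _angle_at(PixelPoint(100, 0), PixelPoint(0, 0), PixelPoint(200, 0)) == 0.0
    # law-of-cosines example: vectors (-1,0) and (1,1) subtend 135 degrees
    theta = 180.0 - _angle_at(PixelPoint(1, 0), PixelPoint(0, 0), PixelPoint(2, 1))
    assert theta == pytest.approx(45.0, abs=1e-9)


def test_classify_pose_threshold_boundary():
    assert classify_pose(1.25) == "straight"
    assert classify_pose(16.9) == "bent"
    assert classify_pose(5.0) == "straight"       # boundary is strict
    assert classify_pose(5.0 + 1e-9) == "bent"
    with pytest.raises(InvalidArgumentError):
        classify_pose(-1.0)


# ---------------------------------------------------------------------------
# depth sampling
# ---------------------------------------------------------------------------

def test_sample_depth_median_and_mask_restriction():
    depth = np.full((20, 20), 700, dtype=np.uint16)
    mask = np.zeros((20, 20), bool)
    mask[:, :10] = True
    depth[mask] = 500
    assert sample_depth(depth, PixelPoint(10.6, 10.0)) == 700  # mixed window median
    assert sample_depth(depth, PixelPoint(10.6, 10.0), mask) == 500


def test_sample_depth_fallback_and_missing():
    depth = np.zeros((30, 30), dtype=np.uint16)
    depth[10, 10] = 640
    assert sample_depth(depth, PixelPoint(12.0, 12.0)) == 640
    with pytest.raises(MissingDepthError):
        sample_depth(depth, PixelPoint(29.0, 29.0))  # nearest valid > 15 px away


# ---------------------------------------------------------------------------
# arc length and straightening
# ---------------------------------------------------------------------------

def _line_skeleton(r0, c0, r1, c1, shape):
    img = np.zeros(shape, bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    img[rr, cc] = True
    return SkeletonImage(img)


def test_arc_length_horizontal_line():
    sk = _line_skeleton(2, 1, 2, 100, (5, 105))
    e, f = PixelPoint(1.0, 2.0), PixelPoint(100.0, 2.0)
    assert arc_length(sk, e, f) == pytest.approx(99.0)


def test_arc_length_diagonal_staircase():
    sk = _line_skeleton(0, 0, 40, 40, (45, 45))
    e, f = PixelPoint(0.0, 0.0), PixelPoint(40.0, 40.0)
    assert arc_length(sk, e, f) == pytest.approx(40 * math.sqrt(2), rel=1e-9)


def test_arc_length_quarter_circle():
    img = np.zeros((110, 110), bool)
    ang = np.linspace(0, math.pi / 2, 600)
    rr = np.clip(np.round(100 - 100 * np.sin(ang)).astype(int), 0, 109)
    cc = np.clip(np.round(100 * np.cos(ang)).astype(int), 0, 109)
    img[rr, cc] = True
    from fishlength.skeleton import extract_midline

    sk = extract_midline(img)  # normalize the rasterized arc to a clean path
    (r0, c0), (r1, c1) = sk.endpoints
    e = PixelPoint(float(c0), float(r0))
    f = PixelPoint(float(c1), float(r1))
    assert arc_length(sk, e, f) == pytest.approx(100 * math.pi / 2, rel=0.03)


def test_arc_length_pairs_endpoints_by_distance():
    sk = _line_skeleton(2, 10, 2, 60, (5, 80))
    e = PixelPoint(5.0, 2.0)    # near the left end
    f = PixelPoint(70.0, 2.0)   # near the right end
    assert arc_length(sk, e, f) == pytest.approx(50 + 5 + 10)
    assert arc_length(sk, f, e) == pytest.approx(50 + 5 + 10)  # order-free


def test_straighten_reduces_to_chord_for_straight_skeleton():
    sk = _line_skeleton(2, 10, 2, 110, (5, 130))
    mask = np.zeros((5, 130), bool)
    mask[1:4, 10:111] = True
    geom = fish_geometry(mask)
    depth = np.full((5, 130), 600, dtype=np.uint16)
    pts = straighten(
        type(geom)(
            contour=geom.contour,
            rect=geom.rect,
            short_sides=geom.short_sides,
            e=PixelPoint(10.0, 2.0),
            f=PixelPoint(110.0, 2.0),
            o=geom.o,
            theta_bend=geom.theta_bend,
        ),
        sk,
        depth,
    )
    assert pts.tail.u == pytest.approx(110.0, abs=0.5)
    assert pts.tail.v == pytest.approx(2.0, abs=0.5)


def test_straighten_semicircle_arc_to_chord_ratio():
    """|em| / |ef| approaches pi/2 for a semicircular spine."""
    r = 60
    img = np.zeros((80, 140), bool)
    ang = np.linspace(0, math.pi, 800)
    rr = np.round(70 - r * np.sin(ang)).astype(int)
    cc = np.round(70 + r * np.cos(ang)).astype(int)
    img[rr, cc] = True
    from fishlength.skeleton import extract_midline

    sk = extract_midline(img)
    e = PixelPoint(70.0 + r, 70.0)
    f = PixelPoint(70.0 - r, 70.0)
    arc = arc_length(sk, e, f)
    chord = 2 * r
    assert arc / chord == pytest.approx(math.pi / 2, rel=0.04)


# ---------------------------------------------------------------------------
# length and evaluation
# ---------------------------------------------------------------------------

def _points(head, tail, d_head, d_tail, pose="straight"):
    return MeasurementPoints(
        head=PixelPoint(*head),
        head_depth_mm=d_head,
        tail=PixelPoint(*tail),
        tail_depth_mm=d_tail,
        pose=pose,
    )


def test_measure_length_similar_triangles():
    cam = default_camera()
    pts = _points((cam.u0 - 150, cam.v0), (cam.u0 + 150, cam.v0), 500.0, 500.0)
    res = measure_length(pts, cam, rm=None)
    assert res.length_mm == pytest.approx(300 * 500 / 600)
    assert res.length_mm == res.length_mm_uncorrected


def test_measure_length_no_water_equals_no_model():
    cam = default_camera()
    same = RefractionModel(camera_height_mm=250.0, n_air=1.0, n_water=1.0)
    pts = _points((100, 120), (400, 300), 480.0, 520.0)
    assert measure_length(pts, cam, same).length_mm == measure_length(pts, cam, None).length_mm


def test_measure_length_symmetric_in_head_tail():
    cam = default_camera()
    rm = RefractionModel(camera_height_mm=350.0)
    a = measure_length(_points((100, 120), (400, 300), 480.0, 520.0), cam, rm)
    b = measure_length(_points((400, 300), (100, 120), 520.0, 480.0), cam, rm)
    assert a.length_mm == pytest.approx(b.length_mm)


def test_measure_length_rejects_bad_depths():
    cam = default_camera()
    with pytest.raises(InvalidArgumentError):
        measure_length(_points((0, 0), (1, 1), 0.0, 100.0), cam)


def test_evaluate_relative_errors():
    rep = evaluate([303.0], [300.0])
    assert rep.re_percent[0] == pytest.approx(1.0)
    rep = evaluate([300.0, 300.0], [300.0, 300.0])
    assert rep.mrpe_percent == 0.0
    rep = evaluate([303.0, 297.0], [300.0, 300.0])
    assert rep.re_percent.tolist() == pytest.approx([1.0, -1.0])
    assert rep.mrpe_percent == pytest.approx(1.0)  # absolute-value mean
    with pytest.raises(InvalidArgumentError):
        evaluate([], [])
    with pytest.raises(InvalidArgumentError):
        evaluate([1.0], [1.0, 2.0])
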