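"""Rotated-box geometry: offset coding, warping, polygons, IoU, NMS."""

import math

import numpy as np
import pytest

from obbseg import geometry as G

RNG = np.random.default_rng(11)


def random_obb(rng, lo=2.0, hi=40.0, span=60.0):
    return G.OrientedBox(
        float(rng.uniform(-span, span)), float(rng.uniform(-span, span)),
        float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)),
        float(rng.uniform(-math.pi, math.pi)),
    )


def mc_iou(a: G.OrientedBox, b: G.OrientedBox, n: int, rng) -> float:
    """Independent Monte-Carlo IoU oracle: point membership sampling."""
    xs_a, ys_a = G.obb_corners(a)
    xs_b, ys_b = G.obb_corners(b)
    x0 = min(xs_a.min(), xs_b.min())
    x1 = max(xs_a.max(), xs_b.max())
    y0 = min(ys_a.min(), ys_b.min())
    y1 = max(ys_a.max(), ys_b.max())
    px = rng.uniform(x0, x1, n)
    py = rng.uniform(y0, y1, n)

    def inside(box):
        # membership under the package's axis convention: wr along (sin, cos)
        ct, st = math.cos(box.theta), math.sin(box.theta)
        dx, dy = px - box.xc, py - box.yc
        u = dx * st + dy * ct
        v = -dx * ct + dy * st
        return (np.abs(u) <= box.wr / 2) & (np.abs(v) <= box.hr / 2)

    ina, inb = inside(a), inside(b)
    union = np.count_nonzero(ina | inb)
    if union == 0:
        return 0.0
    return np.count_nonzero(ina & inb) / union


# -- offsets ----------------------------------------------------------------

def test_encode_offsets_identity_and_hand_cases():
    r = G.OrientedBox(0, 0, 10, 20, 0)
    assert G.encode_offsets(r, r).as_array() == pytest.approx([0, 0, 0, 0, 0])
    off = G.encode_offsets(r, G.OrientedBox(5, 0, 10, 20, 0))
    assert off.as_array() == pytest.approx([0.5, 0, 0, 0, 0])
    off = G.encode_offsets(r, G.OrientedBox(0, 0, 10, 20, math.pi / 2))
    assert off.as_array() == pytest.approx([0, 0, 0, 0, 0.25])


def test_decode_offsets_inverse_hand_case():
    r = G.OrientedBox(0, 0, 10, 20, 0)
    dec = G.decode_offsets(r, G.BoxOffsets(0.5, 0, 0, 0, 0))
    assert (dec.xc, dec.yc, dec.wr, dec.hr, dec.theta) == pytest.approx((5, 0, 10, 20, 0))
    same = G.decode_offsets(r, G.BoxOffsets(0, 0, 0, 0, 0))
    assert same == r


def test_encode_decode_roundtrip_1000_pairs():
    rng = np.random.default_rng(3)
    worst = 0.0
    for _ in range(1000):
        rroi, gt = random_obb(rng), random_obb(rng)
        rec = G.decode_offsets(rroi, G.encode_offsets(rroi, gt))
        dang = abs((rec.theta - gt.theta + math.pi) % (2 * math.pi) - math.pi)
        worst = max(worst, abs(rec.xc - gt.xc), abs(rec.yc - gt.yc),
                    abs(rec.wr - gt.wr), abs(rec.hr - gt.hr), dang)
    assert worst < 1e-6


def test_vectorized_coding_matches_scalar():
    rng = np.random.default_rng(5)
    rr = np.array([[random_obb(rng).xc] * 0 or
                   [b.xc, b.yc, b.wr, b.hr, b.theta]
                   for b in [random_obb(rng) for _ in range(20)]])
    gt = np.array([[b.xc, b.yc, b.wr, b.hr, b.theta]
                   for b in [random_obb(rng) for _ in range(20)]])
    offs = G.encode_offsets_array(rr, gt)
    for i in range(20):
        scalar = G.encode_offsets(G.OrientedBox(*rr[i]), G.OrientedBox(*gt[i]))
        assert offs[i] == pytest.approx(scalar.as_array(), abs=1e-9)
    rec = G.decode_offsets_array(rr, offs)
    assert rec[:, :4] == pytest.approx(gt[:, :4], abs=1e-6)


def test_invalid_box_raises():
    with pytest.raises(G.InvalidBoxError):
        G.OrientedBox(0, 0, -1, 5, 0)
    with pytest.raises(G.InvalidBoxError):
        G.HorizontalBox(0, 0, 3, 0)


# -- warp -------------------------------------------------------------------

def test_warp_center_maps_to_patch_center():
    rng = np.random.default_rng(9)
    for _ in range(100):
        b = random_obb(rng)
        u, v = G.warp_point((b.xc, b.yc), b)
        assert (u, v) == pytest.approx((b.wr / 2, b.hr / 2), abs=1e-9)


def test_warp_printed_matrix_hand_cases():
    b = G.OrientedBox(3, 4, 10, 20, math.pi / 2)
    # identity angle of the printed matrix
    assert G.warp_point((3 + 2, 4 + 1), b) == pytest.approx((2 + 5, 1 + 10))
    b0 = G.OrientedBox(3, 4, 10, 20, 0.0)
    assert G.warp_point((3 + 2, 4 + 1), b0) == pytest.approx((1 + 5, -2 + 10))


def test_warp_standard_convention_identity_at_zero():
    b0 = G.OrientedBox(3, 4, 10, 20, 0.0)
    assert G.warp_point((3 + 2, 4 + 1), b0, convention="standard") == \
        pytest.approx((2 + 5, 1 + 10))


def test_warp_corners_cover_unit_patch():
    # theta = pi/2 is the identity angle of the printed matrix; the box-axis
    # convention makes the property hold at every angle
    rng = np.random.default_rng(31)
    angles = [math.pi / 2] + list(rng.uniform(-math.pi, math.pi, 10))
    for theta in angles:
        b = G.OrientedBox(-7, 2, 12, 30, theta)
        xs, ys = G.obb_corners(b)
        uv = np.array([G.warp_point((x, y), b) for x, y in zip(xs, ys)])
        assert sorted(set(np.round(uv[:, 0], 6))) == pytest.approx([0.0, 12.0])
        assert sorted(set(np.round(uv[:, 1], 6))) == pytest.approx([0.0, 30.0])


def test_unwarp_inverts_warp():
    rng = np.random.default_rng(13)
    for conv in ("printed", "standard"):
        b = random_obb(rng)
        pts = rng.uniform(-50, 50, size=(20, 2))
        uv = np.array([G.warp_point(p, b, conv) for p in pts])
        back = G.unwarp_points(uv, b, conv)
        assert back == pytest.approx(pts, abs=1e-9)


# -- polygons & IoU ---------------------------------------------------------

def test_obb_to_polygon_squares():
    p = G.obb_to_polygon(G.OrientedBox(0, 0, 2, 2, 0))
    assert sorted(map(tuple, np.round(p.vertices, 6))) == [
        (-1, -1), (-1, 1), (1, -1), (1, 1)]
    p45 = G.obb_to_polygon(G.OrientedBox(0, 0, 2, 2, math.pi / 4))
    r2 = math.sqrt(2)
    got = sorted(map(tuple, np.round(p45.vertices, 6)))
    want = sorted([(0, round(r2, 6)), (0, round(-r2, 6)),
                   (round(r2, 6), 0), (round(-r2, 6), 0)])
    assert got == pytest.approx(want)


def test_polygon_area_matches_box_area():
    rng = np.random.default_rng(17)
    for _ in range(500):
        b = random_obb(rng)
        assert G.obb_to_polygon(b).area == pytest.approx(b.area, rel=1e-9)


def test_polygon_ccw_and_min_vertices():
    v = G.obb_to_polygon(G.OrientedBox(5, 5, 4, 2, 0.3)).vertices
    x, y = v[:, 0], v[:, 1]
    assert float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) > 0
    with pytest.raises(ValueError):
        G.Polygon(np.zeros((2, 2)))


def test_rotated_iou_identity_disjoint_and_45deg():
    b = G.OrientedBox(0, 0, 3, 5, 0.7)
    assert G.rotated_iou(b, b) == pytest.approx(1.0)
    far = G.OrientedBox(100, 100, 3, 5, 0.7)
    assert G.rotated_iou(b, far) == 0.0
    sq = G.OrientedBox(0, 0, 1, 1, 0)
    sq45 = G.OrientedBox(0, 0, 1, 1, math.pi / 4)
    inter = 2 * (math.sqrt(2) - 1)  # octagon area
    expect = inter / (2 - inter)
    assert expect == pytest.approx(0.70710678, abs=1e-6)
    assert G.rotated_iou(sq, sq45) == pytest.approx(expect, abs=1e-3)


def test_rotated_iou_against_monte_carlo():
    rng = np.random.default_rng(23)
    for _ in range(25):
        a = random_obb(rng, span=15.0)
        b = random_obb(rng, span=15.0)
        est = mc_iou(a, b, 200_000, rng)
        assert G.rotated_iou(a, b) == pytest.approx(est, abs=0.01)


def test_edge_touching_boxes_have_zero_iou():
    a = G.OrientedBox(0, 0, 2, 2, 0)
    b = G.OrientedBox(2, 0, 2, 2, 0)
    assert G.rotated_iou(a, b) == 0.0


def test_min_area_rect_recovers_box_from_polygon():
    rng = np.random.default_rng(29)
    for _ in range(100):
        b = random_obb(rng)
        rec = G.min_area_rect(G.obb_to_polygon(b).vertices)
        assert G.boxes_equivalent(b, rec, tol_px=1e-6, tol_deg=1e-4)


def test_mask_to_obb_on_rasterized_box():
    b = G.OrientedBox(40, 30, 30, 12, 0.5)
    mask = G.rasterize_obb(b, (64, 96))
    rec = G.mask_to_obb(mask)
    assert G.boxes_equivalent(b, rec, tol_px=1.0, tol_deg=2.0)


def test_axis_aligned_hull():
    b = G.OrientedBox(0, 0, 4, 2, math.pi / 2)
    hb = b.axis_aligned()
    # at theta = pi/2 the box is axis-aligned with wr horizontal
    assert (hb.wh, hb.hh) == pytest.approx((4, 2))


# -- NMS --------------------------------------------------------------------

def _det(score, box, cat=0):
    return G.DetectionResult(category=cat, score=score, box=box)


def test_nms_single_and_disjoint_pass_through():
    b1 = G.OrientedBox(0, 0, 4, 2, 0.1)
    b2 = G.OrientedBox(50, 50, 4, 2, 0.4)
    dets = [_det(0.7, b1)]
    assert G.rotated_nms(dets, 0.5) == dets
    both = [_det(0.7, b1), _det(0.6, b2)]
    assert G.rotated_nms(both, 0.5) == both


def test_nms_suppresses_duplicates_keeps_highest():
    b = G.OrientedBox(10, 10, 6, 3, 0.3)
    dets = [_det(0.8, b), _det(0.9, b)]
    out = G.rotated_nms(dets, 0.5)
    assert len(out) == 1 and out[0].score == 0.9


def test_nms_is_per_category_and_score_sorted():
    b = G.OrientedBox(10, 10, 6, 3, 0.3)
    dets = [_det(0.8, b, cat=1), _det(0.9, b, cat=0)]
    out = G.rotated_nms(dets, 0.5)
    assert len(out) == 2
    assert [d.score for d in out] == [0.9, 0.8]


def test_nms_deterministic_tiebreak_by_index():
    b = G.OrientedBox(10, 10, 6, 3, 0.3)
    dets = [_det(0.9, b), _det(0.9, b)]
    out = G.rotated_nms(dets, 0.5)
    assert out == [dets[0]]
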