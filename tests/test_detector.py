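"""Detector architecture contracts: pyramid, anchors, RoI ops, sampler, loss."""

import math

import numpy as np
import pytest

from obbseg import detector as D
from obbseg import nn
from obbseg.geometry import OrientedBox, decode_offsets_array
from obbseg.nn.autograd import Tensor


@pytest.fixture(scope="module")
def small_detector():
    cfg = D.DetectorConfig(channels=4, num_levels=5, head_fc_dim=32)
    return D.RotatedDetector(cfg, seed=0)


# -- pyramid ----------------------------------------------------------------

def test_pyramid_strides_and_sizes(small_detector):
    img = np.random.default_rng(0).random((128, 128)).astype(np.float32)
    pyr = small_detector.build_pyramid(img)
    assert [fm.stride for fm in pyr] == [4, 8, 16, 32, 64]
    assert [fm.shape[2] for fm in pyr] == [32, 16, 8, 4, 2]
    # equal channel count across levels
    assert len({fm.shape[1] for fm in pyr}) == 1


def test_pyramid_64px_toy_sizes(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    assert [fm.shape[2] for fm in pyr] == [16, 8, 4, 2, 1]


def test_pyramid_pads_non_divisible_input(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((100, 70), dtype=np.float32))
    assert pyr[0].shape[2:] == (128 // 4, 128 // 4)
    assert pyr[0].pad == (28, 58)


def test_zero_input_gives_bias_only_outputs(small_detector):
    p0 = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    p1 = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    for a, b in zip(p0, p1):
        # deterministic, spatially constant (bias-determined) maps
        assert np.array_equal(a.tensor.data, b.tensor.data)
        flat = a.tensor.data.reshape(a.shape[1], -1)
        assert np.allclose(flat, flat[:, :1], atol=1e-6)


# -- anchors ----------------------------------------------------------------

def test_anchor_counts_ratios_and_sizes(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((128, 128), dtype=np.float32))
    anchors = D.generate_anchors(pyr, base_scale=8.0)
    for fm, lv in zip(pyr, anchors.per_level):
        _, _, h, w = fm.shape
        assert len(lv) == 5 * h * w  # five anchors per spatial cell
    # 1:1 anchor at stride 4 with base 8 is 32x32
    p2 = anchors.per_level[0].reshape(-1, 5, 4)
    assert p2[0, 2, 2] == pytest.approx(32.0)
    assert p2[0, 2, 3] == pytest.approx(32.0)
    # 4:1 and 1:4 have equal area with swapped sides
    a14, a41 = p2[0, 0], p2[0, 4]
    assert a14[2] * a14[3] == pytest.approx(a41[2] * a41[3])
    assert (a14[2], a14[3]) == pytest.approx((a41[3], a41[2]))
    ratios = p2[0, :, 2] / p2[0, :, 3]
    assert ratios == pytest.approx([0.25, 0.5, 1.0, 2.0, 4.0])


# -- RPN proposals ----------------------------------------------------------

def _fake_rpn_outputs(anchors, hot=()):
    """Craft per-level logits (1 at chosen anchor indices) and zero deltas."""
    logits, deltas = [], []
    offset = 0
    for lv in anchors.per_level:
        lg = np.full(len(lv), -5.0)
        for h in hot:
            if offset <= h < offset + len(lv):
                lg[h - offset] = 5.0
        logits.append(Tensor(lg))
        deltas.append(Tensor(np.zeros((len(lv), 4))))
        offset += len(lv)
    return logits, deltas


def test_zero_deltas_proposals_equal_anchors(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    anchors = D.generate_anchors(pyr, 4.0)
    logits, deltas = _fake_rpn_outputs(anchors, hot=(7,))
    boxes, scores = small_detector.propose_hrois(anchors, logits, deltas,
                                                 (64, 64), topk=1)
    a = anchors.all[7]
    # proposals equal the anchor up to image clipping
    x0 = max(a[0] - a[2] / 2, 0)
    x1 = min(a[0] + a[2] / 2, 63)
    assert boxes[0][0] == pytest.approx((x0 + x1) / 2)
    assert len(boxes) == 1  # N=1 -> single highest-scoring proposal


def test_oracle_objectness_covers_gt_centers(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    anchors = D.generate_anchors(pyr, 4.0)
    gt_centers = [(16.0, 16.0), (44.0, 40.0)]
    hot = []
    for cx, cy in gt_centers:
        d = np.hypot(anchors.all[:, 0] - cx, anchors.all[:, 1] - cy)
        hot.append(int(np.argmin(d)))
    logits, deltas = _fake_rpn_outputs(anchors, hot=tuple(hot))
    boxes, _ = small_detector.propose_hrois(anchors, logits, deltas, (64, 64))
    for cx, cy in gt_centers:
        inside = [(abs(b[0] - cx) <= b[2] / 2 and abs(b[1] - cy) <= b[3] / 2)
                  for b in boxes[:len(gt_centers)]]
        assert any(inside)


# -- RoI transformer --------------------------------------------------------

def test_learner_zero_output_returns_hroi_at_angle_zero(small_detector):
    pyr = small_detector.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    hrois = np.array([[20.0, 24.0, 10.0, 20.0], [40.0, 30.0, 12.0, 8.0]])
    rrois, offsets = small_detector.rroi_learner(pyr, hrois)
    # final FC is zero-initialized: offsets are exactly zero
    assert np.all(offsets.data == 0.0)
    assert rrois[:, :4] == pytest.approx(hrois)
    assert rrois[:, 4] == pytest.approx([0.0, 0.0])
    assert len(rrois) == len(hrois)  # output count equals input count


def test_learner_quarter_turn_bias():
    cfg = D.DetectorConfig(channels=4, num_levels=2, head_fc_dim=16)
    det = D.RotatedDetector(cfg, seed=1)
    det.learner.fc1.weight.data[:] = 0.0
    det.learner.fc1.bias.data[:] = 0.0
    det.learner.fc2.bias.data[:] = np.array([0, 0, 0, 0, 0.25])
    pyr = det.build_pyramid(np.zeros((64, 64), dtype=np.float32))
    rrois, _ = det.rroi_learner(pyr, np.array([[20.0, 20.0, 10.0, 20.0]]))
    assert rrois[0] == pytest.approx([20, 20, 10, 20, math.pi / 2])


def test_rroi_warp_shape_and_constant_map():
    cfg = D.DetectorConfig(channels=3, num_levels=1)
    det = D.RotatedDetector(cfg, seed=0)
    fm = D.FeatureMap(Tensor(np.full((1, 3, 16, 16), 2.5)), 4)
    rroi = np.array([[32.0, 32.0, 20.0, 14.0, 0.7]])
    patch = det.rroi_warp([fm], rroi)
    assert patch.shape == (1, 3, 7, 7)
    assert np.allclose(patch.data, 2.5, atol=1e-9)


def test_rroi_warp_identity_angle_equals_crop_resize():
    """At theta=pi/2 (printed-matrix identity) warping is a plain axis-aligned
    bilinear crop, checked against a directly computed interpolation."""
    cfg = D.DetectorConfig(channels=1, num_levels=1)
    det = D.RotatedDetector(cfg, seed=0)
    rng = np.random.default_rng(5)
    grid = rng.random((1, 1, 16, 16))
    fm = D.FeatureMap(Tensor(grid), 4)
    xc, yc, wr, hr = 30.0, 28.0, 21.0, 14.0
    patch = det.rroi_warp([fm], np.array([[xc, yc, wr, hr, math.pi / 2]]))
    us = xc - wr / 2 + (np.arange(7) + 0.5) / 7 * wr
    vs = yc - hr / 2 + (np.arange(7) + 0.5) / 7 * hr
    for i, v in enumerate(vs):
        for j, u in enumerate(us):
            sx, sy = u / 4 - 0.5, v / 4 - 0.5
            x0, y0 = int(np.floor(sx)), int(np.floor(sy))
            fx, fy = sx - x0, sy - y0
            ref = (grid[0, 0, y0, x0] * (1 - fx) * (1 - fy)
                   + grid[0, 0, y0, x0 + 1] * fx * (1 - fy)
                   + grid[0, 0, y0 + 1, x0] * (1 - fx) * fy
                   + grid[0, 0, y0 + 1, x0 + 1] * fx * fy)
            assert patch.data[0, 0, i, j] == pytest.approx(ref, abs=1e-9)


def test_head_output_shapes_and_softmax(small_detector):
    patches = Tensor(np.random.default_rng(0).random((3, 4, 7, 7)))
    cls, reg = small_detector.head_forward(patches)
    k = small_detector.cfg.num_classes + 1
    assert cls.shape == (3, k) and k == 10
    assert reg.shape == (3, 5 * k)
    probs = nn.functional.softmax(cls.data, axis=1)
    assert probs.sum(axis=1) == pytest.approx(np.ones(3))


# -- sampler ----------------------------------------------------------------

def test_sampler_batch_sizes_and_ratios():
    rng = np.random.default_rng(0)
    labels = np.array([1] * 300 + [0] * 1000)
    s = D.sample_rois(labels, "hroi", rng)
    assert len(s) == 256
    assert (labels[s] == 1).sum() == 128 and (labels[s] == 0).sum() == 128
    labels = np.array([1] * 50 + [0] * 1000)
    s = D.sample_rois(labels, "rroi", rng)
    assert len(s) == 512
    assert (labels[s] == 1).sum() == 50 and (labels[s] == 0).sum() == 462
    s = D.sample_rois(labels, "obb", rng)
    assert len(s) == 512 and (labels[s] == 1).sum() == 50


def test_sampler_edge_cases_and_determinism():
    labels = np.array([1] * 40)  # zero negatives -> all-positive sample
    s = D.sample_rois(labels, "hroi", np.random.default_rng(1))
    assert len(s) == 40 and (labels[s] == 1).all()
    labels = np.array([1] * 600 + [0] * 600 + [-1] * 100)
    a = D.sample_rois(labels, "rroi", np.random.default_rng(7))
    b = D.sample_rois(labels, "rroi", np.random.default_rng(7))
    assert np.array_equal(a, b)
    assert not np.any(labels[a] == -1)  # ignore labels never sampled


# -- losses -----------------------------------------------------------------

def test_detection_loss_combination_and_linearity():
    rpn = Tensor(0.3)
    cls = Tensor(0.5)
    reg = Tensor(0.2)
    total = D.detection_loss(rpn, cls, reg, alpha1=1.0, alpha2=1.0)
    assert float(total.data) == pytest.approx(1.0)
    doubled = D.detection_loss(rpn, cls, reg, alpha1=1.0, alpha2=2.0)
    assert float(doubled.data) - float(total.data) == pytest.approx(0.2)


def test_train_step_loss_nonnegative_and_deterministic():
    cfg = D.DetectorConfig(channels=4, num_levels=2, head_fc_dim=16,
                           anchor_base_scale=4.0,
                           stage_batch={"hroi": 32, "rroi": 16, "obb": 16})
    det = D.RotatedDetector(cfg, seed=3)
    img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
    boxes = [OrientedBox(30, 30, 20, 10, 0.4), OrientedBox(45, 20, 12, 8, -0.5)]
    labels = [0, 3]
    l1, p1 = det.train_step(img, boxes, labels, np.random.default_rng(11))
    l2, p2 = det.train_step(img, boxes, labels, np.random.default_rng(11))
    assert float(l1.data) >= 0.0
    assert all(v >= 0 for v in p1.values())
    assert float(l1.data) == pytest.approx(float(l2.data))


def test_wrap_turn_distance():
    d = D._wrap_turn(np.array([0.0, 0.45, 0.55, 0.98, -0.98]))
    assert d == pytest.approx([0.0, 0.45, -0.45, -0.02, 0.02])
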