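"""Two-stage rotated detector with an RoI Transformer.

Pipeline: a convolutional backbone with a feature pyramid (levels P2..P6 at
strides {4, 8, 16, 32, 64}), a region proposal network scoring 5 anchors per
cell (aspect ratios {1:4, 1:2, 1:1, 2:1, 4:1}), an RoI Transformer that
(i) regresses a 5-parameter rotated-box offset from each horizontal
proposal treated as a rotated box at angle zero (RRoI Learner) and
(ii) extracts the straightened rotated region by bilinear sampling on the
inverse warp grid (RRoI Warping, 7x7 output), and a head with one shared FC
layer feeding two sibling FCs for (K+1)-way classification and per-class
oriented-box regression.

Training follows the joint loss L_D = L_RPN + a1 * L_cls + a2 * L_reg with
a1 = a2 = 1; L_reg collects the smooth-L1 offset losses of the RRoI Learner
and the head over matched positives.  The angle channel is regressed as the
turn fraction of the offset encoding, with the smooth-L1 applied to the
wrap-aware difference min(|d|, 1 - |d|) so targets on either side of the
0/1 boundary remain trainable.  RoI sampling per stage uses batch sizes
{256, 512, 512} at positive:negative ratios {1:1, 1:3, 1:3}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import (
    DetectionResult,
    OrientedBox,
    decode_offsets_array,
    encode_offsets_array,
    horizontal_iou_matrix,
    rotated_iou_matrix,
    rotated_nms,
    unwarp_points,
)
from .nn import functional as F
from .nn.autograd import Tensor

STAGE_BATCH = {"hroi": 256, "rroi": 512, "obb": 512}
STAGE_POS_FRAC = {"hroi": 1 / 2, "rroi": 1 / 4, "obb": 1 / 4}  # 1:1, 1:3, 1:3


@dataclass
class DetectorConfig:
    num_classes: int = 9
    in_channels: int = 1
    channels: int = 16               # backbone/FPN width
    num_levels: int = 5              # P2..P6 for 5; desk-scale uses 2
    anchor_base_scale: float = 8.0   # anchor side = base * stride at 1:1
    anchor_ratios: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    rpn_pos_thr: float = 0.7
    rpn_neg_thr: float = 0.3
    rpn_pre_nms_topk: int = 600
    rpn_post_nms_topk: int = 64
    rpn_nms_thr: float = 0.7
    roi_pos_thr: float = 0.5
    head_fc_dim: int = 2048
    roi_size: int = 7
    roi_sampling: int = 2            # sampling points per bin side (RoI-Align)
    score_thr: float = 0.05
    nms_thr: float = 0.5
    warp_convention: str = "printed"
    loss_alpha1: float = 1.0
    loss_alpha2: float = 1.0
    min_box: float = 2.0
    stage_batch: dict = field(default_factory=lambda: dict(STAGE_BATCH))
    stage_pos_frac: dict = field(default_factory=lambda: dict(STAGE_POS_FRAC))

    @property
    def strides(self) -> tuple[int, ...]:
        return tuple(4 * 2 ** i for i in range(self.num_levels))


@dataclass
class FeatureMap:
    """One pyramid level: (1, C, H, W) tensor plus its stride in pixels."""

    tensor: Tensor
    stride: int

    @property
    def shape(self):
        return self.tensor.shape


@dataclass
class AnchorSet:
    """Per-level anchor arrays, each (H*W*A, 4) as [xc, yc, w, h]."""

    per_level: list[np.ndarray]
    ratios: tuple[float, ...]
    base_scale: float

    @property
    def all(self) -> np.ndarray:
        return np.concatenate(self.per_level, axis=0)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Backbone(nn.Module):
    """Small residual-free CNN + top-down feature pyramid.

    The contract is the pyramid shape — equal channels at every level and
    strides {4, 8, ...} — not any particular stage depth; width and level
    count are configurable so the same code runs at desk scale.
    """

    def __init__(self, cfg: DetectorConfig, rng):
        c = cfg.channels
        self.cfg = cfg
        self.stem = nn.Sequential(
            nn.ConvBlock(cfg.in_channels, c, stride=2, rng=rng),
            nn.ConvBlock(c, c, stride=2, rng=rng),
        )
        n_body = min(cfg.num_levels, 4) - 1
        self.stages = [nn.ConvBlock(c, c, stride=2, rng=rng)
                       for _ in range(n_body)]
        self.laterals = [nn.Conv2d(c, c, k=1, rng=rng)
                         for _ in range(n_body + 1)]
        self.smooth = [nn.Conv2d(c, c, k=3, rng=rng)
                       for _ in range(n_body + 1)]

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = [self.stem(x)]
        for st in self.stages:
            feats.append(st(feats[-1]))
        # top-down fusion: upsample + lateral sum
        tops = [None] * len(feats)
        tops[-1] = self.laterals[-1](feats[-1])
        for i in range(len(feats) - 2, -1, -1):
            tops[i] = self.laterals[i](feats[i]) + F.upsample_nearest(tops[i + 1], 2)
        outs = [self.smooth[i](t) for i, t in enumerate(tops)]
        if self.cfg.num_levels == 5:  # P6: 2x downsample of P5
            outs.append(F.max_pool2d(outs[-1], 2))
        return outs


class RPNHead(nn.Module):
    """Shared conv head: per-anchor objectness logit + 4 horizontal deltas."""

    def __init__(self, channels: int, num_anchors: int, rng):
        self.conv = nn.ConvBlock(channels, channels, rng=rng)
        self.cls = nn.Conv2d(channels, num_anchors, k=1, rng=rng)
        self.reg = nn.Conv2d(channels, num_anchors * 4, k=1, rng=rng)

    def forward(self, fmap: Tensor) -> tuple[Tensor, Tensor]:
        h = self.conv(fmap)
        return self.cls(h), self.reg(h)


class RRoILearner(nn.Module):
    """RoI-Align + FC stack ending in a 5-dim rotated-offset output.

    The final layer is zero-initialized, so an untrained learner returns the
    horizontal proposal unchanged (angle zero).
    """

    def __init__(self, cfg: DetectorConfig, rng):
        d = cfg.channels * cfg.roi_size ** 2
        self.fc1 = nn.Linear(d, 128, rng=rng)
        self.fc2 = nn.Linear(128, 5, rng=rng, zero_init=True)

    def forward(self, patches: Tensor) -> Tensor:
        n = patches.shape[0]
        return self.fc2(self.fc1(patches.reshape(n, -1)).relu())


class DetectionHead(nn.Module):
    """Shared FC, then sibling FCs for classification and per-class offsets."""

    def __init__(self, cfg: DetectorConfig, rng):
        d = cfg.channels * cfg.roi_size ** 2
        k = cfg.num_classes + 1
        self.fc = nn.Linear(d, cfg.head_fc_dim, rng=rng)
        self.cls = nn.Linear(cfg.head_fc_dim, k, rng=rng)
        self.reg = nn.Linear(cfg.head_fc_dim, 5 * k, rng=rng, zero_init=True)

    def forward(self, patches: Tensor) -> tuple[Tensor, Tensor]:
        n = patches.shape[0]
        h = self.fc(patches.reshape(n, -1)).relu()
        return self.cls(h), self.reg(h)


# ---------------------------------------------------------------------------
# anchor and box utilities (plain numpy)
# ---------------------------------------------------------------------------

def generate_anchors(pyramid: list[FeatureMap], base_scale: float,
                     ratios: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
                     ) -> AnchorSet:
    """5 anchors per cell; area (base*stride)^2, sides scaled by sqrt(ratio)."""
    per_level = []
    for fm in pyramid:
        _, _, h, w = fm.shape
        side = base_scale * fm.stride
        ws = np.array([side * math.sqrt(r) for r in ratios])
        hs = np.array([side / math.sqrt(r) for r in ratios])
        xs = (np.arange(w) + 0.5) * fm.stride - 0.5
        ys = (np.arange(h) + 0.5) * fm.stride - 0.5
        cx, cy = np.meshgrid(xs, ys)
        boxes = np.zeros((h, w, len(ratios), 4))
        boxes[..., 0] = cx[:, :, None]
        boxes[..., 1] = cy[:, :, None]
        boxes[..., 2] = ws[None, None, :]
        boxes[..., 3] = hs[None, None, :]
        per_level.append(boxes.reshape(-1, 4))
    return AnchorSet(per_level, tuple(ratios), base_scale)


def encode_hbox(anchors: np.ndarray, gts: np.ndarray) -> np.ndarray:
    t = np.empty_like(anchors)
    t[:, 0] = (gts[:, 0] - anchors[:, 0]) / anchors[:, 2]
    t[:, 1] = (gts[:, 1] - anchors[:, 1]) / anchors[:, 3]
    t[:, 2] = np.log(gts[:, 2] / anchors[:, 2])
    t[:, 3] = np.log(gts[:, 3] / anchors[:, 3])
    return t


def decode_hbox(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    out = np.empty_like(anchors)
    out[:, 0] = anchors[:, 0] + deltas[:, 0] * anchors[:, 2]
    out[:, 1] = anchors[:, 1] + deltas[:, 1] * anchors[:, 3]
    out[:, 2] = anchors[:, 2] * np.exp(np.clip(deltas[:, 2], -6, 6))
    out[:, 3] = anchors[:, 3] * np.exp(np.clip(deltas[:, 3], -6, 6))
    return out


def horizontal_nms(boxes: np.ndarray, scores: np.ndarray, thr: float,
                   topk: int) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size and len(keep) < topk:
        i = order[0]
        keep.append(i)
        iou = horizontal_iou_matrix(boxes[i:i + 1], boxes[order[1:]])[0]
        order = order[1:][iou <= thr]
    return np.array(keep, dtype=int)


def sample_rois(labels: np.ndarray, stage: str, rng: np.random.Generator,
                batch_sizes: dict | None = None,
                pos_fracs: dict | None = None) -> np.ndarray:
    """Sample candidate indices at the stage's batch size and pos:neg ratio.

    ``labels``: +1 positive, 0 negative, -1 ignore.  Shortfall in positives
    is filled with negatives (and vice versa); deterministic under the rng.
    """
    batch = (batch_sizes or STAGE_BATCH)[stage]
    pos_frac = (pos_fracs or STAGE_POS_FRAC)[stage]
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = min(len(pos), int(round(batch * pos_frac)))
    n_neg = min(len(neg), batch - n_pos)
    if n_pos < int(round(batch * pos_frac)):  # fill shortfall with negatives
        n_neg = min(len(neg), batch - n_pos)
    picked_pos = rng.choice(pos, size=n_pos, replace=False) if n_pos else \
        np.array([], dtype=int)
    picked_neg = rng.choice(neg, size=n_neg, replace=False) if n_neg else \
        np.array([], dtype=int)
    return np.concatenate([picked_pos, picked_neg])


def _wrap_turn(d: np.ndarray) -> np.ndarray:
    """Wrap a turn-fraction difference into [-0.5, 0.5)."""
    return (d + 0.5) % 1.0 - 0.5


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

class RotatedDetector(nn.Module):
    def __init__(self, cfg: DetectorConfig | None = None, seed: int = 0):
        self.cfg = cfg or DetectorConfig()
        rng = np.random.default_rng(seed)
        self.backbone = Backbone(self.cfg, rng)
        self.rpn = RPNHead(self.cfg.channels, len(self.cfg.anchor_ratios), rng)
        self.learner = RRoILearner(self.cfg, rng)
        self.head = DetectionHead(self.cfg, rng)

    # -- feature pyramid -------------------------------------------------
    def prep(self, image: np.ndarray) -> tuple[Tensor, tuple[int, int]]:
        """Pad with reflection to a multiple of the deepest stride."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[None], self.cfg.in_channels, axis=0)
        else:
            img = img.transpose(2, 0, 1)
        mult = self.cfg.strides[-1]
        h, w = img.shape[1:]
        ph = (-h) % mult
        pw = (-w) % mult
        if ph or pw:
            img = np.pad(img, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return Tensor(img[None]), (ph, pw)

    def build_pyramid(self, image: np.ndarray) -> list[FeatureMap]:
        x, pad = self.prep(image)
        outs = self.backbone(x)
        pyramid = [FeatureMap(t, s) for t, s in zip(outs, self.cfg.strides)]
        pyramid[0].pad = pad  # recorded padding offset
        return pyramid

    # -- RPN ---------------------------------------------------------------
    def rpn_forward(self, pyramid: list[FeatureMap]):
        """Per-level (objectness logits, deltas) flattened anchor-major."""
        logits, deltas = [], []
        for fm in pyramid:
            lg, dl = self.rpn(fm.tensor)
            a = lg.shape[1]
            # (1, A, H, W) -> (H*W*A,)
            logits.append(lg.transpose(0, 2, 3, 1).reshape(-1))
            deltas.append(dl.transpose(0, 2, 3, 1).reshape(-1, 4))
        return logits, deltas

    def propose_hrois(self, anchors: AnchorSet, logits, deltas,
                      image_shape: tuple[int, int],
                      topk: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Decode, clip, pre-NMS top-N, horizontal NMS.  Returns (boxes, scores)."""
        cfg = self.cfg
        all_anchors = anchors.all
        scores = np.concatenate([l.data for l in logits])
        dl = np.concatenate([d.data for d in deltas], axis=0)
        boxes = decode_hbox(all_anchors, dl)
        h, w = image_shape
        x0 = np.clip(boxes[:, 0] - boxes[:, 2] / 2, 0, w - 1)
        x1 = np.clip(boxes[:, 0] + boxes[:, 2] / 2, 0, w - 1)
        y0 = np.clip(boxes[:, 1] - boxes[:, 3] / 2, 0, h - 1)
        y1 = np.clip(boxes[:, 1] + boxes[:, 3] / 2, 0, h - 1)
        boxes = np.stack([(x0 + x1) / 2, (y0 + y1) / 2,
                          np.maximum(x1 - x0, cfg.min_box),
                          np.maximum(y1 - y0, cfg.min_box)], axis=1)
        order = np.argsort(-scores, kind="stable")[:cfg.rpn_pre_nms_topk]
        keep = horizontal_nms(boxes[order], scores[order], cfg.rpn_nms_thr,
                              topk or cfg.rpn_post_nms_topk)
        sel = order[keep]
        return boxes[sel], scores[sel]

    # -- RoI Transformer ---------------------------------------------------
    def _assign_level(self, areas: np.ndarray) -> np.ndarray:
        lvl = np.floor(np.log2(np.sqrt(areas) / self.cfg.anchor_base_scale + 1e-9)) - 2
        return np.clip(lvl, 0, self.cfg.num_levels - 1).astype(int)

    def _roi_align(self, pyramid, hrois: np.ndarray) -> Tensor:
        """RoI-Align a fixed grid (roi_size^2, roi_sampling^2 pts/bin)."""
        cfg = self.cfg
        n = cfg.roi_size * cfg.roi_sampling
        levels = self._assign_level(hrois[:, 2] * hrois[:, 3])
        patches = []
        for i, box in enumerate(hrois):
            fm = pyramid[levels[i]]
            xc, yc, bw, bh = box
            us = xc - bw / 2 + (np.arange(n) + 0.5) / n * bw
            vs = yc - bh / 2 + (np.arange(n) + 0.5) / n * bh
            gx, gy = np.meshgrid(us, vs)
            sx = gx / fm.stride - 0.5
            sy = gy / fm.stride - 0.5
            samp = F.bilinear_sample(fm.tensor.reshape(*fm.shape[1:]),
                                     sx.ravel(), sy.ravel())
            c = samp.shape[0]
            samp = samp.reshape(c, cfg.roi_size, cfg.roi_sampling,
                                cfg.roi_size, cfg.roi_sampling)
            patches.append(samp.mean(axis=(2, 4)))
        return nn.stack(patches, axis=0)

    def rroi_learner(self, pyramid, hrois: np.ndarray
                     ) -> tuple[np.ndarray, Tensor]:
        """Predict rotated boxes from horizontal proposals.

        Returns (decoded (N, 5) rotated boxes, raw offset Tensor for loss).
        """
        if len(hrois) == 0:
            raise ValueError("rroi_learner needs at least one proposal")
        patches = self._roi_align(pyramid, hrois)
        offsets = self.learner(patches)
        as_obb = np.concatenate([hrois, np.zeros((len(hrois), 1))], axis=1)
        rrois = decode_offsets_array(as_obb, offsets.data)
        rrois[:, 2:4] = np.maximum(rrois[:, 2:4], self.cfg.min_box)
        return rrois, offsets

    def rroi_warp(self, pyramid, rrois: np.ndarray) -> Tensor:
        """Extract straightened out_size x out_size patches for each RRoI."""
        cfg = self.cfg
        n = cfg.roi_size
        levels = self._assign_level(rrois[:, 2] * rrois[:, 3])
        patches = []
        for i, rb in enumerate(rrois):
            fm = pyramid[levels[i]]
            box = OrientedBox(*rb)
            us = (np.arange(n) + 0.5) / n * box.wr
            vs = (np.arange(n) + 0.5) / n * box.hr
            gu, gv = np.meshgrid(us, vs)
            uv = np.stack([gu.ravel(), gv.ravel()], axis=1)
            xy = unwarp_points(uv, box, self.cfg.warp_convention)
            sx = xy[:, 0] / fm.stride - 0.5
            sy = xy[:, 1] / fm.stride - 0.5
            samp = F.bilinear_sample(fm.tensor.reshape(*fm.shape[1:]), sx, sy)
            patches.append(samp.reshape(samp.shape[0], n, n))
        return nn.stack(patches, axis=0)

    def head_forward(self, patches: Tensor) -> tuple[Tensor, Tensor]:
        return self.head(patches)

    # -- inference ---------------------------------------------------------
    def detect(self, image: np.ndarray) -> list[DetectionResult]:
        cfg = self.cfg
        pyramid = self.build_pyramid(image)
        anchors = generate_anchors(pyramid, cfg.anchor_base_scale,
                                   cfg.anchor_ratios)
        logits, deltas = self.rpn_forward(pyramid)
        hrois, _ = self.propose_hrois(anchors, logits, deltas,
                                      image.shape[:2])
        if len(hrois) == 0:
            return []
        rrois, _ = self.rroi_learner(pyramid, hrois)
        patches = self.rroi_warp(pyramid, rrois)
        cls_logits, reg = self.head_forward(patches)
        probs = F.softmax(cls_logits.data, axis=1)
        dets: list[DetectionResult] = []
        k = cfg.num_classes
        reg_data = reg.data.reshape(len(rrois), k + 1, 5)
        for c in range(k):
            sc = probs[:, c]
            sel = np.flatnonzero(sc >= cfg.score_thr)
            if sel.size == 0:
                continue
            boxes = decode_offsets_array(rrois[sel], reg_data[sel, c])
            for j, bi in enumerate(sel):
                bb = boxes[j]
                if bb[2] < cfg.min_box or bb[3] < cfg.min_box:
                    continue
                dets.append(DetectionResult(
                    category=c, score=float(sc[bi]),
                    box=OrientedBox(*bb).canonical()))
        return rotated_nms(dets, cfg.nms_thr)

    # -- training ----------------------------------------------------------
    def _rpn_targets(self, anchors: np.ndarray, gt_hboxes: np.ndarray):
        iou = horizontal_iou_matrix(anchors, gt_hboxes)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        labels = np.full(len(anchors), -1, dtype=int)
        labels[best_iou < self.cfg.rpn_neg_thr] = 0
        labels[best_iou >= self.cfg.rpn_pos_thr] = 1
        # force the best anchor for each ground truth positive
        labels[iou.argmax(axis=0)] = 1
        return labels, best_gt

    def train_step(self, image: np.ndarray, gt_obbs: list[OrientedBox],
                   gt_labels: list[int], rng: np.random.Generator
                   ) -> tuple[Tensor, dict]:
        """One forward/backward-ready joint loss for a single scene."""
        cfg = self.cfg
        pyramid = self.build_pyramid(image)
        anchors = generate_anchors(pyramid, cfg.anchor_base_scale,
                                   cfg.anchor_ratios)
        gt_arr = np.array([[b.xc, b.yc, b.wr, b.hr, b.theta] for b in gt_obbs])
        gt_h = np.array([[hb.xc, hb.yc, hb.wh, hb.hh]
                         for hb in (b.axis_aligned() for b in gt_obbs)])
        gt_lab = np.asarray(gt_labels, dtype=int)

        # --- RPN loss
        logits, deltas = self.rpn_forward(pyramid)
        logits_t = nn.concat(logits, axis=0)
        deltas_t = nn.concat(deltas, axis=0)
        labels, best_gt = self._rpn_targets(anchors.all, gt_h)
        sample = sample_rois(labels, "hroi", rng, cfg.stage_batch,
                             cfg.stage_pos_frac)
        rpn_cls = F.bce_with_logits(logits_t[sample],
                                    (labels[sample] == 1).astype(np.float32))
        pos = sample[labels[sample] == 1]
        if pos.size:
            t = encode_hbox(anchors.all[pos], gt_h[best_gt[pos]])
            rpn_reg = F.smooth_l1(deltas_t[pos], t, beta=1.0 / 9.0)
        else:
            rpn_reg = Tensor(0.0)
        rpn_loss = rpn_cls + rpn_reg

        # --- proposals (detached) + jittered GT boxes to stabilise training
        hrois, _ = self.propose_hrois(anchors, logits, deltas, image.shape[:2])
        jitter = gt_h[None].repeat(4, axis=0).reshape(-1, 4).copy()
        jitter[:, :2] += rng.normal(0, 0.05, jitter[:, :2].shape) * jitter[:, 2:]
        jitter[:, 2:] *= np.exp(rng.normal(0, 0.08, jitter[:, 2:].shape))
        cand = np.concatenate([hrois, gt_h, jitter], axis=0)

        # --- RRoI learner stage: label by horizontal IoU
        iou_h = horizontal_iou_matrix(cand, gt_h)
        best = iou_h.argmax(axis=1)
        lab = np.where(iou_h.max(axis=1) >= cfg.roi_pos_thr, 1, 0)
        sel = sample_rois(lab, "rroi", rng, cfg.stage_batch, cfg.stage_pos_frac)
        cand_s = cand[sel]
        rrois, offsets = self.rroi_learner(pyramid, cand_s)
        pos_mask = lab[sel] == 1
        if pos_mask.any():
            as_obb = np.concatenate([cand_s, np.zeros((len(cand_s), 1))], axis=1)
            t = encode_offsets_array(as_obb[pos_mask], gt_arr[best[sel][pos_mask]])
            pred = offsets[np.flatnonzero(pos_mask)]
            # wrap-aware angle target: shift the target to the nearest turn
            t = t.copy()
            d = pred.data[:, 4] - t[:, 4]
            t[:, 4] = pred.data[:, 4] - _wrap_turn(d)
            learner_reg = F.smooth_l1(pred, t, beta=1.0 / 9.0)
        else:
            learner_reg = Tensor(0.0)

        # --- head stage: label by rotated IoU of decoded RRoIs
        rroi_boxes = [OrientedBox(*r) for r in rrois]
        iou_r = rotated_iou_matrix(rroi_boxes, gt_obbs)
        best_r = iou_r.argmax(axis=1)
        lab_r = np.where(iou_r.max(axis=1) >= cfg.roi_pos_thr, 1, 0)
        sel_r = sample_rois(lab_r, "obb", rng, cfg.stage_batch,
                            cfg.stage_pos_frac)
        rrois_s = rrois[sel_r]
        patches = self.rroi_warp(pyramid, rrois_s)
        cls_logits, reg = self.head_forward(patches)
        cls_targets = np.where(lab_r[sel_r] == 1,
                               gt_lab[best_r[sel_r]], cfg.num_classes)
        head_cls = F.softmax_cross_entropy(cls_logits, cls_targets)
        posr = np.flatnonzero(lab_r[sel_r] == 1)
        if posr.size:
            gt_match = gt_arr[best_r[sel_r][posr]]
            t = encode_offsets_array(rrois_s[posr], gt_match)
            k = cfg.num_classes + 1
            reg_rows = reg.reshape(len(sel_r), k, 5)[
                posr, gt_lab[best_r[sel_r][posr]]]
            t = t.copy()
            d = reg_rows.data[:, 4] - t[:, 4]
            t[:, 4] = reg_rows.data[:, 4] - _wrap_turn(d)
            head_reg = F.smooth_l1(reg_rows, t, beta=1.0 / 9.0)
        else:
            head_reg = Tensor(0.0)

        loss = (rpn_loss + cfg.loss_alpha1 * head_cls
                + cfg.loss_alpha2 * (learner_reg + head_reg))
        parts = {"rpn_cls": float(rpn_cls.data), "rpn_reg": float(rpn_reg.data),
                 "learner_reg": float(learner_reg.data),
                 "head_cls": float(head_cls.data),
                 "head_reg": float(head_reg.data)}
        return loss, parts


def detection_loss(rpn_loss: Tensor, cls_loss: Tensor, reg_loss: Tensor,
                   alpha1: float = 1.0, alpha2: float = 1.0) -> Tensor:
    """Joint detection loss L_D = L_RPN + a1 * L_cls + a2 * L_reg."""
    return rpn_loss + alpha1 * cls_loss + alpha2 * reg_loss


def train_detector(model: RotatedDetector, scenes, iters: int,
                   lr: float = 5e-3, momentum: float = 0.9,
                   weight_decay: float = 1e-4, optimizer: str = "sgd",
                   seed: int = 0, log_every: int = 0) -> list[float]:
    """SGD (momentum 0.9, weight decay 1e-4 by default) over scene tuples.

    ``scenes``: list of (image, [OrientedBox], [label]) tuples.  Returns the
    per-iteration total-loss history.
    """
    if optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=lr, momentum=momentum,
                     weight_decay=weight_decay)
    else:
        opt = nn.Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)
    history = []
    for it in range(iters):
        img, boxes, labels = scenes[int(rng.integers(len(scenes)))]
        opt.zero_grad()
        loss, parts = model.train_step(img, boxes, labels, rng)
        loss.backward()
        opt.lr = nn.poly_decay(lr, it, iters, 0.9, lr * 0.05)
        opt.step()
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(f"detection loss diverged at iteration {it}")
        history.append(val)
        if log_every and it % log_every == 0:
            avg = float(np.mean(history[-log_every:]))
            print(f"[det] iter {it:4d} loss {avg:.4f} "
                  + " ".join(f"{k}={v:.3f}" for k, v in parts.items()))
    return history
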