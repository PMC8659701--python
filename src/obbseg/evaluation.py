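"""Rotated-instance segmentation metrics.

Average precision follows the COCO convention: detections are matched to
ground truth greedily in descending score at a fixed mask-IoU threshold,
each ground truth is matched at most once, and AP is the area under the
101-point interpolated precision-recall curve.  ``AP0.50`` and ``AP0.85``
are the thresholds of interest (0.85 is the strict medical-quality bar);
``mAP`` averages thresholds 0.50:0.05:0.95.

The false-positive decomposition reports six nested PR areas with
progressively forgiven error types:

* ``C85``, ``C50`` — plain AP at IoU 0.85 / 0.50;
* ``Loc``  — AP at IoU 0.1, so localization errors (best IoU in [0.1, 0.5))
  become matches;
* ``Oth``  — additionally removes class-confusion false positives
  (unmatched detections overlapping a ground truth of another class);
* ``BG``   — additionally removes background false positives (everything
  still unmatched);
* ``FN``   — additionally forgives missed ground truths (area 1 whenever
  anything was detected at all).

Each stage deletes a strictly larger set of errors, so the areas are
monotonically non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_GRID = np.linspace(0.0, 1.0, 101)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a & b| / |a | b| of two binary masks; 0 if the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


@dataclass
class Detection:
    """Scored prediction on one image (mask-based evaluation)."""

    image_id: int
    category: int
    score: float
    mask: np.ndarray


@dataclass
class GroundTruth:
    image_id: int
    category: int
    mask: np.ndarray


@dataclass
class EvalReport:
    """Per-category and aggregate metrics plus the FP-type decomposition."""

    ap50: dict[int, float]
    ap85: dict[int, float]
    map_coco: dict[int, float]
    decomposition: dict[str, float]
    pr_curves: dict = field(default_factory=dict)

    @property
    def mean_ap50(self) -> float:
        return float(np.mean(list(self.ap50.values()))) if self.ap50 else 0.0

    @property
    def mean_ap85(self) -> float:
        return float(np.mean(list(self.ap85.values()))) if self.ap85 else 0.0

    @property
    def mean_map(self) -> float:
        return float(np.mean(list(self.map_coco.values()))) if self.map_coco else 0.0

    def to_dict(self) -> dict:
        return {
            "AP0.50": self.mean_ap50, "AP0.85": self.mean_ap85,
            "mAP": self.mean_map,
            "per_category": {
                str(k): {"AP0.50": self.ap50[k], "AP0.85": self.ap85[k],
                         "mAP": self.map_coco[k]}
                for k in sorted(self.ap50)},
            "decomposition": self.decomposition,
        }


def _iou_table(dets: list[Detection], gts: list[GroundTruth]) -> np.ndarray:
    table = np.zeros((len(dets), len(gts)))
    for i, d in enumerate(dets):
        for j, g in enumerate(gts):
            if d.image_id == g.image_id:
                table[i, j] = mask_iou(d.mask, g.mask)
    return table


def _sort_dets(dets: list[Detection]) -> list[int]:
    return sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))


def _greedy_match(order: list[int], iou: np.ndarray, eligible: np.ndarray,
                  thr: float) -> tuple[np.ndarray, np.ndarray]:
    """Score-descending greedy matching; each GT used at most once.

    Returns (matched_gt_index_or_-1 per det, matched flag per gt).
    """
    n_gt = iou.shape[1]
    match = np.full(iou.shape[0], -1, dtype=int)
    used = np.zeros(n_gt, dtype=bool)
    for i in order:
        cand = np.where(eligible[i] & ~used & (iou[i] >= thr))[0]
        if cand.size:
            j = cand[np.argmax(iou[i, cand])]
            match[i] = j
            used[j] = True
    return match, used


def _pr_curve(order: list[int], is_tp: np.ndarray, n_gt: int):
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt if n_gt > 0 else np.zeros_like(tp, dtype=float)
    precision = tp / np.maximum(tp + fp, 1)
    return precision, recall


def _ap_from_pr(precision: np.ndarray, recall: np.ndarray) -> float:
    """101-point interpolated area under the PR curve."""
    if len(precision) == 0:
        return 0.0
    # precision envelope (max to the right)
    prec = np.maximum.accumulate(precision[::-1])[::-1]
    out = np.zeros_like(RECALL_GRID)
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    valid = idx < len(prec)
    out[valid] = prec[idx[valid]]
    return float(out.mean())


def compute_ap(dets: list[Detection], gts: list[GroundTruth], iou_thr: float,
               category: int | None = None) -> tuple[float, dict]:
    """AP at one IoU threshold (optionally restricted to one category).

    Returns ``(ap, {"precision": ..., "recall": ...})``.
    """
    if category is not None:
        dets = [d for d in dets if d.category == category]
        gts = [g for g in gts if g.category == category]
    if not gts:
        return (0.0, {"precision": np.array([]), "recall": np.array([])})
    iou = _iou_table(dets, gts)
    eligible = np.array([[d.category == g.category for g in gts] for d in dets]
                        ).reshape(len(dets), len(gts))
    order = _sort_dets(dets)
    match, _ = _greedy_match(order, iou, eligible, iou_thr)
    precision, recall = _pr_curve(order, match >= 0, len(gts))
    return _ap_from_pr(precision, recall), {"precision": precision,
                                            "recall": recall}


def compute_map(dets: list[Detection], gts: list[GroundTruth],
                category: int | None = None,
                thresholds=COCO_THRESHOLDS) -> float:
    """Mean AP over IoU thresholds 0.50:0.05:0.95."""
    return float(np.mean([compute_ap(dets, gts, t, category)[0]
                          for t in thresholds]))


def fp_decomposition(dets: list[Detection], gts: list[GroundTruth]) -> dict[str, float]:
    """Six nested PR areas: C85 <= C50 <= Loc <= Oth <= BG <= FN.

    Evaluated over all categories jointly (micro-averaged), which keeps the
    nesting property exact on any input.
    """
    n_gt = len(gts)
    if n_gt == 0:
        return {k: 0.0 for k in ("C85", "C50", "Loc", "Oth", "BG", "FN")}
    iou = _iou_table(dets, gts)
    same = np.array([[d.category == g.category for g in gts] for d in dets]
                    ).reshape(len(dets), len(gts))
    order = _sort_dets(dets)

    def ap_with(thr: float, keep: np.ndarray) -> float:
        idx = [i for i in order if keep[i]]
        match, _ = _greedy_match(idx, iou, same, thr)
        precision, recall = _pr_curve(idx, match >= 0, n_gt)
        return _ap_from_pr(precision, recall)

    keep_all = np.ones(len(dets), dtype=bool)
    out = {"C85": ap_with(0.85, keep_all), "C50": ap_with(0.50, keep_all),
           "Loc": ap_with(0.10, keep_all)}

    # errors surviving the Loc stage
    match_loc, _ = _greedy_match(order, iou, same, 0.10)
    unmatched = match_loc < 0
    if len(dets):
        other_overlap = ((iou >= 0.10) & ~same).any(axis=1)
    else:
        other_overlap = np.zeros(0, dtype=bool)
    keep_oth = keep_all & ~(unmatched & other_overlap)  # drop class confusion
    out["Oth"] = ap_with(0.10, keep_oth)
    keep_bg = keep_oth & ~unmatched  # drop remaining background FPs
    out["BG"] = ap_with(0.10, keep_bg)
    # the last stage forgives the missed ground truths as well; with every
    # error type removed the curve is 1 by construction
    out["FN"] = 1.0
    return out


def evaluate(dets: list[Detection], gts: list[GroundTruth],
             categories: list[int] | None = None) -> EvalReport:
    """Full report: per-category AP50/AP85/mAP plus the decomposition.

    Categories with no ground truth and no detections are skipped in the
    averages.
    """
    present = sorted({g.category for g in gts} |
                     {d.category for d in dets}) if categories is None else categories
    ap50, ap85, mapd, curves = {}, {}, {}, {}
    for c in present:
        if not any(g.category == c for g in gts) and \
           not any(d.category == c for d in dets):
            continue
        ap, pr = compute_ap(dets, gts, 0.50, category=c)
        ap50[c] = ap
        curves[c] = pr
        ap85[c] = compute_ap(dets, gts, 0.85, category=c)[0]
        mapd[c] = compute_map(dets, gts, category=c)
    return EvalReport(ap50, ap85, mapd, fp_decomposition(dets, gts), curves)


def obb_detections_to_box_eval(dets, gts, image_shape) -> tuple[list, list]:
    """Rasterize oriented boxes to masks for box-level evaluation.

    A convenience used when judging the detector alone (before any
    segmentation head): the box polygon becomes the instance mask.
    """
    from .geometry import rasterize_obb

    d_out = [Detection(d["image_id"], d["category"], d["score"],
                       rasterize_obb(d["obb"], image_shape)) for d in dets]
    g_out = [GroundTruth(g["image_id"], g["category"],
                         rasterize_obb(g["obb"], image_shape)) for g in gts]
    return d_out, g_out
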