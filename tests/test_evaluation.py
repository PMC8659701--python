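"""Mask-AP evaluator vs a brute-force oracle, plus decomposition properties."""

import itertools

import numpy as np
import pytest

from obbseg import evaluation as E


def sq_mask(x0, y0, w, h, shape=(20, 20)):
    m = np.zeros(shape, dtype=bool)
    m[y0:y0 + h, x0:x0 + w] = True
    return m


def det(mask, score, cat=0, img=0):
    return E.Detection(img, cat, score, mask)


def gt(mask, cat=0, img=0):
    return E.GroundTruth(img, cat, mask)


def brute_force_ap(dets, gts, thr):
    """Independent AP oracle: explicit loop matching + trapezoid-free
    101-point interpolation computed from first principles."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    used = set()
    tps = []
    for i in order:
        best_j, best_iou = None, thr
        for j, g in enumerate(gts):
            if j in used or g.category != dets[i].category \
               or g.image_id != dets[i].image_id:
                continue
            iou = E.mask_iou(dets[i].mask, g.mask)
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            used.add(best_j)
            tps.append(True)
        else:
            tps.append(False)
    precisions, recalls = [], []
    tp = fp = 0
    for is_tp in tps:
        tp += is_tp
        fp += not is_tp
        precisions.append(tp / (tp + fp))
        recalls.append(tp / len(gts))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        p_at = [p for p, rr in zip(precisions, recalls) if rr >= r]
        total += max(p_at) if p_at else 0.0
    return total / 101


# -- mask IoU ---------------------------------------------------------------

def test_mask_iou_cases():
    a = sq_mask(0, 0, 4, 4)
    assert E.mask_iou(a, a) == 1.0
    assert E.mask_iou(a, sq_mask(10, 10, 4, 4)) == 0.0
    # half-overlapping equal-area rectangles: |inter| = A/2, |union| = 3A/2
    b = sq_mask(2, 0, 4, 4)
    assert E.mask_iou(a, b) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        E.mask_iou(a, np.zeros((5, 5), dtype=bool))
    assert E.mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0


# -- AP ---------------------------------------------------------------------

def test_ap_analytic_cases():
    g = [gt(sq_mask(0, 0, 10, 10))]
    d_perfect = [det(sq_mask(0, 0, 10, 10), 0.9)]
    assert E.compute_ap(d_perfect, g, 0.50)[0] == 1.0
    assert E.compute_ap(d_perfect, g, 0.85)[0] == 1.0
    # exact IoU 0.6: a 10x6 mask inside the 10x10 GT (60/100)
    d_06 = [det(sq_mask(0, 2, 10, 6), 0.9)]
    assert E.mask_iou(d_06[0].mask, g[0].mask) == pytest.approx(0.6)
    assert E.compute_ap(d_06, g, 0.50)[0] == 1.0
    assert E.compute_ap(d_06, g, 0.85)[0] == 0.0


def test_duplicate_detection_ordering_matters():
    g = [gt(sq_mask(0, 0, 10, 10))]
    m = sq_mask(0, 0, 10, 10)
    dup_good = [det(m, 0.9), det(m, 0.8)]
    assert E.compute_ap(dup_good, g, 0.5)[0] == 1.0
    dup_bad = [det(sq_mask(10, 10, 5, 5), 0.9), det(m, 0.8)]
    assert E.compute_ap(dup_bad, g, 0.5)[0] < 1.0


def test_compute_ap_matches_brute_force_exhaustively():
    """All score orderings of up to 6 detections against up to 4 GTs."""
    rng = np.random.default_rng(42)
    shapes = [(rng.integers(0, 10), rng.integers(0, 10),
               rng.integers(2, 8), rng.integers(2, 8)) for _ in range(6)]
    gts = [gt(sq_mask(*s), cat=int(i % 2)) for i, s in enumerate(
        [(0, 0, 6, 6), (8, 8, 6, 6), (0, 10, 5, 5), (12, 2, 5, 5)])]
    masks = [sq_mask(*s) for s in shapes]
    cats = [int(rng.integers(0, 2)) for _ in masks]
    for perm in itertools.permutations(range(4), 4):
        scores = [0.9 - 0.1 * p for p in perm] + [0.45, 0.35]
        dets = [det(m, s, cat=c) for m, s, c in zip(masks, scores, cats)]
        for thr in (0.1, 0.5, 0.85):
            ours = E.compute_ap(dets, gts, thr)[0]
            ref = brute_force_ap(dets, gts, thr)
            assert ours == pytest.approx(ref, abs=1e-9), (perm, thr)


def test_order_invariance():
    rng = np.random.default_rng(3)
    gts = [gt(sq_mask(0, 0, 8, 8)), gt(sq_mask(10, 10, 6, 6), cat=1)]
    dets = [det(sq_mask(0, 0, 8, 8), 0.7), det(sq_mask(9, 9, 7, 7), 0.6, cat=1),
            det(sq_mask(3, 3, 8, 8), 0.5)]
    base = E.compute_ap(dets, gts, 0.5)[0]
    for _ in range(5):
        perm = rng.permutation(len(dets))
        assert E.compute_ap([dets[i] for i in perm], gts, 0.5)[0] == base


def test_map_threshold_counting():
    g = [gt(sq_mask(0, 0, 10, 10))]
    d_06 = [det(sq_mask(0, 2, 10, 6), 0.9)]  # IoU 0.6 exactly
    assert E.compute_map(d_06, g) == pytest.approx(3 / 10)
    d_perfect = [det(sq_mask(0, 0, 10, 10), 0.9)]
    assert E.compute_map(d_perfect, g) == 1.0
    assert E.compute_map([], g) == 0.0


# -- decomposition ----------------------------------------------------------

def test_decomposition_perfect_detections_all_one():
    gts = [gt(sq_mask(0, 0, 8, 8)), gt(sq_mask(10, 10, 6, 6), cat=1)]
    dets = [det(g_.mask, 0.9 - 0.1 * i, cat=g_.category)
            for i, g_ in enumerate(gts)]
    dec = E.fp_decomposition(dets, gts)
    assert all(v == pytest.approx(1.0) for v in dec.values())


def test_decomposition_localization_error_recovered_at_loc():
    g = [gt(sq_mask(0, 0, 10, 10))]
    # IoU ~0.3: overlap 40 of union ~130
    d = [det(sq_mask(0, 6, 10, 10), 0.9)]
    iou = E.mask_iou(d[0].mask, g[0].mask)
    assert 0.1 <= iou < 0.5
    dec = E.fp_decomposition(d, g)
    assert dec["C50"] == 0.0
    assert dec["Loc"] == pytest.approx(1.0)


def test_decomposition_class_confusion_recovered_at_oth():
    g = [gt(sq_mask(0, 0, 10, 10), cat=0)]
    wrong_class = [det(sq_mask(0, 0, 10, 10), 0.9, cat=1)]
    dec = E.fp_decomposition(wrong_class, g)
    assert dec["Loc"] == 0.0
    # removing the confused FP empties the list; recall stays 0 until FN
    assert dec["Oth"] == dec["BG"] == 0.0
    assert dec["FN"] == 1.0
    # a confusion alongside a real match raises precision once removed
    g2 = [gt(sq_mask(0, 0, 10, 10), cat=0), gt(sq_mask(12, 12, 6, 6), cat=1)]
    d2 = [det(sq_mask(12, 12, 6, 6), 0.95, cat=0),  # wrong class
          det(sq_mask(0, 0, 10, 10), 0.90, cat=0)]
    dec2 = E.fp_decomposition(d2, g2)
    assert dec2["Oth"] > dec2["Loc"]


def test_decomposition_monotone_on_random_inputs():
    rng = np.random.default_rng(11)
    names = ("C85", "C50", "Loc", "Oth", "BG", "FN")
    for trial in range(20):
        gts = [gt(sq_mask(rng.integers(0, 12), rng.integers(0, 12),
                          rng.integers(3, 8), rng.integers(3, 8)),
                  cat=int(rng.integers(0, 3))) for _ in range(rng.integers(1, 5))]
        dets = [det(sq_mask(rng.integers(0, 12), rng.integers(0, 12),
                            rng.integers(3, 8), rng.integers(3, 8)),
                    float(rng.random()), cat=int(rng.integers(0, 3)))
                for _ in range(rng.integers(0, 7))]
        dec = E.fp_decomposition(dets, gts)
        vals = [dec[k] for k in names]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:])), (trial, dec)
        assert all(0.0 <= v <= 1.0 for v in vals)


def test_evaluate_report_shape_and_skipping():
    gts = [gt(sq_mask(0, 0, 8, 8), cat=0)]
    dets = [det(sq_mask(0, 0, 8, 8), 0.9, cat=0)]
    rep = E.evaluate(dets, gts)
    assert rep.mean_ap50 == 1.0 and rep.mean_ap85 == 1.0
    assert set(rep.ap50) == {0}  # absent categories skipped
    d = rep.to_dict()
    assert d["decomposition"]["FN"] == 1.0
    empty = E.evaluate([], gts)
    assert empty.mean_ap50 == 0.0
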