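"""Rotated-box geometry: offset coding, warping, polygons, rotated IoU and NMS.

A rotated box (OBB / RRoI) is the 5-tuple ``(xc, yc, wr, hr, theta)`` in image
coordinates (x rightward, y downward, 0-based pixel centers), with ``theta``
in radians.  Horizontal boxes are the axis-aligned special case ``(xc, yc,
wh, hh)``.  Regression offsets between two rotated boxes are the 5-tuple
``(tx, ty, tw, th, ttheta)`` where the translation is expressed in the frame
of the reference box, the sizes as log-ratios, and the angle as a *turn
fraction*: the angle difference reduced mod 2*pi and divided by 2*pi, so
``ttheta`` always lies in [0, 1).

The straightening warp used to extract a rotated region applies the matrix

    [[ sin(theta),  cos(theta)],
     [-cos(theta),  sin(theta)]]

to centered coordinates and shifts by (wr/2, hr/2).  This matrix is a rotation
by (theta - 90 deg): it is the identity at theta = pi/2.  A conventional
rotation-by-(-theta) variant is available via ``convention="standard"``.

To keep the package self-consistent with that matrix, the ``wr`` side of an
oriented box runs along the image direction ``(sin theta, cos theta)`` and
``hr`` along ``(-cos theta, sin theta)``: at theta = pi/2 the box is
axis-aligned with ``wr`` horizontal, and the straightening warp maps the box
corners onto the corners of [0, wr] x [0, hr] at every angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

TWO_PI = 2.0 * math.pi


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive width or height."""


@dataclass(frozen=True)
class HorizontalBox:
    """Axis-aligned box: center (xc, yc), width wh, height hh (pixels)."""

    xc: float
    yc: float
    wh: float
    hh: float

    def __post_init__(self) -> None:
        if not (self.wh > 0 and self.hh > 0):
            raise InvalidBoxError(f"non-positive box size ({self.wh}, {self.hh})")

    @property
    def x0(self) -> float:
        return self.xc - self.wh / 2.0

    @property
    def y0(self) -> float:
        return self.yc - self.hh / 2.0

    @property
    def x1(self) -> float:
        return self.xc + self.wh / 2.0

    @property
    def y1(self) -> float:
        return self.yc + self.hh / 2.0

    @property
    def area(self) -> float:
        return self.wh * self.hh

    def to_oriented(self) -> "OrientedBox":
        """View as a rotated box at angle zero."""
        return OrientedBox(self.xc, self.yc, self.wh, self.hh, 0.0)


@dataclass(frozen=True)
class OrientedBox:
    """Rotated rectangle: center, side lengths and angle in radians.

    The ``wr`` side runs along direction ``(sin theta, cos theta)``, the
    ``hr`` side along the perpendicular ``(-cos theta, sin theta)``; the box
    is axis-aligned (wr horizontal) at theta = pi/2.
    """

    xc: float
    yc: float
    wr: float
    hr: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.wr > 0 and self.hr > 0):
            raise InvalidBoxError(f"non-positive box size ({self.wr}, {self.hr})")

    @property
    def area(self) -> float:
        return self.wr * self.hr

    def canonical(self) -> "OrientedBox":
        """Reduce the angle mod pi into [-pi/2, pi/2) without swapping sides.

        A rectangle is invariant under theta -> theta + pi, so this loses
        nothing; the remaining (wr, hr, theta) <-> (hr, wr, theta +- pi/2)
        ambiguity is left to consumers that compare boxes up to symmetry.
        """
        t = (self.theta + math.pi / 2.0) % math.pi - math.pi / 2.0
        return OrientedBox(self.xc, self.yc, self.wr, self.hr, t)

    def axis_aligned(self) -> HorizontalBox:
        """Smallest horizontal box containing this rotated box."""
        xs, ys = obb_corners(self)
        w = float(xs.max() - xs.min())
        h = float(ys.max() - ys.min())
        return HorizontalBox(float(xs.mean()), float(ys.mean()), w, h)


@dataclass(frozen=True)
class BoxOffsets:
    """Regression targets between a reference rotated box and a target box."""

    tx: float
    ty: float
    tw: float
    th: float
    ttheta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tw, self.th, self.ttheta])


@dataclass(frozen=True)
class Polygon:
    """Simple polygon as an (N, 2) float array of (x, y) vertices, CCW."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (N>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def to_shapely(self) -> _ShPolygon:
        return _ShPolygon(self.vertices)


# ---------------------------------------------------------------------------
# offset coding
# ---------------------------------------------------------------------------

def encode_offsets(rroi: OrientedBox, gt: OrientedBox) -> BoxOffsets:
    """Regression targets of ``gt`` relative to the reference ``rroi``.

    The center shift is projected onto the reference box's axes and divided
    by its side lengths; sizes are log-ratios; the angle difference is
    reduced mod 2*pi and expressed as a fraction of a full turn.
    """
    ct, st = math.cos(rroi.theta), math.sin(rroi.theta)
    dx, dy = gt.xc - rroi.xc, gt.yc - rroi.yc
    tx = (dx * ct + dy * st) / rroi.wr
    ty = (dy * ct - dx * st) / rroi.hr
    tw = math.log(gt.wr / rroi.wr)
    th = math.log(gt.hr / rroi.hr)
    ttheta = ((gt.theta - rroi.theta) % TWO_PI) / TWO_PI
    return BoxOffsets(tx, ty, tw, th, ttheta)


def decode_offsets(rroi: OrientedBox, off: BoxOffsets) -> OrientedBox:
    """Inverse of :func:`encode_offsets` (angle recovered mod 2*pi)."""
    ct, st = math.cos(rroi.theta), math.sin(rroi.theta)
    a = off.tx * rroi.wr
    b = off.ty * rroi.hr
    xc = rroi.xc + a * ct - b * st
    yc = rroi.yc + a * st + b * ct
    wr = rroi.wr * math.exp(off.tw)
    hr = rroi.hr * math.exp(off.th)
    theta = rroi.theta + off.ttheta * TWO_PI
    return OrientedBox(xc, yc, wr, hr, theta)


def encode_offsets_array(rrois: np.ndarray, gts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_offsets` on (N, 5) arrays of box parameters."""
    rrois = np.asarray(rrois, dtype=float)
    gts = np.asarray(gts, dtype=float)
    ct, st = np.cos(rrois[:, 4]), np.sin(rrois[:, 4])
    dx = gts[:, 0] - rrois[:, 0]
    dy = gts[:, 1] - rrois[:, 1]
    tx = (dx * ct + dy * st) / rrois[:, 2]
    ty = (dy * ct - dx * st) / rrois[:, 3]
    tw = np.log(gts[:, 2] / rrois[:, 2])
    th = np.log(gts[:, 3] / rrois[:, 3])
    tt = ((gts[:, 4] - rrois[:, 4]) % TWO_PI) / TWO_PI
    return np.stack([tx, ty, tw, th, tt], axis=1)


def decode_offsets_array(rrois: np.ndarray, offs: np.ndarray) -> np.ndarray:
    """Vectorized :func:`decode_offsets` on (N, 5) arrays."""
    rrois = np.asarray(rrois, dtype=float)
    offs = np.asarray(offs, dtype=float)
    ct, st = np.cos(rrois[:, 4]), np.sin(rrois[:, 4])
    a = offs[:, 0] * rrois[:, 2]
    b = offs[:, 1] * rrois[:, 3]
    xc = rrois[:, 0] + a * ct - b * st
    yc = rrois[:, 1] + a * st + b * ct
    wr = rrois[:, 2] * np.exp(np.clip(offs[:, 2], -8.0, 8.0))
    hr = rrois[:, 3] * np.exp(np.clip(offs[:, 3], -8.0, 8.0))
    theta = rrois[:, 4] + offs[:, 4] * TWO_PI
    return np.stack([xc, yc, wr, hr, theta], axis=1)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_matrix(theta: float, convention: str = "printed") -> np.ndarray:
    """Straightening matrix for a rotated region.

    ``"printed"`` is [[sin, cos], [-cos, sin]] (identity at theta = pi/2);
    ``"standard"`` is the usual rotation by -theta (identity at theta = 0).
    """
    ct, st = math.cos(theta), math.sin(theta)
    if convention == "printed":
        return np.array([[st, ct], [-ct, st]])
    if convention == "standard":
        return np.array([[ct, st], [-st, ct]])
    raise ValueError(f"unknown warp convention {convention!r}")


def warp_point(p: Sequence[float], rroi: OrientedBox,
               convention: str = "printed") -> tuple[float, float]:
    """Map an image point into the straightened frame of ``rroi``.

    The box center maps to (wr/2, hr/2) for every angle.
    """
    m = warp_matrix(rroi.theta, convention)
    d = np.array([p[0] - rroi.xc, p[1] - rroi.yc])
    out = m @ d + np.array([rroi.wr / 2.0, rroi.hr / 2.0])
    return float(out[0]), float(out[1])


def unwarp_points(uv: np.ndarray, rroi: OrientedBox,
                  convention: str = "printed") -> np.ndarray:
    """Inverse warp: straightened-frame (u, v) -> image (x, y), vectorized.

    The warp matrix is orthonormal, so the inverse is its transpose.
    """
    m = warp_matrix(rroi.theta, convention)
    uv = np.asarray(uv, dtype=float) - np.array([rroi.wr / 2.0, rroi.hr / 2.0])
    xy = uv @ m  # (M^T @ uv^T)^T == uv @ M
    xy[:, 0] += rroi.xc
    xy[:, 1] += rroi.yc
    return xy


# ---------------------------------------------------------------------------
# polygons, IoU, NMS
# ---------------------------------------------------------------------------

def obb_corners(b: OrientedBox) -> tuple[np.ndarray, np.ndarray]:
    """Corner coordinates (xs, ys), each shape (4,)."""
    ct, st = math.cos(b.theta), math.sin(b.theta)
    ux, uy = st * b.wr / 2.0, ct * b.wr / 2.0
    vx, vy = -ct * b.hr / 2.0, st * b.hr / 2.0
    xs = b.xc + np.array([ux + vx, -ux + vx, -ux - vx, ux - vx])
    ys = b.yc + np.array([uy + vy, -uy + vy, -uy - vy, uy - vy])
    return xs, ys


def obb_to_polygon(b: OrientedBox) -> Polygon:
    """Four-corner polygon of a rotated box, counter-clockwise."""
    xs, ys = obb_corners(b)
    verts = np.stack([xs, ys], axis=1)
    x, y = verts[:, 0], verts[:, 1]
    shoelace = float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if shoelace < 0:
        verts = verts[::-1]
    return Polygon(verts)


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Intersection-over-union of two rotated boxes via polygon clipping.

    Symmetric, in [0, 1]; zero-area (edge-touching) intersections count as 0.
    """
    if a == b:
        return 1.0
    pa = obb_to_polygon(a).to_shapely()
    pb = obb_to_polygon(b).to_shapely()
    inter = pa.intersection(pb).area
    if inter <= 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return float(min(inter / union, 1.0))


def rotated_iou_matrix(boxes_a: Sequence[OrientedBox],
                       boxes_b: Sequence[OrientedBox]) -> np.ndarray:
    """Pairwise rotated IoU, shape (len(a), len(b))."""
    polys_a = [obb_to_polygon(x).to_shapely() for x in boxes_a]
    polys_b = [obb_to_polygon(x).to_shapely() for x in boxes_b]
    out = np.zeros((len(polys_a), len(polys_b)))
    for i, pa in enumerate(polys_a):
        for j, pb in enumerate(polys_b):
            inter = pa.intersection(pb).area
            if inter > 0:
                out[i, j] = inter / (pa.area + pb.area - inter)
    return out


def horizontal_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of axis-aligned boxes given as (N, 4) [xc, yc, w, h]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ax0, ay0 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax1, ay1 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx0, by0 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx1, by1 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax1[:, None], bx1[None]) - np.maximum(ax0[:, None], bx0[None]), 0, None)
    ih = np.clip(np.minimum(ay1[:, None], by1[None]) - np.maximum(ay0[:, None], by0[None]), 0, None)
    inter = iw * ih
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = (b[:, 2] * b[:, 3])[None]
    union = area_a + area_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


@dataclass(frozen=True)
class DetectionResult:
    """One detection: category index, confidence score and rotated box."""

    category: int
    score: float
    box: OrientedBox


def rotated_nms(dets: Sequence[DetectionResult], iou_thr: float) -> list[DetectionResult]:
    """Greedy rotated non-maximum suppression.

    Detections are visited in descending score (ties broken by input index);
    a detection is suppressed if its rotated IoU with an already kept,
    same-category detection exceeds ``iou_thr``.  Output is score-sorted.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept: list[int] = []
    polys = {}
    for i in order:
        di = dets[i]
        if i not in polys:
            polys[i] = obb_to_polygon(di.box).to_shapely()
        ok = True
        for j in kept:
            if dets[j].category != di.category:
                continue
            inter = polys[i].intersection(polys[j]).area
            if inter > 0:
                iou = inter / (polys[i].area + polys[j].area - inter)
                if iou > iou_thr:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return [dets[i] for i in kept]


def min_area_rect(points: np.ndarray) -> OrientedBox:
    """Minimum-area rotated rectangle of a point set, as an OrientedBox.

    Angle is canonicalized to [-pi/2, pi/2).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        # degenerate: pad with a tiny box around the points
        xc, yc = pts[:, 0].mean(), pts[:, 1].mean()
        return OrientedBox(float(xc), float(yc), 1e-3, 1e-3, 0.0)
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except QhullError:
        hull_pts = pts
    from shapely.geometry import MultiPoint

    rect = MultiPoint([tuple(p) for p in hull_pts]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear points
        xc, yc = pts[:, 0].mean(), pts[:, 1].mean()
        return OrientedBox(float(xc), float(yc), 1e-3, 1e-3, 0.0)
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    # wr runs along (sin theta, cos theta)
    theta = math.atan2(e1[0], e1[1])
    xc, yc = corners.mean(axis=0)
    return OrientedBox(float(xc), float(yc), max(w, 1e-3), max(h, 1e-3), theta).canonical()


def mask_to_obb(mask: np.ndarray) -> OrientedBox:
    """Minimum-area rotated rectangle of a binary mask's pixel centers."""
    ys, xs = np.nonzero(np.asarray(mask))
    if len(xs) == 0:
        raise ValueError("empty mask has no bounding box")
    pts = np.stack([xs, ys], axis=1).astype(float)
    return min_area_rect(pts)


def rasterize_obb(b: OrientedBox, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the rotated box."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = math.cos(b.theta), math.sin(b.theta)
    dx = xx - b.xc
    dy = yy - b.yc
    u = dx * st + dy * ct
    v = -dx * ct + dy * st
    return (np.abs(u) <= b.wr / 2.0) & (np.abs(v) <= b.hr / 2.0)


def boxes_equivalent(a: OrientedBox, b: OrientedBox, tol_px: float = 1.0,
                     tol_deg: float = 1.0) -> bool:
    """Compare two rotated rectangles up to the 90-degree side-swap symmetry."""
    candidates = [b.canonical()]
    bc = b.canonical()
    for shift in (math.pi / 2.0, -math.pi / 2.0):
        try:
            candidates.append(OrientedBox(bc.xc, bc.yc, bc.hr, bc.wr, bc.theta + shift).canonical())
        except InvalidBoxError:  # pragma: no cover
            pass
    ac = a.canonical()
    tol_rad = math.radians(tol_deg)
    for cand in candidates:
        d_ang = abs((ac.theta - cand.theta + math.pi / 2.0) % math.pi - math.pi / 2.0)
        if (abs(ac.xc - cand.xc) <= tol_px and abs(ac.yc - cand.yc) <= tol_px
                and abs(ac.wr - cand.wr) <= tol_px and abs(ac.hr - cand.hr) <= tol_px
                and d_ang <= tol_rad):
            return True
    return False
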