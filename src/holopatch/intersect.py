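"""Exact mesh self-intersection detection.

Broad phase: axis-aligned bounding boxes of all triangles are tested
for overlap in chunks (vectorised all-pairs culling).  Pairs sharing a
vertex index are excluded — a conforming mesh touches itself along
every interior edge, which is not a fold.

Narrow phase: the surviving pairs undergo an exact triangle/triangle
intersection test (plane-side interval test for transversal pairs;
2D polygon overlap for coplanar pairs).  Grazing contact within the
floating-point threshold is not reported: a fold is a genuine crossing,
not a touch.
"""

from __future__ import annotations

import numpy as np

_EPS_REL = 1e-10


def _aabb_candidate_pairs(vertices: np.ndarray, triangles: np.ndarray, chunk: int = 512):
    """Index pairs (i < j) of triangles whose bounding boxes overlap and
    which share no vertex."""
    corners = vertices[triangles]
    lo = corners.min(axis=1)
    hi = corners.max(axis=1)
    m = len(triangles)
    pairs = []
    for start in range(0, m, chunk):
        end = min(start + chunk, m)
        # only pairs with j > i to avoid duplicates
        over = (
            (lo[start:end, None, 0] <= hi[None, :, 0])
            & (hi[start:end, None, 0] >= lo[None, :, 0])
            & (lo[start:end, None, 1] <= hi[None, :, 1])
            & (hi[start:end, None, 1] >= lo[None, :, 1])
            & (lo[start:end, None, 2] <= hi[None, :, 2])
            & (hi[start:end, None, 2] >= lo[None, :, 2])
        )
        ii, jj = np.nonzero(over)
        ii = ii + start
        keep = jj > ii
        ii, jj = ii[keep], jj[keep]
        if len(ii):
            # exclude pairs sharing any vertex index
            ti = triangles[ii]
            tj = triangles[jj]
            shared = (ti[:, :, None] == tj[:, None, :]).any(axis=(1, 2))
            ii, jj = ii[~shared], jj[~shared]
        if len(ii):
            pairs.append(np.stack([ii, jj], axis=1))
    if not pairs:
        return np.zeros((0, 2), dtype=np.int64)
    return np.concatenate(pairs)


def _interval_on_line(tri, d, proj, eps):
    """Intersection interval of a triangle with the plane of the other,
    projected on the common line.  ``d``: signed distances of the three
    vertices to the other plane (mixed signs); ``proj``: projections of
    the vertices on the line direction."""
    # identify the vertex alone on its side
    pos = d > eps
    neg = d < -eps
    zero = ~(pos | neg)
    if zero.all():
        return None  # coplanar, handled elsewhere
    if zero.sum() == 2:
        # an edge lies in the plane: touching, not crossing
        return None
    if zero.sum() == 1:
        kz = int(np.nonzero(zero)[0][0])
        others = [k for k in range(3) if k != kz]
        if (d[others[0]] > 0) == (d[others[1]] > 0):
            # plane only touched at a vertex
            return None
        k0 = kz
    else:
        if pos.sum() == 1:
            k0 = int(np.nonzero(pos)[0][0])
        else:
            k0 = int(np.nonzero(neg)[0][0])
    k1, k2 = [k for k in range(3) if k != k0]
    t1 = proj[k0] + (proj[k1] - proj[k0]) * d[k0] / (d[k0] - d[k1]) if d[k0] != d[k1] else proj[k0]
    t2 = proj[k0] + (proj[k2] - proj[k0]) * d[k0] / (d[k0] - d[k2]) if d[k0] != d[k2] else proj[k0]
    return (t1, t2) if t1 <= t2 else (t2, t1)


def _coplanar_overlap(t1: np.ndarray, t2: np.ndarray, n: np.ndarray, eps: float) -> bool:
    """2D area-overlap test for coplanar triangles (projected on the
    dominant axis of the shared normal)."""
    from shapely.geometry import Polygon

    axis = int(np.argmax(np.abs(n)))
    cols = [c for c in range(3) if c != axis]
    p1 = Polygon(t1[:, cols])
    p2 = Polygon(t2[:, cols])
    if not (p1.is_valid and p2.is_valid):
        return False
    inter = p1.intersection(p2)
    return inter.area > max(eps, 1e-12) * max(p1.area, p2.area)


def triangles_intersect(t1: np.ndarray, t2: np.ndarray, eps: float | None = None) -> bool:
    """Exact intersection test between two triangles given as (3, 3)
    coordinate arrays (plane-interval method)."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    scale = max(np.abs(t1).max(), np.abs(t2).max(), 1.0)
    if eps is None:
        eps = _EPS_REL * scale

    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    d2 = (t2 - t1[0]) @ n1 / np.linalg.norm(n1)
    d1 = (t1 - t2[0]) @ n2 / np.linalg.norm(n2)

    if (d2 > eps).all() or (d2 < -eps).all():
        return False
    if (d1 > eps).all() or (d1 < -eps).all():
        return False

    copl1 = (np.abs(d1) <= eps).all()
    copl2 = (np.abs(d2) <= eps).all()
    if copl1 and copl2:
        return _coplanar_overlap(t1, t2, n1, eps)

    line = np.cross(n1, n2)
    ln = np.linalg.norm(line)
    if ln < eps * max(np.linalg.norm(n1), np.linalg.norm(n2)):
        # numerically parallel but not coplanar within eps: no crossing
        return _coplanar_overlap(t1, t2, n1, eps) if (copl1 or copl2) else False
    line = line / ln
    i1 = _interval_on_line(t1, d1, t1 @ line, eps)
    i2 = _interval_on_line(t2, d2, t2 @ line, eps)
    if i1 is None or i2 is None:
        return False
    lo = max(i1[0], i2[0])
    hi = min(i1[1], i2[1])
    return hi - lo > eps


def _prefilter_plane_side(corners: np.ndarray, pairs: np.ndarray, eps: float) -> np.ndarray:
    """Drop candidate pairs where one triangle lies strictly on one side of
    the other's plane (vectorised cheap rejection)."""
    for first, second in ((0, 1), (1, 0)):
        if len(pairs) == 0:
            break
        a = corners[pairs[:, first]]
        b = corners[pairs[:, second]]
        n = np.cross(a[:, 1] - a[:, 0], a[:, 2] - a[:, 0])
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
        d = np.einsum("pvj,pj->pv", b - a[:, 0][:, None, :], n)
        one_side = (d > eps).all(axis=1) | (d < -eps).all(axis=1)
        pairs = pairs[~one_side]
    return pairs


def self_intersecting_pairs(vertices: np.ndarray, triangles: np.ndarray) -> list[tuple[int, int]]:
    """All non-adjacent intersecting triangle pairs of an indexed mesh,
    as (i, j) with i < j, sorted."""
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    if len(triangles) < 2:
        return []
    pairs = _aabb_candidate_pairs(vertices, triangles)
    if len(pairs) == 0:
        return []
    corners = vertices[triangles]
    scale = max(float(np.abs(vertices).max()), 1.0)
    eps = _EPS_REL * scale
    pairs = _prefilter_plane_side(corners, pairs, eps)
    out = []
    for i, j in pairs:
        if triangles_intersect(corners[i], corners[j], eps):
            out.append((int(i), int(j)))
    out.sort()
    return out
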