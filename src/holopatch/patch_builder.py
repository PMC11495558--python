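"""From marked boundary to printable patch template.

The modelling pipeline mirrors the interactive patch-drawing workflow:

1. :func:`collect_boundary` — turn an ordered sequence of fingertip
   sphere centres into surface contact points (one collision point per
   sphere position), or :func:`anchor_boundary` for the desktop-style
   workflow of explicitly placed, adjustable anchor points;
2. :func:`interpolate_ring` — a closed periodic Catmull–Rom spline
   through the marked points, optionally conformed back onto the heart
   surface, giving the patch circumference;
3. :func:`ring_midpoint` + :func:`build_surface` — an apex is placed at
   the ring midpoint offset by a user-controlled curvature height ``h``
   along the ring normal, and the surface is swept as a fan of radial
   cubic Bézier spokes from the ring to the apex;
4. :func:`solidify` — thicken the template into a watertight printable
   shell, refusing surfaces that carry a self-intersection;
5. :func:`detect_self_intersections` — exact triangle/triangle
   intersection testing over bounding-box candidate pairs, the check
   that recognises the "double fold" marking artefact.

Bézier spoke construction.  For a boundary point ``P``, ring normal
``n`` and apex ``A = M + h*n`` (``M`` the ring midpoint), the spoke is
the cubic Bézier with control points::

    B0 = P
    B1 = P + (1/3) * T(A - P)        # leave the boundary in the wall's
    B2 = A - (1/3) * T(A - P)        # tangent plane; arrive at the apex
    B3 = A                           # tangentially (flat, rounded dome)

where ``T(v) = v - (v.n) n`` removes the normal component.  With
``h = 0`` and a planar ring every control point lies in the ring plane
and the patch degenerates to the flat disc; ``h`` is the single
curvature dial exposed to the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ArtifactError,
    BoundaryError,
    GeometryError,
    ParameterError,
)
from .mesh_core import SpatialIndex, SurfacePoint, TriangleMesh
from . import intersect

DEFAULT_N_SPOKES = 128
DEFAULT_N_RINGS = 32
DEFAULT_CONFORM_TOL = 0.5  # mm


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class MarkedBoundary:
    """Ordered loop of surface points defining a patch circumference."""

    points: list  # of SurfacePoint
    source_mode: str = "sphere_marking"  # or "anchor_points"
    dedup_tol: float = 1e-6

    def __post_init__(self):
        if len(self.points) < 3:
            raise BoundaryError(
                f"insufficient marking: need >= 3 boundary points, got {len(self.points)}"
            )

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])


@dataclass
class RingCurve:
    """Closed patch circumference: spline samples (cyclic, no duplicated
    endpoint) through the marked knots."""

    samples: np.ndarray
    knots: np.ndarray
    conformed: bool = False
    max_conform_residual: float = 0.0

    def length(self) -> float:
        d = np.diff(self.samples, axis=0, append=self.samples[:1])
        return float(np.linalg.norm(d, axis=1).sum())


@dataclass
class PatchTemplate:
    """Tessellated patch surface with its generating ring, apex and
    curvature offset."""

    surface: TriangleMesh
    ring: RingCurve
    apex: np.ndarray
    curvature_offset: float
    tessellation: tuple = (DEFAULT_N_SPOKES, DEFAULT_N_RINGS)


@dataclass
class SolidPatch:
    """Watertight printable shell of a patch template."""

    shell: TriangleMesh
    thickness: float


# ---------------------------------------------------------------------------
# boundary collection
# ---------------------------------------------------------------------------


def collect_boundary(
    mesh: TriangleMesh,
    index: SpatialIndex,
    stroke_centers: np.ndarray,
    sphere_radius: float,
    dedup_tol: float = 0.25,
) -> MarkedBoundary:
    """Collect fingertip contact points from a marking stroke.

    For each sphere centre, the triangles the sphere overlaps are found
    and the single closest contact point is kept (the fingertip touch).
    Centres whose sphere misses the mesh contribute nothing; consecutive
    near-duplicate contacts within ``dedup_tol`` collapse to one.
    """
    if sphere_radius <= 0:
        raise ParameterError("sphere_radius must be positive")
    picked: list[SurfacePoint] = []
    for center in np.asarray(stroke_centers, dtype=float):
        hits = index.sphere_collision_points(center, sphere_radius)
        if not hits:
            continue
        d = [np.linalg.norm(h.position - center) for h in hits]
        best = hits[int(np.argmin(d))]
        if picked and np.linalg.norm(best.position - picked[-1].position) <= dedup_tol:
            continue
        picked.append(best)
    if len(picked) >= 3 and np.linalg.norm(
        picked[-1].position - picked[0].position
    ) <= dedup_tol:
        picked.pop()
    if len(picked) < 3:
        raise BoundaryError(
            f"insufficient marking: only {len(picked)} contact points survive"
        )
    return MarkedBoundary(picked, source_mode="sphere_marking", dedup_tol=dedup_tol)


def anchor_boundary(
    mesh: TriangleMesh,
    index: SpatialIndex,
    anchors: np.ndarray,
    adjustments: dict[int, np.ndarray] | None = None,
) -> MarkedBoundary:
    """Desktop-style boundary from explicitly placed anchor points.

    Each anchor snaps to its closest surface point; ``adjustments`` maps
    anchor index to a replacement position, applied then re-snapped.
    Ten or more anchors are typical practice; fewer succeed with a
    warning.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 3 or len(anchors) < 3:
        raise BoundaryError("need >= 3 anchor points of shape (n, 3)")
    if len(anchors) < 10:
        warnings.warn(
            f"only {len(anchors)} anchor points; 10 or more are typical for a "
            "well-resolved boundary",
            stacklevel=2,
        )
    positions = anchors.copy()
    if adjustments:
        for i, p in adjustments.items():
            positions[i] = np.asarray(p, dtype=float)
    snapped = [index.closest_surface_point(p)[0] for p in positions]
    return MarkedBoundary(snapped, source_mode="anchor_points")


def order_ring(points: list[SurfacePoint]) -> list[SurfacePoint]:
    """Order an unordered set of boundary points into a loop.

    Greedy nearest-neighbour chaining starting from the first point,
    then orientation normalised to counter-clockwise about the best-fit
    plane normal (normal signed so its largest-magnitude component is
    positive, for determinism).  Output is a permutation of the input.
    """
    if len(points) < 3:
        raise BoundaryError("need >= 3 points to order a ring")
    pos = np.array([p.position for p in points])
    n = len(pos)
    used = np.zeros(n, dtype=bool)
    chain = [0]
    used[0] = True
    for _ in range(n - 1):
        last = pos[chain[-1]]
        d = np.linalg.norm(pos - last, axis=1)
        d[used] = np.inf
        nxt = int(np.argmin(d))
        chain.append(nxt)
        used[nxt] = True

    ordered = pos[chain]
    centered = ordered - ordered.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    # signed area about the normal: positive = CCW
    cross = np.cross(centered, np.roll(centered, -1, axis=0)).sum(axis=0)
    if float(cross @ normal) < 0:
        chain = [chain[0]] + chain[1:][::-1]
    return [points[i] for i in chain]


# ---------------------------------------------------------------------------
# ring interpolation
# ---------------------------------------------------------------------------


def _catmull_rom_closed(knots: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Evaluate a closed uniform Catmull–Rom spline through ``knots`` at
    global parameters ``params`` in [0, k)."""
    k = len(knots)
    seg = np.floor(params).astype(int) % k
    t = params - np.floor(params)
    p0 = knots[(seg - 1) % k]
    p1 = knots[seg]
    p2 = knots[(seg + 1) % k]
    p3 = knots[(seg + 2) % k]
    t = t[:, None]
    # standard Catmull-Rom basis (tension 0.5)
    return 0.5 * (
        2 * p1
        + (-p0 + p2) * t
        + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t ** 2
        + (-p0 + 3 * p1 - 3 * p2 + p3) * t ** 3
    )


def interpolate_ring(
    marked: MarkedBoundary,
    n_samples: int = 256,
    conform: bool = False,
    mesh: TriangleMesh | None = None,
    index: SpatialIndex | None = None,
    conform_tol: float = DEFAULT_CONFORM_TOL,
) -> RingCurve:
    """Closed periodic cubic spline through the marked boundary points.

    Samples are evenly spaced in spline parameter.  With ``conform``,
    each sample is replaced by its closest point on the heart surface so
    the ring lies on the anatomy; the largest residual distance moved is
    recorded (a residual above ``conform_tol`` is reported, not an
    error — the marking may genuinely bridge the defect).

    A knot sequence that doubles back on itself is not rejected here;
    the resulting pleated surface is caught downstream by
    :func:`detect_self_intersections`.
    """
    knots = marked.positions()
    k = len(knots)
    if n_samples < k:
        raise ParameterError("n_samples must be at least the number of knots")
    params = np.linspace(0.0, k, n_samples, endpoint=False)
    samples = _catmull_rom_closed(knots, params)

    max_resid = 0.0
    if conform:
        if index is None:
            if mesh is None:
                raise ParameterError("conform=True requires a mesh or index")
            index = SpatialIndex(mesh)
        conformed = np.empty_like(samples)
        for i, s in enumerate(samples):
            sp, d = index.closest_surface_point(s)
            conformed[i] = sp.position
            max_resid = max(max_resid, d)
        samples = conformed
    return RingCurve(samples, knots, conformed=conform, max_conform_residual=max_resid)


def ring_midpoint(ring: RingCurve, away_from: np.ndarray | None = None):
    """Ring midpoint and unit normal.

    Midpoint is the arithmetic mean of the samples; the normal is the
    smallest-variance principal axis of the samples.  Its sign points
    away from ``away_from`` (typically the heart-mesh centroid, i.e.
    toward the marking side); without a reference the sign is fixed so
    the largest-magnitude component is positive.
    """
    samples = ring.samples
    mid = samples.mean(axis=0)
    centered = samples - mid
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError("degenerate (collinear) ring")
    normal = vt[2]
    if away_from is not None:
        if float(normal @ (mid - np.asarray(away_from, dtype=float))) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return mid, normal


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------


def _resample_ring(ring: RingCurve, n: int) -> np.ndarray:
    if len(ring.samples) == n:
        return ring.samples
    # re-evaluate the spline when possible, else arc-length resample
    if not ring.conformed:
        params = np.linspace(0.0, len(ring.knots), n, endpoint=False)
        return _catmull_rom_closed(ring.knots, params)
    pts = ring.samples
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    want = np.linspace(0, total, n, endpoint=False)
    idx = np.clip(np.searchsorted(arc, want, side="right") - 1, 0, len(pts) - 1)
    frac = (want - arc[idx]) / np.where(seg[idx] == 0, 1.0, seg[idx])
    nxt = (idx + 1) % len(pts)
    return pts[idx] + frac[:, None] * (pts[nxt] - pts[idx])


def build_surface(
    ring: RingCurve,
    h: float = 0.0,
    n_spokes: int = DEFAULT_N_SPOKES,
    n_rings: int = DEFAULT_N_RINGS,
    normal_hint: np.ndarray | None = None,
) -> PatchTemplate:
    """Sweep the patch surface from the ring to an apex.

    The apex sits at ``midpoint + h * normal``; each boundary sample is
    joined to the apex by a cubic Bézier spoke (see module docstring)
    and the spokes are tessellated into ``n_spokes x n_rings`` quads
    split into triangles, the apex closing the centre.  The surface
    boundary reproduces the ring samples exactly.

    ``normal_hint`` disambiguates the normal's sign (e.g. the marking
    side); ``h`` is signed along the resulting normal.
    """
    if n_spokes < 3 or n_rings < 1:
        raise ParameterError("need n_spokes >= 3 and n_rings >= 1")
    mid, normal = ring_midpoint(ring)
    if normal_hint is not None and float(normal @ np.asarray(normal_hint, dtype=float)) < 0:
        normal = -normal
    boundary = _resample_ring(ring, n_spokes)
    apex = mid + h * normal

    ap = apex - boundary  # (n_spokes, 3)
    tangential = ap - (ap @ normal)[:, None] * normal[None, :]
    b0 = boundary
    b1 = boundary + tangential / 3.0
    b2 = apex - tangential / 3.0
    b3 = np.broadcast_to(apex, b0.shape)

    # vertex rows at t = 0 .. (n_rings-1)/n_rings along each spoke, then apex
    verts = [boundary]
    for j in range(1, n_rings):
        t = j / n_rings
        row = (
            (1 - t) ** 3 * b0
            + 3 * (1 - t) ** 2 * t * b1
            + 3 * (1 - t) * t ** 2 * b2
            + t ** 3 * b3
        )
        verts.append(row)
    vertices = np.concatenate(verts + [apex[None, :]])
    apex_id = len(vertices) - 1

    faces = []
    s = n_spokes
    for j in range(n_rings - 1):
        row0 = j * s
        row1 = (j + 1) * s
        for i in range(s):
            i2 = (i + 1) % s
            faces.append([row0 + i, row0 + i2, row1 + i])
            faces.append([row0 + i2, row1 + i2, row1 + i])
    last = (n_rings - 1) * s
    for i in range(s):
        i2 = (i + 1) % s
        faces.append([last + i, last + i2, apex_id])

    surface = TriangleMesh(vertices, np.array(faces, dtype=np.int64))
    ring_out = RingCurve(boundary, ring.knots, ring.conformed, ring.max_conform_residual)
    return PatchTemplate(surface, ring_out, apex, h, (n_spokes, n_rings))


# ---------------------------------------------------------------------------
# self-intersection and solidification
# ---------------------------------------------------------------------------


def detect_self_intersections(surface: TriangleMesh) -> list[tuple[int, int]]:
    """Non-adjacent triangle pairs of ``surface`` that intersect.

    Candidate pairs come from axis-aligned bounding-box overlap culling;
    candidates sharing a vertex are excluded and the survivors undergo
    an exact triangle/triangle intersection test (including the coplanar
    case).  An empty list certifies a fold-free patch.
    """
    return intersect.self_intersecting_pairs(surface.vertices, surface.triangles)


def solidify(patch: PatchTemplate, thickness: float) -> SolidPatch:
    """Thicken the template into a watertight printable shell.

    The shell is the template surface offset by ``thickness`` along
    per-vertex normals, the original surface with reversed orientation,
    and a side wall stitching the two boundary loops.  A template that
    carries a self-intersection is refused (the fold would bake an
    unprintable artefact into the shell); run
    :func:`detect_self_intersections` and re-mark the boundary instead.
    """
    if thickness <= 0:
        raise ParameterError("thickness must be positive")
    surface = patch.surface
    pairs = detect_self_intersections(surface)
    if pairs:
        raise ArtifactError(
            f"patch surface has {len(pairs)} self-intersecting triangle pairs "
            "('double fold'); re-mark the boundary",
            intersecting_pairs=pairs,
        )
    vn = surface.compute_vertex_normals()
    n = surface.n_vertices
    bottom_faces = surface.triangles[:, ::-1]  # reversed winding
    top_verts = surface.vertices + thickness * vn
    top_faces = surface.triangles + n

    n_spokes = patch.tessellation[0]
    side = []
    for i in range(n_spokes):  # boundary vertices are 0..n_spokes-1 by construction
        i2 = (i + 1) % n_spokes
        side.append([i, i2, n + i])
        side.append([i2, n + i2, n + i])
    side = np.array(side, dtype=np.int64)

    shell_vertices = np.concatenate([surface.vertices, top_verts])
    shell_faces = np.concatenate([bottom_faces, top_faces, side])
    shell = TriangleMesh(shell_vertices, shell_faces)
    # orientation: make enclosed volume positive (outward normals)
    if shell.signed_volume() < 0:
        shell = TriangleMesh(shell.vertices, shell.triangles[:, ::-1])
    return SolidPatch(shell, thickness)
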