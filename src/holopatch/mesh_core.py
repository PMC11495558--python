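"""Triangle-mesh data model, file I/O and exact spatial queries.

This module holds the three primitives every other stage of the patch
pipeline builds on:

* :class:`TriangleMesh` — an indexed triangle surface in millimetres,
  the in-memory form of the segmented heart model and of every patch
  surface the pipeline produces;
* :class:`SurfacePoint` — a point constrained to the mesh surface,
  stored with its triangle and barycentric coordinates (the "collision
  point" of the marking workflow);
* :class:`SpatialIndex` — a k-d tree over triangle bounds supporting
  exact closest-point and sphere-overlap queries.  Queries are
  guaranteed to agree with a brute-force scan over all triangles; the
  tree only prunes candidates.

File I/O (STL binary/ascii, OBJ, ascii PLY) is delegated to
:mod:`trimesh`; on import, duplicate vertices are merged within a fixed
tolerance so that downstream curvature estimation sees a connected
manifold rather than the per-facet vertex soup STL stores.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import MeshContentError, MeshFormatError, ParameterError

#: Vertex-merge tolerance on import, in mm.  STL duplicates every vertex
#: per facet; merging below the scanner / segmentation noise floor is
#: lossless for this application.
MERGE_TOL = 1e-6

_SUPPORTED = {"stl", "obj", "ply"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Indexed triangle surface with coordinates in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions.  Must be finite.
    triangles : (m, 3) int array
        Vertex indices, each in ``[0, n)``.  Zero-area triangles are
        dropped at construction.
    vertex_normals : (n, 3) float array, optional
        Per-vertex normals; recomputed lazily when absent.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshContentError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshContentError("triangles must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshContentError("non-finite vertex coordinates")
        n = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise MeshContentError("triangle index out of range")
        # drop degenerate (zero-area) triangles once, at construction
        if self.triangles.size:
            a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
            areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
            keep = areas > 1e-12
            if not keep.all():
                self.triangles = self.triangles[keep]

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> np.ndarray:
        """Return the (m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.triangles]

    def face_normals(self) -> np.ndarray:
        """Unit face normals, (m, 3)."""
        tri = self.triangle_corners()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm == 0, 1.0, norm)

    def area(self) -> float:
        """Total surface area in mm² (sum of half cross-product magnitudes)."""
        tri = self.triangle_corners()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (cached on the instance)."""
        if self.vertex_normals is not None:
            return self.vertex_normals
        tri = self.triangle_corners()
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        self.vertex_normals = vn / np.where(norm == 0, 1.0, norm)
        return self.vertex_normals

    # -- topology -----------------------------------------------------------

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        if unique:
            e = np.unique(np.sort(e, axis=1), axis=0)
        return e

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one triangle, as sorted index pairs."""
        e = np.sort(
            np.concatenate(
                [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be) if be.size else np.array([], dtype=np.int64)

    def euler_characteristic(self) -> int:
        referenced = np.unique(self.triangles)
        return int(len(referenced) - len(self.edges()) + self.n_triangles)

    def is_watertight(self) -> bool:
        """True when the surface has no boundary edges and every edge is
        shared by exactly two triangles."""
        e = np.sort(
            np.concatenate(
                [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
            ),
            axis=1,
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def signed_volume(self) -> float:
        """Enclosed volume (mm³) via the divergence theorem; positive for a
        consistently outward-oriented closed surface."""
        tri = self.triangle_corners()
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- cleanup ------------------------------------------------------------

    def merged(self, tol: float = MERGE_TOL) -> "TriangleMesh":
        """Return a copy with vertices closer than ``tol`` merged."""
        if self.n_vertices == 0:
            return TriangleMesh(self.vertices.copy(), self.triangles.copy())
        key = np.round(self.vertices / tol).astype(np.int64)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        verts = self.vertices[first]
        tris = inverse[self.triangles]
        # remove triangles collapsed by the merge
        ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
        return TriangleMesh(verts, tris[ok])

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "TriangleMesh":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.triangles.copy())


@dataclass(frozen=True)
class SurfacePoint:
    """A point on a mesh surface: position, owning triangle and barycentric
    weights (non-negative, summing to one)."""

    position: np.ndarray
    triangle_id: int
    barycentric: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=np.float64))
        object.__setattr__(self, "barycentric", np.asarray(self.barycentric, dtype=np.float64))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = Path(path).suffix.lstrip(".").lower()
    if f not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh format {f!r} (use STL, OBJ or PLY)")
    return f


def read_mesh(path, fmt: str | None = None, merge_tol: float = MERGE_TOL) -> TriangleMesh:
    """Read an STL / OBJ / PLY triangle mesh, merging duplicate vertices.

    Parameters
    ----------
    path : str or Path
    fmt : {"stl", "obj", "ply"}, optional
        Inferred from the file extension when omitted.
    merge_tol : float
        Vertex-merge tolerance in mm.

    Raises
    ------
    MeshFormatError
        File does not parse under the named standard.
    MeshContentError
        File parses but contains no triangles.
    """
    path = os.fspath(path)
    f = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise MeshFormatError(f"no such file: {path}")
    if f == "stl":
        # a binary STL is at least header + count = 84 bytes; shorter files
        # can only be (possibly empty) ascii STL starting with "solid"
        size = os.path.getsize(path)
        if size < 84:
            with open(path, "rb") as fh:
                head = fh.read(5)
            if head != b"solid":
                raise MeshFormatError(f"{path}: truncated or malformed STL")
    try:
        loaded = trimesh.load(path, file_type=f, process=False, force="mesh")
    except MeshFormatError:
        raise
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshFormatError(f"could not parse {path} as {f}: {exc}") from exc
    verts = np.asarray(getattr(loaded, "vertices", np.zeros((0, 3))), dtype=float)
    faces = np.asarray(getattr(loaded, "faces", np.zeros((0, 3), dtype=int)), dtype=np.int64)
    if len(verts) == 0 or len(faces) == 0:
        raise MeshContentError(f"{path}: empty mesh")
    mesh = TriangleMesh(verts, faces).merged(merge_tol)
    if mesh.n_triangles == 0:
        raise MeshContentError(f"{path}: no valid triangles after cleanup")
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None, stl_mode: str = "binary") -> None:
    """Write a mesh to STL (binary or ascii), OBJ or ascii PLY.

    Binary STL follows the standard layout: 80-byte header, uint32
    triangle count, 50 bytes per triangle, little-endian.
    """
    path = os.fspath(path)
    f = _infer_format(path, fmt)
    if mesh.n_triangles == 0:
        raise MeshContentError("refusing to write an empty mesh")
    if stl_mode not in ("binary", "ascii"):
        raise ParameterError(f"stl_mode must be 'binary' or 'ascii', got {stl_mode!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    try:
        if f == "stl":
            data = tm.export(file_type="stl" if stl_mode == "binary" else "stl_ascii")
        elif f == "ply":
            data = tm.export(file_type="ply", encoding="ascii")
        else:
            data = tm.export(file_type="obj")
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
    except (OSError, IOError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# point-triangle geometry
# ---------------------------------------------------------------------------


def closest_point_on_triangles(q: np.ndarray, corners: np.ndarray):
    """Closest point to ``q`` on each of a batch of triangles.

    Implements the region-based projection of a point onto a triangle
    (clamping the unconstrained plane projection to the triangle's edges
    and vertices), vectorised over the batch.

    Parameters
    ----------
    q : (3,) array
    corners : (m, 3, 3) array

    Returns
    -------
    points : (m, 3) closest points
    bary : (m, 3) barycentric coordinates of those points
    dist : (m,) Euclidean distances
    """
    q = np.asarray(q, dtype=float)
    a = corners[:, 0]
    ab = corners[:, 1] - a
    ac = corners[:, 2] - a
    ap = q - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = q - corners[:, 1]
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = q - corners[:, 2]
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    m = len(corners)
    u = np.empty(m)
    v = np.empty(m)
    done = np.zeros(m, dtype=bool)

    # vertex A region
    mask = (d1 <= 0) & (d2 <= 0)
    u[mask] = 0.0
    v[mask] = 0.0
    done |= mask
    # vertex B region
    mask = ~done & (d3 >= 0) & (d4 <= d3)
    u[mask] = 1.0
    v[mask] = 0.0
    done |= mask
    # vertex C region
    mask = ~done & (d6 >= 0) & (d5 <= d6)
    u[mask] = 0.0
    v[mask] = 1.0
    done |= mask
    # edge AB
    vc = d1 * d4 - d3 * d2
    mask = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom != 0, d1 / denom, 0.0)
    u[mask] = t[mask]
    v[mask] = 0.0
    done |= mask
    # edge AC
    vb = d5 * d2 - d1 * d6
    mask = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom != 0, d2 / denom, 0.0)
    u[mask] = 0.0
    v[mask] = t[mask]
    done |= mask
    # edge BC
    va = d3 * d6 - d5 * d4
    mask = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    u[mask] = 1.0 - t[mask]
    v[mask] = t[mask]
    done |= mask
    # interior
    mask = ~done
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        uu = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        vv = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    u[mask] = uu[mask]
    v[mask] = vv[mask]

    points = a + u[:, None] * ab + v[:, None] * ac
    bary = np.stack([1.0 - u - v, u, v], axis=1)
    # clamp tiny negatives from floating point
    bary = np.clip(bary, 0.0, 1.0)
    bary /= bary.sum(axis=1, keepdims=True)
    dist = np.linalg.norm(points - q, axis=1)
    return points, bary, dist


# ---------------------------------------------------------------------------
# spatial index
# ---------------------------------------------------------------------------


class SpatialIndex:
    """k-d tree over triangle bounds for exact proximity queries.

    The tree stores triangle centroids together with each triangle's
    circumscribing radius; candidate sets are pruned with the triangle
    inequality and the surviving candidates are tested exactly, so
    results are identical to a brute-force scan over every triangle.
    Ties in the closest-triangle query break toward the lowest triangle
    index.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_triangles == 0:
            raise MeshContentError("cannot index an empty mesh")
        self.mesh = mesh
        self._corners = mesh.triangle_corners()
        self._centroids = self._corners.mean(axis=1)
        self._radii = np.linalg.norm(
            self._corners - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radii.max())
        self._tree = cKDTree(self._centroids)

    # -- queries ------------------------------------------------------------

    def closest_surface_point(self, q) -> tuple[SurfacePoint, float]:
        """Closest point on the mesh to ``q`` and its distance (mm)."""
        q = np.asarray(q, dtype=float)
        _, i0 = self._tree.query(q)
        # exact distance to the seed triangle is a valid upper bound
        _, _, d0 = closest_point_on_triangles(q, self._corners[[i0]])
        ub = float(d0[0])
        cand = self._tree.query_ball_point(q, ub + self._rmax + 1e-12)
        cand = np.sort(np.asarray(cand, dtype=np.int64))
        pts, bary, dist = closest_point_on_triangles(q, self._corners[cand])
        k = int(np.argmin(dist))  # first minimum -> lowest triangle id on ties
        tid = int(cand[k])
        return SurfacePoint(pts[k], tid, bary[k]), float(dist[k])

    def sphere_collision_points(self, center, radius: float) -> list[SurfacePoint]:
        """One :class:`SurfacePoint` per triangle overlapping the sphere.

        A triangle overlaps when its minimal distance to ``center`` is at
        most ``radius``; the returned point is the closest point of that
        triangle, ordered by triangle index.
        """
        if radius <= 0:
            raise ParameterError(f"sphere radius must be positive, got {radius}")
        center = np.asarray(center, dtype=float)
        cand = self._tree.query_ball_point(center, radius + self._rmax + 1e-12)
        if not cand:
            return []
        cand = np.sort(np.asarray(cand, dtype=np.int64))
        pts, bary, dist = closest_point_on_triangles(center, self._corners[cand])
        hit = dist <= radius
        return [
            SurfacePoint(pts[i], int(cand[i]), bary[i])
            for i in np.nonzero(hit)[0]
        ]


def build_index(mesh: TriangleMesh) -> SpatialIndex:
    """Build the spatial acceleration structure for a mesh."""
    return SpatialIndex(mesh)
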