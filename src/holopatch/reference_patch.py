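"""Digitising a scanned physical patch into a reference mesh (DRP).

The surgical leftover material (Gore-Tex shreds or the metal trimming
foil of a pericardial patch) is scanned into a point cloud; this module
turns that cloud into a digital reference patch — the gold standard the
digitally designed patches are compared against — with a fully
automatic pipeline:

1. :func:`remove_outliers` — statistical outlier removal on mean
   k-nearest-neighbour distances;
2. :func:`reconstruct_patch` — PCA plane fit, 2D projection, boundary
   and interior triangulation by the alpha complex of the projected
   Delaunay triangulation, and a moving-least-squares lift back to 3D
   so the gentle curvature of a real patch survives digitisation.

Only a single contiguous scanned object is reconstructed; registering
multiple fragments into one patch is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .errors import GeometryError, MeshFormatError, ParameterError
from .mesh_core import TriangleMesh
from .patch_builder import RingCurve

#: Ratio of the smallest to middle PCA standard deviation above which a
#: cloud is rejected as not sheet-like.
SHEET_RATIO_MAX = 0.3


@dataclass
class PointCloud:
    """Unstructured 3D point set in mm, optionally with per-point
    confidence weights."""

    points: np.ndarray
    confidence: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshFormatError("point cloud must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise MeshFormatError("non-finite point coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DRPatch:
    """Digital reference patch: reconstructed mesh, its fitted plane and
    its boundary ring."""

    mesh: TriangleMesh
    fit_plane: tuple  # (point, unit normal)
    boundary: RingCurve


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_point_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read an XYZ (whitespace-separated x y z per line) or ascii PLY
    point cloud; coordinates are taken as mm."""
    path = Path(path)
    f = (fmt or path.suffix.lstrip(".")).lower()
    if f == "xyz":
        pts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    pts.append([float(parts[0]), float(parts[1]), float(parts[2])])
                except (ValueError, IndexError) as exc:
                    raise MeshFormatError(
                        f"{path}:{lineno}: expected three numbers, got {line!r}"
                    ) from exc
        if not pts:
            raise MeshFormatError(f"{path}: no points")
        return PointCloud(np.array(pts))
    if f == "ply":
        import trimesh

        try:
            loaded = trimesh.load(str(path), file_type="ply", process=False)
            pts = np.asarray(loaded.vertices, dtype=float)
        except MeshFormatError:
            raise
        except Exception as exc:
            raise MeshFormatError(f"{path}: could not parse PLY: {exc}") from exc
        if len(pts) == 0:
            raise MeshFormatError(f"{path}: no points")
        return PointCloud(pts)
    raise MeshFormatError(f"unsupported point-cloud format {f!r} (use XYZ or PLY)")


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a cloud as XYZ text (one ``x y z`` line per point)."""
    np.savetxt(path, cloud.points, fmt="%.9g")


# ---------------------------------------------------------------------------
# cleanup
# ---------------------------------------------------------------------------


def remove_outliers(
    cloud: PointCloud, k_neighbors: int = 8, sd_multiplier: float = 3.0
) -> PointCloud:
    """Statistical outlier removal.

    A point is dropped when its mean distance to its ``k_neighbors``
    nearest neighbours exceeds the global mean of that statistic by more
    than ``sd_multiplier`` standard deviations.  Deterministic; an
    infinite multiplier is the identity.  The default 3-SD cut removes
    gross scanner artefacts while keeping the outline of the scanned
    patch (edge points sit in the natural tail of the k-NN statistic);
    tighten to 2 SD for heavily contaminated scans.
    """
    pts = cloud.points
    if k_neighbors >= len(pts):
        raise ParameterError("k_neighbors must be smaller than the number of points")
    if not np.isfinite(sd_multiplier):
        return PointCloud(pts.copy())
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_neighbors + 1)  # first neighbour is the point itself
    mean_d = dist[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + sd_multiplier * mean_d.std(ddof=1)
    keep = mean_d <= thresh
    return PointCloud(pts[keep])


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def _fit_plane(pts: np.ndarray):
    center = pts.mean(axis=0)
    centered = pts - center
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    sd = sv / np.sqrt(len(pts))
    return center, vt, sd


def _alpha_complex(pts2d: np.ndarray, alpha: float):
    """Triangles of the 2D Delaunay triangulation with circumradius <=
    alpha (the alpha complex of the point set)."""
    tri = Delaunay(pts2d)
    simp = tri.simplices
    a = pts2d[simp[:, 0]]
    b = pts2d[simp[:, 1]]
    c = pts2d[simp[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    u = b - a
    v = c - a
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = (la * lb * lc) / (2.0 * area2)
    keep = np.isfinite(circum_r) & (circum_r <= alpha)
    return simp[keep]


def _largest_component(faces: np.ndarray) -> np.ndarray:
    """Faces of the largest edge-connected component."""
    if len(faces) == 0:
        return faces
    # union-find over vertices
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for f in faces:
        r = find(int(f[0]))
        for v in f[1:]:
            rv = find(int(v))
            if rv != r:
                parent[rv] = r
    roots = np.array([find(int(f[0])) for f in faces])
    vals, counts = np.unique(roots, return_counts=True)
    return faces[roots == vals[np.argmax(counts)]]


def _mls_lift(xy: np.ndarray, height: np.ndarray, query: np.ndarray, radius: float):
    """Moving-least-squares quadratic fit of ``height(x, y)`` evaluated at
    the query points, with a Gaussian weight of scale ``radius / 2``."""
    tree = cKDTree(xy)
    out = np.empty(len(query))
    scale = radius / 2.0
    for i, q in enumerate(query):
        idx = tree.query_ball_point(q, radius)
        if len(idx) < 6:
            _, idx = tree.query(q, k=min(8, len(xy)))
            idx = np.atleast_1d(idx)
        local = xy[idx] - q
        z = height[idx]
        w = np.exp(-(local ** 2).sum(axis=1) / (2 * scale ** 2))
        A = np.column_stack(
            [
                np.ones(len(idx)),
                local[:, 0],
                local[:, 1],
                local[:, 0] ** 2,
                local[:, 0] * local[:, 1],
                local[:, 1] ** 2,
            ]
        )
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        out[i] = coef[0]
    return out


def _boundary_loop(faces: np.ndarray) -> np.ndarray:
    """Ordered vertex loop of the (longest) boundary of a triangulated
    region."""
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    be = uniq[counts == 1]
    if len(be) == 0:
        raise GeometryError("reconstructed region has no boundary")
    adj: dict[int, list[int]] = {}
    for u, v in be:
        adj.setdefault(int(u), []).append(int(v))
        adj.setdefault(int(v), []).append(int(u))
    loops = []
    visited = set()
    for start in adj:
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxts = [x for x in adj[cur] if x != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return np.array(max(loops, key=len), dtype=np.int64)


def reconstruct_patch(cloud: PointCloud, alpha: float | None = None) -> DRPatch:
    """Reconstruct a sheet-like point cloud into a reference patch mesh.

    Pipeline: PCA plane fit (rejecting clouds whose out-of-plane spread
    is not small against their in-plane spread); projection to the
    plane; alpha-complex triangulation of the projected points (``alpha``
    defaults to 3x the median nearest-neighbour spacing, tightening the
    hull to the scanned outline); moving-least-squares lift of the
    vertices back off the plane, smoothing scanner noise while keeping
    genuine curvature.
    """
    pts = cloud.points
    if len(pts) < 50:
        raise ParameterError("need >= 50 points for reconstruction")
    center, axes, sd = _fit_plane(pts)
    if sd[2] > SHEET_RATIO_MAX * sd[1]:
        raise GeometryError(
            f"cloud is not sheet-like (out-of-plane/in-plane spread "
            f"{sd[2]:.3g}/{sd[1]:.3g})"
        )
    local = (pts - center) @ axes.T
    xy = local[:, :2]
    height = local[:, 2]

    tree = cKDTree(xy)
    nn, _ = tree.query(xy, k=2)
    spacing = float(np.median(nn[:, 1]))
    if alpha is None:
        alpha = 3.0 * spacing

    faces = _largest_component(_alpha_complex(xy, alpha))
    if len(faces) == 0:
        raise GeometryError("alpha too small: no triangles survive")

    used = np.unique(faces)
    remap = -np.ones(len(xy), dtype=np.int64)
    remap[used] = np.arange(len(used))
    faces = remap[faces]
    xy_used = xy[used]

    lifted = _mls_lift(xy, height, xy_used, radius=max(7 * spacing, 1.5 * alpha))
    verts3 = center + xy_used[:, 0, None] * axes[0] + xy_used[:, 1, None] * axes[1] + lifted[:, None] * axes[2]
    mesh = TriangleMesh(verts3, faces)

    loop = _boundary_loop(mesh.triangles)
    ring = RingCurve(mesh.vertices[loop], mesh.vertices[loop], conformed=False)
    return DRPatch(mesh, (center, axes[2]), ring)
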