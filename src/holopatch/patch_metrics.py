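"""Quantitative characterisation of patch surfaces.

Three families of measurements, matching how digital patches are
compared against the surgical reference:

* surface area (mm², sum of triangle areas);
* discrete Gaussian curvature (mm⁻²) by the angle-deficit estimator
  with mixed Voronoi areas, summarised as mean / median / IQR and
  classified dome (K > 0), saddle (K < 0) or flat;
* principal-component diameters (mm): the extents of the vertex cloud
  along its first two principal axes.

Curvature is intrinsic: positive at dome-like (elliptic) points,
negative at saddle-like (hyperbolic) points, zero on developable
surfaces.  The angle-deficit estimator at a vertex v is

    K(v) = (2*pi - sum of incident triangle angles at v) / A_mixed(v)

where ``A_mixed`` is the obtuse-safe mixed Voronoi area.  Boundary
vertices have no full angular fan and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, MeshContentError, ParameterError
from .mesh_core import TriangleMesh
from .intersect import self_intersecting_pairs

#: |K_mean| below this (mm⁻², the curvature of a 100 mm sphere) counts
#: as flat for shape classification.
FLAT_EPS = 1e-4


@dataclass
class CurvatureField:
    """Per-interior-vertex Gaussian curvature of one mesh."""

    values: np.ndarray       # K at the interior vertices, mm⁻²
    vertex_ids: np.ndarray   # which vertices the values belong to
    boundary_excluded: bool = True


@dataclass
class PatchMetrics:
    """Bundle of the per-patch quantities used for method comparison."""

    area: float
    K_mean: float
    K_median: float
    K_iqr: tuple
    d_major: float
    d_minor: float
    n_self_intersections: int
    shape_class: str

    def as_dict(self) -> dict:
        return {
            "area_mm2": self.area,
            "K_mean": self.K_mean,
            "K_median": self.K_median,
            "K_iqr_low": self.K_iqr[0],
            "K_iqr_high": self.K_iqr[1],
            "d_major_mm": self.d_major,
            "d_minor_mm": self.d_minor,
            "n_self_intersections": self.n_self_intersections,
            "shape_class": self.shape_class,
        }


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm²."""
    return mesh.area()


def _mixed_voronoi_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex mixed Voronoi areas (obtuse-safe).

    Non-obtuse triangles contribute the circumcentric Voronoi pieces
    (1/8)(|e_ik|² cot(angle_j) + |e_ij|² cot(angle_k)) to vertex i;
    obtuse triangles contribute area/2 to their obtuse vertex and
    area/4 to the other two.
    """
    v = mesh.vertices
    f = mesh.triangles
    p = v[f]  # (m, 3, 3)
    areas = np.zeros(mesh.n_vertices)

    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    l2 = np.einsum("mij,mij->mi", e, e)  # squared edge lengths opposite each vertex
    tri_area = 0.5 * np.linalg.norm(np.cross(e[:, 1], e[:, 2]), axis=1)

    # cotangent at vertex i = (l_j² + l_k² - l_i²) / (4 * area)
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = np.stack(
            [
                (l2[:, 1] + l2[:, 2] - l2[:, 0]),
                (l2[:, 2] + l2[:, 0] - l2[:, 1]),
                (l2[:, 0] + l2[:, 1] - l2[:, 2]),
            ],
            axis=1,
        ) / (4.0 * tri_area[:, None])

    obtuse_at = cot < 0  # angle > 90° exactly where its cotangent is negative
    any_obtuse = obtuse_at.any(axis=1)

    # non-obtuse: Voronoi pieces
    safe = ~any_obtuse
    if safe.any():
        fa = f[safe]
        l2s = l2[safe]
        cots = cot[safe]
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            # edge i-j has squared length l2[k] and opposite angle at k;
            # edge i-k has squared length l2[j] and opposite angle at j
            contrib = (l2s[:, k] * cots[:, k] + l2s[:, j] * cots[:, j]) / 8.0
            np.add.at(areas, fa[:, i], contrib)
    # obtuse: half to the obtuse corner, quarter to the others
    if any_obtuse.any():
        fo = f[any_obtuse]
        ao = tri_area[any_obtuse]
        oo = obtuse_at[any_obtuse]
        for i in range(3):
            contrib = np.where(oo[:, i], ao / 2.0, ao / 4.0)
            np.add.at(areas, fo[:, i], contrib)
    return areas


def _angle_sums(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.triangles
    p = v[f]
    sums = np.zeros(mesh.n_vertices)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        u = p[:, j] - p[:, i]
        w = p[:, k] - p[:, i]
        cu = np.linalg.norm(np.cross(u, w), axis=1)
        du = np.einsum("ij,ij->i", u, w)
        ang = np.arctan2(cu, du)
        np.add.at(sums, f[:, i], ang)
    return sums


def gaussian_curvature(mesh: TriangleMesh) -> CurvatureField:
    """Angle-deficit Gaussian curvature at interior vertices.

    Boundary vertices are excluded (their angular fan is incomplete);
    vertices on non-manifold edges are excluded with a warning.
    """
    if mesh.n_triangles == 0:
        raise MeshContentError("empty mesh has no curvature")
    sums = _angle_sums(mesh)
    areas = _mixed_voronoi_areas(mesh)

    e = np.sort(
        np.concatenate(
            [mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]], mesh.triangles[:, [2, 0]]]
        ),
        axis=1,
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    excluded = set(np.unique(uniq[counts == 1]).tolist())
    nonmanifold = np.unique(uniq[counts > 2])
    if nonmanifold.size:
        warnings.warn(
            f"{nonmanifold.size} vertices on non-manifold edges excluded from curvature",
            stacklevel=2,
        )
        excluded |= set(nonmanifold.tolist())

    referenced = np.unique(mesh.triangles)
    interior = np.array(
        [vid for vid in referenced if vid not in excluded], dtype=np.int64
    )
    if interior.size == 0:
        raise GeometryError("mesh has no interior vertices (curvature undefined)")
    K = (2.0 * np.pi - sums[interior]) / areas[interior]
    return CurvatureField(K, interior)


def curvature_summary(field: CurvatureField):
    """(mean, median, (25th, 75th percentile)) of a curvature field.

    Percentiles use linear interpolation between order statistics.
    """
    vals = np.asarray(field.values, dtype=float)
    if vals.size == 0:
        raise MeshContentError("empty curvature field")
    q25, q75 = np.percentile(vals, [25, 75])
    return float(vals.mean()), float(np.median(vals)), (float(q25), float(q75))


def shape_class(K_mean: float, eps: float = FLAT_EPS) -> str:
    """Classify a patch by mean Gaussian curvature: ``dome`` (K > eps),
    ``saddle`` (K < -eps) or ``flat``."""
    if eps < 0:
        raise ParameterError("eps must be non-negative")
    if K_mean > eps:
        return "dome"
    if K_mean < -eps:
        return "saddle"
    return "flat"


def pca_diameters(mesh_or_points) -> tuple[float, float]:
    """Major and minor diameters along the first two principal axes.

    The vertex cloud is reduced to its two principal components and the
    diameter along each axis is the extent (max minus min) of the
    vertex projections; returned as (d_major, d_minor).
    """
    if isinstance(mesh_or_points, TriangleMesh):
        pts = mesh_or_points.vertices
    else:
        pts = np.asarray(mesh_or_points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need >= 3 points for PCA diameters")
    centered = pts - pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] < 1e-12 * max(sv[0], 1.0):
        raise GeometryError("collinear points: PCA diameters undefined")
    d = []
    for axis in vt[:2]:
        proj = centered @ axis
        d.append(float(proj.max() - proj.min()))
    d_major, d_minor = max(d), min(d)
    return d_major, d_minor


def curvature_histogram(field: CurvatureField, bins: int = 50):
    """(bin_edges, counts) of the curvature distribution, for export."""
    counts, edges = np.histogram(field.values, bins=bins)
    return edges, counts


def compute_metrics(mesh: TriangleMesh, flat_eps: float = FLAT_EPS) -> PatchMetrics:
    """Full metric bundle for one patch surface."""
    area = surface_area(mesh)
    field = gaussian_curvature(mesh)
    k_mean, k_median, k_iqr = curvature_summary(field)
    d_major, d_minor = pca_diameters(mesh)
    n_int = len(self_intersecting_pairs(mesh.vertices, mesh.triangles))
    return PatchMetrics(
        area=area,
        K_mean=k_mean,
        K_median=k_median,
        K_iqr=k_iqr,
        d_major=d_major,
        d_minor=d_minor,
        n_self_intersections=n_int,
        shape_class=shape_class(k_mean, flat_eps),
    )
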