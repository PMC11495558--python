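"""Seeded generators of synthetic anatomy and evaluator cohorts.

Patient meshes from the clinical workflow are not redistributable, so
every downstream stage is exercised on synthetic stand-ins generated
here:

* :func:`generate_septal_wall` — a flat or spherically curved wall
  segment carrying an elliptical defect, the minimal geometry on which
  boundary marking, ring interpolation and patch construction behave as
  they do on a segmented heart;
* :func:`generate_marking_stroke` — an ordered sequence of fingertip
  sphere centres circling the defect rim, with optional Gaussian hand
  jitter, emulating the mixed-reality marking gesture;
* :func:`simulate_marking_fold` — displaces a contiguous arc of a
  stroke onto an adjacent parallel plane with an angular step backward,
  the gesture error that produces the "double fold" self-intersection
  artefact;
* :func:`generate_method_cohort` — a long-format patient x evaluator x
  method table of patch areas and diameters with per-method
  multiplicative bias and lognormal evaluator noise, mirroring the
  structure of a method-comparison study (one reference patch per
  patient, several evaluators per modality);
* :func:`generate_patch_cloud` — a noisy surface scan of an elliptical
  patch (flat or a spherical-cap section), emulating a structured-light
  scanner point cloud of surgical leftover material.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .errors import ParameterError
from .mesh_core import TriangleMesh, build_index

# Fixed patch aspect ratio (major/minor) used when deriving the two
# principal diameters from an area; clinical patches are mildly oblong.
DIAMETER_ASPECT = 1.3

METHOD_DRP = "DRP"
METHOD_HOLO = "HOLO"
METHOD_DESKTOP = "DESKTOP"


@dataclass(frozen=True)
class DefectSpec:
    """Elliptical defect in the wall plane: centre, semi-axes (a >= b > 0,
    mm) and in-plane orientation (rad)."""

    center: tuple = (0.0, 0.0, 0.0)
    semi_axes: tuple = (10.0, 7.0)
    orientation: float = 0.0

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ParameterError(f"semi-axes must satisfy a >= b > 0, got {self.semi_axes}")


@dataclass(frozen=True)
class StrokeSpec:
    """Marking-stroke parameters: number of sphere centres, radial offset
    from the defect rim (mm), hand jitter SD (mm), marking-sphere radius
    (mm) and seed."""

    n_centers: int = 24
    radial_offset: float = 3.0
    jitter_sd: float = 0.3
    sphere_radius: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_centers < 8:
            raise ParameterError("a marking stroke needs at least 8 sphere centres")
        if self.sphere_radius <= 0:
            raise ParameterError("sphere_radius must be positive")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")


@dataclass(frozen=True)
class CohortParams:
    """Cohort generator parameters.

    True patch areas are lognormal across patients (study patch areas
    span a >20x range, which a lognormal captures with two parameters).
    Each evaluator's digital patch multiplies the patient's reference
    area by a per-method bias and a lognormal noise of the given
    coefficient of variation.  Defaults reflect a study in which
    mixed-reality patches run larger than desktop patches, with the
    desktop method undersizing relative to the reference.
    """

    n_patients: int = 10
    n_evaluators: int = 5
    log_area_mean: float = 5.6   # log mm²; exp(5.6) ≈ 270 mm²
    log_area_sd: float = 1.0
    bias_holo: float = 0.84
    bias_desktop: float = 0.84 / 1.42
    evaluator_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_evaluators < 2:
            raise ParameterError("need at least 2 evaluators")
        for name in ("n_patients", "log_area_sd", "bias_holo", "bias_desktop"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.evaluator_cv < 0:
            raise ParameterError("evaluator_cv must be non-negative")


# ---------------------------------------------------------------------------
# wall mesh
# ---------------------------------------------------------------------------


def _ellipse_frame(defect: DefectSpec):
    c = np.asarray(defect.center, dtype=float)[:2]
    th = defect.orientation
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return c, rot


def _ellipse_u(xy: np.ndarray, defect: DefectSpec) -> np.ndarray:
    """Normalised elliptical radius: u < 1 inside the defect, u = 1 on the rim."""
    c, rot = _ellipse_frame(defect)
    local = (xy - c) @ rot  # rotate into ellipse frame
    a, b = defect.semi_axes
    return np.hypot(local[:, 0] / a, local[:, 1] / b)


def _ellipse_rim_points(defect: DefectSpec, spacing: float, offset: float = 0.0):
    """Points at constant normal offset from the defect rim, approximately
    equally spaced by arc length, with their outward in-plane normals."""
    a, b = defect.semi_axes
    c, rot = _ellipse_frame(defect)
    # dense parameter sampling, then arc-length resampling
    t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    base = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    grad = np.stack([np.cos(t) / a, np.sin(t) / b], axis=1)
    nrm = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    pts = base + offset * nrm
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    total = arc[-1] + seg[-1]
    n = max(16, int(round(total / spacing)))
    want = np.linspace(0, total, n, endpoint=False)
    idx = np.searchsorted(arc, want, side="right") - 1
    out_pts = pts[idx] @ rot.T + c
    out_nrm = nrm[idx] @ rot.T
    return out_pts, out_nrm


def generate_septal_wall(
    extent: float = 80.0,
    curvature_radius: float | None = None,
    defect: DefectSpec = DefectSpec(),
    mesh_step: float = 1.5,
    seed: int = 0,
) -> TriangleMesh:
    """Generate a wall segment of side ``extent`` with an elliptical defect.

    The wall is meshed as a jittered lattice in its plane, triangulated
    by Delaunay, with the defect cut out along an explicit rim polygon.
    When ``curvature_radius`` is given, the wall is lifted onto a sphere
    of that radius (so every vertex lies exactly on the sphere), giving
    a gently curved septum-like surface.

    Deterministic for a fixed seed.
    """
    a, b = defect.semi_axes
    c = np.asarray(defect.center, dtype=float)[:2]
    if np.max(np.abs(c)) + max(a, b) >= extent / 2:
        raise ParameterError("defect ellipse must fit strictly inside the wall extent")
    if curvature_radius is not None and extent / np.sqrt(2) >= curvature_radius:
        raise ParameterError("wall extent too large for the requested curvature radius")

    rng = np.random.default_rng(seed)
    half = extent / 2
    n = int(round(extent / mesh_step)) + 1
    axis = np.linspace(-half, half, n)
    gx, gy = np.meshgrid(axis, axis)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)

    # jitter interior lattice points (stabilises the Delaunay of a regular
    # grid); border and near-rim points stay put / are removed
    interior = (np.abs(grid[:, 0]) < half - 1e-9) & (np.abs(grid[:, 1]) < half - 1e-9)
    jitter = rng.uniform(-0.15 * mesh_step, 0.15 * mesh_step, size=grid.shape)
    grid = grid + jitter * interior[:, None]

    # drop lattice points inside the defect or hugging its rim
    u = _ellipse_u(grid, defect)
    clearance = 1.0 + 0.45 * mesh_step / b
    keep = u >= clearance
    rim, _ = _ellipse_rim_points(defect, mesh_step)
    pts2d = np.concatenate([grid[keep], rim])

    tri2d = Delaunay(pts2d)
    cent = pts2d[tri2d.simplices].mean(axis=1)
    outside = _ellipse_u(cent, defect) >= 1.0
    faces = tri2d.simplices[outside]

    if curvature_radius is None:
        z = np.zeros(len(pts2d))
    else:
        r2 = (pts2d ** 2).sum(axis=1)
        z = curvature_radius - np.sqrt(curvature_radius ** 2 - r2)
    verts = np.column_stack([pts2d, z])
    return TriangleMesh(verts, faces)


# ---------------------------------------------------------------------------
# marking stroke
# ---------------------------------------------------------------------------


def generate_marking_stroke(
    mesh: TriangleMesh, defect: DefectSpec, stroke: StrokeSpec
) -> np.ndarray:
    """Ordered fingertip sphere centres circling the defect rim.

    Centres sit ``radial_offset`` mm outside the rim (measured along the
    rim's in-plane normal), are lifted onto the wall surface, and then
    perturbed by isotropic Gaussian jitter of SD ``jitter_sd`` in 3D.

    Returns an (n_centers, 3) array; deterministic per ``stroke.seed``.
    """
    n = stroke.n_centers
    a, b = defect.semi_axes
    c, rot = _ellipse_frame(defect)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    base = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    grad = np.stack([np.cos(t) / a, np.sin(t) / b], axis=1)
    nrm = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    xy = (base + stroke.radial_offset * nrm) @ rot.T + c

    # lift onto the wall surface so centres hover at the wall, not the plane
    index = build_index(mesh)
    centers = np.empty((n, 3))
    for i, p in enumerate(xy):
        sp, _ = index.closest_surface_point(np.array([p[0], p[1], 0.0]))
        centers[i] = [p[0], p[1], sp.position[2]]

    if stroke.jitter_sd > 0:
        rng = np.random.default_rng(stroke.seed)
        centers = centers + rng.normal(0.0, stroke.jitter_sd, size=centers.shape)
    return centers


def stroke_outward_normals(defect: DefectSpec, n_centers: int) -> np.ndarray:
    """In-plane outward unit normals of the rim at the stroke's angular
    stations (useful for measuring radial marking deviations)."""
    _, rot = _ellipse_frame(defect)
    t = np.linspace(0, 2 * np.pi, n_centers, endpoint=False)
    a, b = defect.semi_axes
    grad = np.stack([np.cos(t) / a, np.sin(t) / b], axis=1)
    nrm = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    nrm3 = np.column_stack([nrm @ rot.T, np.zeros(n_centers)])
    return nrm3


def simulate_marking_fold(
    centers: np.ndarray,
    arc_start: int,
    arc_len: int,
    plane_lift: float = 3.0,
    angle_shift: float | None = None,
) -> np.ndarray:
    """Corrupt a marking stroke the way an imprecise fingertip does.

    A contiguous arc of ``arc_len`` centres is displaced onto an
    adjacent parallel plane (``plane_lift`` mm along the stroke's
    best-fit-plane normal) and rotated backwards about the stroke
    centroid by ``angle_shift`` radians (default: 1.5 angular spacings),
    so the marked sequence doubles back on itself.  Interpolating such a
    stroke produces a pleated ring and a self-intersecting patch
    surface — the "double fold" artefact.
    """
    pts = np.asarray(centers, dtype=float).copy()
    n = len(pts)
    if not (0 < arc_len < n):
        raise ParameterError("arc_len must be in (0, n_centers)")
    if angle_shift is None:
        angle_shift = 1.5 * (2 * np.pi / n)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # best-fit plane normal = smallest principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    idx = (arc_start + np.arange(arc_len)) % n
    # rotate the arc backwards about the normal axis (Rodrigues)
    kx, ky, kz = normal
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    R = (
        np.eye(3)
        + np.sin(-angle_shift) * K
        + (1 - np.cos(-angle_shift)) * (K @ K)
    )
    pts[idx] = (centered[idx] @ R.T) + centroid + plane_lift * normal
    return pts


# ---------------------------------------------------------------------------
# evaluator cohort
# ---------------------------------------------------------------------------


def _diameters_from_area(area: np.ndarray, aspect: float = DIAMETER_ASPECT):
    """Major/minor diameters of a fixed-aspect ellipse of the given area."""
    a = np.sqrt(area * aspect / np.pi)
    return 2 * a, 2 * a / aspect


def generate_method_cohort(params: CohortParams) -> pd.DataFrame:
    """Long-format method-comparison table.

    One reference (DRP) record per patient with a lognormal true area;
    per patient x evaluator, one record per digital method whose area is
    ``true_area * bias * noise`` with mean-one lognormal noise of the
    given coefficient of variation.  Diameters are those of a
    fixed-aspect ellipse with the record's area.

    Columns: patient_id, evaluator_id (NA for DRP), method, area_mm2,
    d_major_mm, d_minor_mm.
    """
    rng = np.random.default_rng(params.seed)
    true_area = np.exp(
        rng.normal(params.log_area_mean, params.log_area_sd, size=params.n_patients)
    )
    sigma = np.sqrt(np.log1p(params.evaluator_cv ** 2))

    rows = []
    for p in range(params.n_patients):
        rows.append((p + 1, pd.NA, METHOD_DRP, true_area[p]))
    for p in range(params.n_patients):
        for e in range(params.n_evaluators):
            for method, bias in (
                (METHOD_HOLO, params.bias_holo),
                (METHOD_DESKTOP, params.bias_desktop),
            ):
                if sigma > 0:
                    noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma))
                else:
                    noise = 1.0
                rows.append((p + 1, e + 1, method, true_area[p] * bias * noise))

    table = pd.DataFrame(rows, columns=["patient_id", "evaluator_id", "method", "area_mm2"])
    dmaj, dmin = _diameters_from_area(table["area_mm2"].to_numpy(dtype=float))
    table["d_major_mm"] = dmaj
    table["d_minor_mm"] = dmin
    return table


# ---------------------------------------------------------------------------
# scanned-patch point cloud
# ---------------------------------------------------------------------------


def generate_patch_cloud(
    semi_axes: tuple = (10.0, 5.0),
    curvature_radius: float | None = None,
    spacing: float = 0.35,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_outliers: int = 0,
    outlier_offset: float = 50.0,
) -> np.ndarray:
    """Surface-scan point cloud of an elliptical patch.

    Interior points on a jittered lattice plus points along the patch
    outline (a scanner sees the edge of the physical material), lifted
    onto a sphere of ``curvature_radius`` when given, with isotropic
    Gaussian measurement noise of SD ``noise_sd`` (a structured-light
    scanner is ~0.1 mm).  Optionally appends gross outliers for testing
    statistical cleanup.
    """
    a, b = semi_axes
    rng = np.random.default_rng(seed)
    half = max(a, b)
    n = int(round(2 * half / spacing)) + 1
    axis = np.linspace(-half, half, n)
    gx, gy = np.meshgrid(axis, axis)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    grid += rng.uniform(-0.2 * spacing, 0.2 * spacing, size=grid.shape)
    u = np.hypot(grid[:, 0] / a, grid[:, 1] / b)
    inside = grid[u < 1 - 0.3 * spacing / b]

    t = np.linspace(0, 2 * np.pi, max(32, int(round(2 * np.pi * a / spacing))), endpoint=False)
    rim = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)

    xy = np.concatenate([inside, rim])
    if curvature_radius is None:
        z = np.zeros(len(xy))
    else:
        z = curvature_radius - np.sqrt(curvature_radius ** 2 - (xy ** 2).sum(axis=1))
    pts = np.column_stack([xy, z])
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    if n_outliers > 0:
        far = rng.normal(0.0, 1.0, size=(n_outliers, 3))
        far /= np.linalg.norm(far, axis=1, keepdims=True)
        pts = np.concatenate([pts, outlier_offset * far])
    return pts
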