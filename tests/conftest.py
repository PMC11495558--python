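"""Shared fixtures: synthetic anatomy, canonical patch surfaces, oracles."""

import numpy as np
import pytest

from holopatch import mesh_core, patch_builder as pb
from holopatch import synthetic_anatomy as syn
from holopatch.patch_builder import _catmull_rom_closed


# ---------------------------------------------------------------------------
# canonical geometry
# ---------------------------------------------------------------------------


def circle_knots(radius=10.0, n=24, z=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.full(n, z)])


def spline_ring(knots, n_samples=256):
    """Closed Catmull-Rom ring through the given knots."""
    params = np.linspace(0, len(knots), n_samples, endpoint=False)
    return pb.RingCurve(_catmull_rom_closed(knots, params), knots)


@pytest.fixture(scope="session")
def circle_ring():
    return spline_ring(circle_knots())


@pytest.fixture(scope="session")
def flat_disc_template(circle_ring):
    """Flat disc of radius 10 at the default tessellation."""
    return pb.build_surface(circle_ring, h=0.0, n_spokes=128, n_rings=32)


@pytest.fixture(scope="session")
def defect():
    return syn.DefectSpec(center=(0.0, 0.0, 0.0), semi_axes=(10.0, 10.0))


@pytest.fixture(scope="session")
def flat_wall(defect):
    return syn.generate_septal_wall(
        extent=80.0, curvature_radius=None, defect=defect, mesh_step=1.5, seed=0
    )


@pytest.fixture(scope="session")
def flat_wall_index(flat_wall):
    return mesh_core.build_index(flat_wall)


@pytest.fixture(scope="session")
def curved_wall(defect):
    return syn.generate_septal_wall(
        extent=60.0, curvature_radius=50.0, defect=defect, mesh_step=1.5, seed=0
    )


@pytest.fixture(scope="session")
def icosphere15():
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=4, radius=15.0)
    return mesh_core.TriangleMesh(np.array(ico.vertices), np.array(ico.faces))


def random_soup(n_triangles, rng, extent=20.0):
    """Random triangle soup mesh inside a cube (for query oracles)."""
    v = rng.uniform(-extent, extent, size=(n_triangles * 3, 3))
    f = np.arange(n_triangles * 3).reshape(-1, 3)
    return mesh_core.TriangleMesh(v, f)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_closest(mesh, q):
    """Scan every triangle for the closest point (lowest-id tie break)."""
    corners = mesh.triangle_corners()
    pts, bary, dist = mesh_core.closest_point_on_triangles(q, corners)
    k = int(np.argmin(dist))
    return k, float(dist[k]), pts[k]


def brute_force_sphere_hits(mesh, center, radius):
    corners = mesh.triangle_corners()
    _, _, dist = mesh_core.closest_point_on_triangles(center, corners)
    return np.nonzero(dist <= radius)[0]


def _segment_triangle_crosses(p, q, tri, eps):
    """Does segment pq properly cross the triangle's interior?"""
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nn = np.linalg.norm(n)
    if nn == 0:
        return False
    n = n / nn
    dp = float((p - tri[0]) @ n)
    dq = float((q - tri[0]) @ n)
    if dp * dq >= -eps * eps:
        return False
    t = dp / (dp - dq)
    x = p + t * (q - p)
    # barycentric inside test
    v0 = tri[1] - tri[0]
    v1 = tri[2] - tri[0]
    v2 = x - tri[0]
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    den = d00 * d11 - d01 * d01
    if den == 0:
        return False
    a = (d11 * d20 - d01 * d21) / den
    b = (d00 * d21 - d01 * d20) / den
    return a > eps and b > eps and (1 - a - b) > eps


def oracle_triangles_intersect(t1, t2, eps=1e-10):
    """Edge-through-triangle oracle (plus 2D overlap for coplanar pairs);
    formulated independently of the plane-interval implementation."""
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n1 = n1 / np.linalg.norm(n1)
    d2 = np.abs((t2 - t1[0]) @ n1)
    if (d2 < eps * 10).all():
        from shapely.geometry import Polygon

        axis = int(np.argmax(np.abs(n1)))
        cols = [c for c in range(3) if c != axis]
        inter = Polygon(t1[:, cols]).intersection(Polygon(t2[:, cols]))
        return inter.area > 1e-12
    for a, b in ((t1, t2), (t2, t1)):
        for i in range(3):
            if _segment_triangle_crosses(a[i], a[(i + 1) % 3], b, eps):
                return True
    return False


def oracle_all_pairs_intersections(mesh, eps=1e-10):
    """Exact intersection test on every non-adjacent pair, no culling."""
    tris = mesh.triangles
    corners = mesh.triangle_corners()
    m = len(tris)
    out = []
    for i in range(m):
        si = set(tris[i].tolist())
        for j in range(i + 1, m):
            if si & set(tris[j].tolist()):
                continue
            if oracle_triangles_intersect(corners[i], corners[j], eps):
                out.append((i, j))
    return out


def folded_stroke_fixture(defect, flat_wall, flat_wall_index):
    """The standard single-fold marking artefact on the synthetic wall."""
    stroke = syn.StrokeSpec(
        n_centers=24, radial_offset=3.0, jitter_sd=0.0, sphere_radius=3.0, seed=1
    )
    centers = syn.generate_marking_stroke(flat_wall, defect, stroke)
    folded = syn.simulate_marking_fold(centers, arc_start=5, arc_len=3, plane_lift=3.0)
    return centers, folded
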