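"""Boundary marking, ring interpolation, Bézier surface construction,
solidification and fold detection."""

import numpy as np
import pytest

from holopatch import mesh_core, patch_builder as pb, patch_metrics as pm
from holopatch import synthetic_anatomy as syn
from holopatch.errors import (
    ArtifactError,
    BoundaryError,
    GeometryError,
    ParameterError,
)

from conftest import (
    circle_knots,
    folded_stroke_fixture,
    oracle_all_pairs_intersections,
    spline_ring,
)


# ---------------------------------------------------------------------------
# boundary collection
# ---------------------------------------------------------------------------


def test_collect_boundary_keeps_stroke_order(flat_wall, flat_wall_index, defect):
    stroke = syn.StrokeSpec(n_centers=24, radial_offset=3.0, jitter_sd=0.0, seed=0)
    centers = syn.generate_marking_stroke(flat_wall, defect, stroke)
    marked = pb.collect_boundary(flat_wall, flat_wall_index, centers, 3.0)
    assert len(marked.points) == 24
    pos = marked.positions()
    # contact points circle the rim in the same angular order as the stroke
    ang = np.unwrap(np.arctan2(pos[:, 1], pos[:, 0]))
    assert np.all(np.diff(ang) > 0)
    # every contact point lies on the wall surface
    for p in marked.points:
        _, d = flat_wall_index.closest_surface_point(p.position)
        assert d < 1e-9


def test_collect_boundary_dedups_coincident_centers(flat_wall, flat_wall_index, defect):
    stroke = syn.StrokeSpec(n_centers=12, radial_offset=3.0, jitter_sd=0.0, seed=0)
    centers = syn.generate_marking_stroke(flat_wall, defect, stroke)
    doubled = np.repeat(centers, 2, axis=0)
    marked = pb.collect_boundary(flat_wall, flat_wall_index, doubled, 3.0)
    assert len(marked.points) == 12


def test_collect_boundary_far_stroke_errors(flat_wall, flat_wall_index):
    far = np.array([[0, 0, 50.0], [10, 0, 50.0], [0, 10, 50.0]])
    with pytest.raises(BoundaryError, match="insufficient"):
        pb.collect_boundary(flat_wall, flat_wall_index, far, 3.0)


def test_anchor_boundary_snapping(flat_wall, flat_wall_index):
    t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    on_surface = np.column_stack([13 * np.cos(t), 13 * np.sin(t), np.zeros(10)])
    marked = pb.anchor_boundary(flat_wall, flat_wall_index, on_surface)
    assert np.allclose(marked.positions(), on_surface, atol=1e-9)
    off = on_surface + [0, 0, 1.0]
    marked2 = pb.anchor_boundary(flat_wall, flat_wall_index, off)
    for p in marked2.points:
        _, d = flat_wall_index.closest_surface_point(p.position)
        assert d < 1e-6
    adjusted = pb.anchor_boundary(
        flat_wall, flat_wall_index, on_surface, adjustments={0: [14.0, 0.0, 0.0]}
    )
    assert adjusted.positions()[0][0] == pytest.approx(14.0, abs=1e-9)


def test_anchor_boundary_warns_below_ten(flat_wall, flat_wall_index):
    t = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    pts = np.column_stack([13 * np.cos(t), 13 * np.sin(t), np.zeros(6)])
    with pytest.warns(UserWarning, match="anchor points"):
        marked = pb.anchor_boundary(flat_wall, flat_wall_index, pts)
    assert len(marked.points) == 6


# ---------------------------------------------------------------------------
# ring ordering and interpolation
# ---------------------------------------------------------------------------


def _as_surface_points(pos):
    return [
        mesh_core.SurfacePoint(p, 0, np.array([1.0, 0.0, 0.0])) for p in pos
    ]


def test_order_ring_recovers_angular_order():
    rng = np.random.default_rng(4)
    n = 20
    t = np.sort(rng.uniform(0, 2 * np.pi, n))
    pos = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros(n)])
    perm = rng.permutation(n)
    ordered = pb.order_ring(_as_surface_points(pos[perm]))
    got = np.array([p.position for p in ordered])
    ang = np.unwrap(np.arctan2(got[:, 1], got[:, 0]))
    diffs = np.diff(ang)
    assert np.all(diffs > 0)  # CCW about +z


def test_order_ring_preserves_ordered_input():
    pos = circle_knots(n=12)
    ordered = pb.order_ring(_as_surface_points(pos))
    got = np.array([p.position for p in ordered])
    start = int(np.argmin(np.linalg.norm(got - pos[0], axis=1)))
    rolled = np.roll(got, -start, axis=0)
    assert np.allclose(rolled, pos)


def test_interpolate_ring_circle_circumference(flat_wall, flat_wall_index, defect):
    stroke = syn.StrokeSpec(n_centers=24, radial_offset=0.0, jitter_sd=0.0, seed=0)
    centers = syn.generate_marking_stroke(flat_wall, defect, stroke)
    # knots exactly on a radius-10 circle
    marked = pb.collect_boundary(flat_wall, flat_wall_index, centers, 3.0)
    ring = pb.interpolate_ring(marked, n_samples=256)
    assert ring.length() == pytest.approx(2 * np.pi * 10.0, rel=0.005)
    # the spline passes through every knot exactly (integer parameters)
    knots = marked.positions()
    from holopatch.patch_builder import _catmull_rom_closed

    at_knots = _catmull_rom_closed(knots, np.arange(len(knots), dtype=float))
    assert np.allclose(at_knots, knots, atol=1e-12)


def test_interpolate_ring_conforms_to_curved_wall(curved_wall):
    index = mesh_core.build_index(curved_wall)
    t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    anchors = np.column_stack([13 * np.cos(t), 13 * np.sin(t), np.full(16, 2.0)])
    marked = pb.anchor_boundary(curved_wall, index, anchors)
    ring = pb.interpolate_ring(marked, n_samples=128, conform=True, index=index)
    assert ring.conformed
    for s in ring.samples:
        _, d = index.closest_surface_point(s)
        assert d < 1e-9
    assert ring.max_conform_residual < pb.DEFAULT_CONFORM_TOL


def test_interpolate_ring_requires_enough_samples(flat_wall, flat_wall_index, defect):
    stroke = syn.StrokeSpec(n_centers=24, jitter_sd=0.0, seed=0)
    centers = syn.generate_marking_stroke(flat_wall, defect, stroke)
    marked = pb.collect_boundary(flat_wall, flat_wall_index, centers, 3.0)
    with pytest.raises(ParameterError):
        pb.interpolate_ring(marked, n_samples=10)


# ---------------------------------------------------------------------------
# midpoint and normal
# ---------------------------------------------------------------------------


def test_ring_midpoint_planar_circle(circle_ring):
    mid, normal = pb.ring_midpoint(circle_ring)
    assert np.allclose(mid, 0.0, atol=1e-9)
    assert abs(abs(normal[2]) - 1.0) < 1e-9


def test_ring_midpoint_translation_equivariance(circle_ring):
    shift = np.array([5.0, -3.0, 7.0])
    shifted = pb.RingCurve(circle_ring.samples + shift, circle_ring.knots + shift)
    mid0, _ = pb.ring_midpoint(circle_ring)
    mid1, _ = pb.ring_midpoint(shifted)
    assert np.allclose(mid1 - mid0, shift, atol=1e-9)


def test_ring_midpoint_saddle_matches_pca_oracle():
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    samples = np.column_stack(
        [8 * np.cos(t), 8 * np.sin(t), (64 * np.cos(t) ** 2 - 64 * np.sin(t) ** 2) / 30]
    )
    ring = pb.RingCurve(samples, samples)
    mid, normal = pb.ring_midpoint(ring)
    assert np.allclose(mid, samples.mean(axis=0))
    cov = np.cov((samples - mid).T)
    w, v = np.linalg.eigh(cov)
    oracle = v[:, 0]  # smallest-variance axis
    assert abs(abs(normal @ oracle) - 1.0) < 1e-9


def test_ring_midpoint_sign_convention(circle_ring):
    _, n_up = pb.ring_midpoint(circle_ring, away_from=[0, 0, -10.0])
    _, n_down = pb.ring_midpoint(circle_ring, away_from=[0, 0, 10.0])
    assert n_up[2] > 0 > n_down[2]


def test_ring_midpoint_collinear_errors():
    pts = np.column_stack([np.linspace(0, 1, 8), np.zeros(8), np.zeros(8)])
    with pytest.raises(GeometryError):
        pb.ring_midpoint(pb.RingCurve(pts, pts))


# ---------------------------------------------------------------------------
# surface construction
# ---------------------------------------------------------------------------


def test_flat_disc_area(flat_disc_template):
    assert flat_disc_template.surface.area() == pytest.approx(np.pi * 100, rel=0.01)


def test_doming_strictly_increases_area(circle_ring):
    a0 = pb.build_surface(circle_ring, h=0.0).surface.area()
    a5 = pb.build_surface(circle_ring, h=5.0).surface.area()
    assert a5 > a0


def test_dome_and_saddle_curvature_signs(circle_ring):
    dome = pb.build_surface(circle_ring, h=5.0, normal_hint=[0, 0, 1])
    k_dome = pm.gaussian_curvature(dome.surface).values.mean()
    assert k_dome > 0
    t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    wavy = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 3 * np.sin(2 * t)])
    saddle = pb.build_surface(spline_ring(wavy), h=0.0)
    k_saddle = pm.gaussian_curvature(saddle.surface).values.mean()
    assert k_saddle < 0


def test_boundary_fidelity_bit_exact(circle_ring):
    tpl = pb.build_surface(circle_ring, h=3.0, n_spokes=64, n_rings=16)
    assert np.array_equal(tpl.surface.vertices[:64], tpl.ring.samples)
    # topological boundary of the surface = those first 64 vertices
    assert set(tpl.surface.boundary_vertices().tolist()) == set(range(64))


def test_flat_limit_stays_in_ring_plane(flat_disc_template):
    assert np.abs(flat_disc_template.surface.vertices[:, 2]).max() < 1e-6


def test_refinement_convergence(circle_ring):
    a1 = pb.build_surface(circle_ring, h=4.0, n_spokes=64, n_rings=16).surface.area()
    a2 = pb.build_surface(circle_ring, h=4.0, n_spokes=128, n_rings=32).surface.area()
    assert abs(a2 - a1) / a1 < 0.005


def test_rigid_invariance_of_patch_metrics():
    # elliptical ring: non-degenerate principal axes, so PCA diameters
    # are well-defined and must be bit-stable under rigid motion
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    knots = np.column_stack([12 * np.cos(t), 7 * np.sin(t), np.zeros(24)])
    ring = spline_ring(knots)
    tpl = pb.build_surface(ring, h=4.0, n_spokes=64, n_rings=16)

    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    shift = np.array([11.0, -7.0, 3.0])
    ring_r = spline_ring(knots @ q.T + shift)
    tpl_r = pb.build_surface(ring_r, h=4.0, n_spokes=64, n_rings=16)

    assert tpl_r.surface.area() == pytest.approx(tpl.surface.area(), rel=1e-9)
    d0 = pm.pca_diameters(tpl.surface)
    d1 = pm.pca_diameters(tpl_r.surface)
    assert d1 == pytest.approx(d0, rel=1e-9)
    k0 = pm.gaussian_curvature(tpl.surface).values.mean()
    k1 = pm.gaussian_curvature(tpl_r.surface).values.mean()
    assert abs(k1) == pytest.approx(abs(k0), rel=1e-6)


def test_build_surface_validation(circle_ring):
    with pytest.raises(ParameterError):
        pb.build_surface(circle_ring, n_spokes=2)


# ---------------------------------------------------------------------------
# solidify
# ---------------------------------------------------------------------------


def test_solidify_flat_disc_volume(flat_disc_template):
    solid = pb.solidify(flat_disc_template, thickness=1.0)
    area = flat_disc_template.surface.area()
    assert solid.shell.is_watertight()
    assert len(solid.shell.boundary_edges()) == 0
    assert solid.shell.euler_characteristic() == 2
    assert solid.shell.signed_volume() == pytest.approx(area * 1.0, rel=0.02)


def test_solidify_matches_trimesh_volume(flat_disc_template):
    """Cross-check the shell's volume and watertightness with trimesh."""
    import trimesh

    solid = pb.solidify(flat_disc_template, thickness=1.0)
    tm = trimesh.Trimesh(
        vertices=solid.shell.vertices, faces=solid.shell.triangles, process=False
    )
    assert tm.is_watertight
    assert tm.volume == pytest.approx(solid.shell.signed_volume(), rel=1e-9)


def test_solidify_refuses_folded_patch(flat_wall, flat_wall_index, defect):
    _, folded = folded_stroke_fixture(defect, flat_wall, flat_wall_index)
    marked = pb.collect_boundary(flat_wall, flat_wall_index, folded, 3.0)
    ring = pb.interpolate_ring(marked, n_samples=96)
    tpl = pb.build_surface(ring, h=4.0, n_spokes=96, n_rings=24, normal_hint=[0, 0, 1])
    with pytest.raises(ArtifactError) as err:
        pb.solidify(tpl, 1.0)
    assert err.value.intersecting_pairs


def test_solidify_validation(flat_disc_template):
    with pytest.raises(ParameterError):
        pb.solidify(flat_disc_template, thickness=0.0)


# ---------------------------------------------------------------------------
# self-intersection detection
# ---------------------------------------------------------------------------


def test_clean_dome_has_no_intersections(circle_ring):
    tpl = pb.build_surface(circle_ring, h=5.0, n_spokes=64, n_rings=16)
    assert pb.detect_self_intersections(tpl.surface) == []


@pytest.mark.parametrize("h", [0.0, 3.0], ids=["coplanar", "transversal"])
def test_self_crossing_knot_sequence_self_intersects(h):
    """A knot sequence that doubles back on itself (figure-eight-like
    traversal) pleats the surface into detectable self-intersections,
    both in the flat (coplanar-triangle) and domed (transversal) case."""
    knots = circle_knots(n=32)
    knots[10:14] = knots[10:14][::-1]  # reverse a contiguous arc
    ring = spline_ring(knots, n_samples=96)
    tpl = pb.build_surface(ring, h=h, n_spokes=96, n_rings=12)
    assert len(pb.detect_self_intersections(tpl.surface)) >= 1


def test_detection_matches_all_pairs_oracle(flat_wall, flat_wall_index, defect):
    """Culled detection equals exhaustive all-pairs testing on a folded
    patch small enough to brute-force."""
    _, folded = folded_stroke_fixture(defect, flat_wall, flat_wall_index)
    marked = pb.collect_boundary(flat_wall, flat_wall_index, folded, 3.0)
    ring = pb.interpolate_ring(marked, n_samples=48)
    tpl = pb.build_surface(ring, h=4.0, n_spokes=48, n_rings=12, normal_hint=[0, 0, 1])
    assert tpl.surface.n_triangles <= 2000
    got = pb.detect_self_intersections(tpl.surface)
    expect = oracle_all_pairs_intersections(tpl.surface)
    assert got == expect
    assert len(got) >= 1


def test_single_fold_changes_area_below_ten_percent(flat_wall, flat_wall_index, defect):
    clean, folded = folded_stroke_fixture(defect, flat_wall, flat_wall_index)
    areas = {}
    for name, centers in (("clean", clean), ("folded", folded)):
        marked = pb.collect_boundary(flat_wall, flat_wall_index, centers, 3.0)
        ring = pb.interpolate_ring(marked, n_samples=96)
        tpl = pb.build_surface(ring, h=4.0, n_spokes=96, n_rings=24, normal_hint=[0, 0, 1])
        areas[name] = tpl.surface.area()
        if name == "folded":
            assert len(pb.detect_self_intersections(tpl.surface)) >= 1
    rel_change = abs(areas["folded"] - areas["clean"]) / areas["clean"]
    assert rel_change < 0.10
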