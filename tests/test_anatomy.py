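import numpy as np
import pytest
import trimesh
from scipy.optimize import least_squares

from ossa.anatomy import (
    AnatomicalFrame,
    DegenerateFitError,
    Sphere,
    align_to_frame,
    build_femoral_frame,
    cut_partial_femur,
    cut_partial_tibia,
    estimate_anatomical_axis,
    fit_sphere,
    rigid_align_regions,
)
from ossa.geometry import rotation_about_axis
from ossa.mesh import TriangleMesh


def sphere_points(center, radius, n, rng=None, noise=0.0):
    if rng is None:
        # deterministic spiral points, exactly on the sphere
        k = np.arange(n)
        phi = np.arccos(1 - 2 * (k + 0.5) / n)
        theta = np.pi * (1 + 5**0.5) * k
        pts = np.column_stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])
    else:
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = center + radius * pts
    if noise and rng is not None:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestFitSphere:
    def test_exact_on_noiseless_points(self):
        pts = sphere_points((1.0, 2.0, 3.0), 5.0, 6)
        s = fit_sphere(pts)
        np.testing.assert_allclose(s.center, [1, 2, 3], atol=1e-9)
        assert s.radius == pytest.approx(5.0, abs=1e-9)
        assert s.rms < 1e-9

    def test_noisy_fit_matches_geometric_least_squares(self, rng):
        pts = sphere_points(np.zeros(3), 1.0, 500, rng=rng, noise=0.01)
        s = fit_sphere(pts, refine=True)
        # independent nonlinear least-squares oracle on the same points
        def resid(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        oracle = least_squares(resid, [0.1, -0.1, 0.1, 0.9]).x
        np.testing.assert_allclose(s.center, oracle[:3], atol=1e-6)
        assert s.radius == pytest.approx(oracle[3], abs=1e-6)
        assert np.linalg.norm(s.center) < 0.005

    def test_coplanar_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]])
        with pytest.raises(DegenerateFitError):
            fit_sphere(pts)

    def test_rigid_invariance(self, rng):
        pts = sphere_points((2.0, -1.0, 4.0), 3.0, 40, rng=rng, noise=0.005)
        R = rotation_about_axis([0.3, 0.5, 0.8], 0.7)
        t = np.array([5.0, -2.0, 1.0])
        s0 = fit_sphere(pts)
        s1 = fit_sphere(pts @ R.T + t)
        np.testing.assert_allclose(s1.center, R @ s0.center + t, atol=1e-8)
        assert s1.radius == pytest.approx(s0.radius, abs=1e-8)


def make_cylinder(length=100.0, radius=8.0, bend_deg=0.0, n_rings=25, n_seg=24):
    """Open tube of stacked symmetric rings along +y (exact rotational
    symmetry, so section centroids lie exactly on the axis)."""
    ys = np.linspace(-length / 2, length / 2, n_rings)
    ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    v = np.array([[radius * np.cos(a), y, radius * np.sin(a)] for y in ys for a in ang])
    f = []
    for r in range(n_rings - 1):
        for s in range(n_seg):
            a0, a1 = r * n_seg + s, r * n_seg + (s + 1) % n_seg
            b0, b1 = a0 + n_seg, a1 + n_seg
            f += [(a0, a1, b0), (a1, b1, b0)]
    f = np.array(f)
    if bend_deg:
        sel = v[:, 1] > 0
        R = rotation_about_axis([1.0, 0, 0], np.deg2rad(bend_deg))
        v = v.copy()
        v[sel] = v[sel] @ R.T
    return TriangleMesh(v, f)


class TestAnatomicalAxis:
    def test_straight_cylinder_axis(self):
        axis = estimate_anatomical_axis(make_cylinder())
        np.testing.assert_allclose(axis, [0, 1, 0], atol=1e-6)

    def test_bent_cylinder_matches_tls_oracle(self):
        mesh = make_cylinder(bend_deg=10.0)
        axis = estimate_anatomical_axis(mesh, shaft_fraction=(0.25, 0.75), n_sections=12)
        # oracle: total-least-squares line through the same section centroids
        v = mesh.vertices
        c = v - v.mean(0)
        _, _, Vt = np.linalg.svd(c, full_matrices=False)
        t = c @ Vt[0]
        lo, hi = t.min() + 0.25 * np.ptp(t), t.min() + 0.75 * np.ptp(t)
        edges = np.linspace(lo, hi, 13)
        cents = np.array([v[(t >= a) & (t < b)].mean(0) for a, b in zip(edges[:-1], edges[1:])])
        _, _, Vt2 = np.linalg.svd(cents - cents.mean(0), full_matrices=False)
        oracle = Vt2[0] * np.sign(Vt2[0][np.argmax(np.abs(Vt2[0]))])
        angle = np.degrees(np.arccos(np.clip(abs(axis @ oracle), -1, 1)))
        assert angle < 1.0

    def test_flat_disc_rejected(self):
        tm = trimesh.creation.cylinder(radius=20.0, height=1.0, sections=32)
        with pytest.raises(DegenerateFitError, match="elongation"):
            estimate_anatomical_axis(TriangleMesh.from_trimesh(tm))


class TestFemoralFrame:
    def test_orthogonal_inputs(self):
        f = build_femoral_frame(
            Sphere((0, 0, 10), 5.0), Sphere((0, 0, -10), 5.0), np.array([0.0, 1, 0]), "left"
        )
        np.testing.assert_allclose(f.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.y, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.z, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.x, [1, 0, 0], atol=1e-12)

    def test_oblique_axis_reorthogonalized_keeping_y(self):
        y_in = np.array([0.0, 0.9806, 0.1961])
        f = build_femoral_frame(Sphere((0, 0, 10), 5.0), Sphere((0, 0, -10), 5.0), y_in, "left")
        np.testing.assert_allclose(f.y, y_in / np.linalg.norm(y_in), atol=1e-12)
        G = f.axes @ f.axes.T
        assert np.abs(G - np.eye(3)).max() < 1e-9
        assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-9)
        # oracle: Gram-Schmidt of the inter-condylar direction against y
        y = y_in / np.linalg.norm(y_in)
        d = np.array([0.0, 0, 1.0])
        z = d - (d @ y) * y
        np.testing.assert_allclose(f.z, z / np.linalg.norm(z), atol=1e-9)

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateFitError):
            build_femoral_frame(Sphere((0, 0, 1), 5.0), Sphere((0, 0, 1), 5.0), np.array([0.0, 1, 0]), "left")

    def test_axis_near_intercondylar_line_rejected(self):
        with pytest.raises(DegenerateFitError, match="5 deg"):
            build_femoral_frame(
                Sphere((0, 0, 10), 5.0), Sphere((0, 0, -10), 5.0), np.array([0.0, 0.01, 1.0]), "left"
            )


class TestAlignment:
    def test_identity_frame_is_noop(self, tetrahedron):
        out = align_to_frame(tetrahedron, AnatomicalFrame.identity())
        np.testing.assert_allclose(out.vertices, tetrahedron.vertices, atol=1e-15)
        assert out.aligned

    def test_round_trip_and_distance_preservation(self, tetrahedron):
        frame = build_femoral_frame(
            Sphere((3, 1, 10), 5.0), Sphere((2, 0, -10), 5.0), np.array([0.1, 1.0, 0.05]), "right"
        )
        out = align_to_frame(tetrahedron, frame)
        back = frame.to_world(out.vertices)
        np.testing.assert_allclose(back, tetrahedron.vertices, atol=1e-9)
        d0 = np.linalg.norm(tetrahedron.vertices[0] - tetrahedron.vertices[1])
        d1 = np.linalg.norm(out.vertices[0] - out.vertices[1])
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_condyle_midpoint_lands_at_origin(self, rng):
        c_med, c_lat = np.array([4.0, -2.0, 11.0]), np.array([3.0, -1.0, -9.0])
        pts_med = sphere_points(c_med, 5.0, 30, rng=rng)
        pts_lat = sphere_points(c_lat, 5.0, 30, rng=rng)
        frame = build_femoral_frame(fit_sphere(pts_med), fit_sphere(pts_lat), np.array([0.0, 1, 0]), "left")
        s_med2 = fit_sphere(frame.to_local(pts_med))
        s_lat2 = fit_sphere(frame.to_local(pts_lat))
        np.testing.assert_allclose(0.5 * (s_med2.center + s_lat2.center), 0, atol=1e-9)


def aligned_block(y_lo=-50.0, y_hi=50.0):
    tm = trimesh.creation.box(extents=[20, y_hi - y_lo, 20])
    mesh = TriangleMesh.from_trimesh(tm.subdivide().subdivide())
    mesh.vertices[:, 1] += (y_hi + y_lo) / 2
    mesh.aligned = True
    return mesh


class TestPartialCuts:
    def test_distal_femur_cut_matches_vertex_filter(self):
        mesh = aligned_block(-50, 50)
        out = cut_partial_femur(mesh, "distal", Sphere((0, 0, 0), 10.0))
        assert out.vertices[:, 1].max() <= -10.0 + 1e-9
        assert out.vertices[:, 1].min() == pytest.approx(-50.0)
        # retained inter-vertex distances unchanged (pure subset)
        assert out.n_vertices == int((mesh.vertices[:, 1] <= -10).sum())

    def test_proximal_femur_cut(self):
        mesh = aligned_block(-50, 50)
        out = cut_partial_femur(mesh, "proximal", Sphere((0, 0, 0), 10.0))
        assert out.vertices[:, 1].min() >= 10.0 - 1e-9

    def test_cut_longer_than_bone_returns_whole_mesh_with_warning(self):
        mesh = aligned_block(-50, 50)
        with pytest.warns(UserWarning, match="exceeds bone length"):
            out = cut_partial_femur(mesh, "distal", Sphere((0, 0, 0), 30.0))
        assert out.n_vertices == mesh.n_vertices

    def test_unaligned_mesh_rejected(self, tetrahedron):
        with pytest.raises(ValueError, match="aligned"):
            cut_partial_femur(tetrahedron, "distal", Sphere((0, 0, 0), 10.0))

    def test_tibia_cut_retains_proximal_part(self):
        mesh = aligned_block(-100, 0)
        out = cut_partial_tibia(mesh, np.array([0.0, -20.0, 0.0]))
        assert out.vertices[:, 1].min() >= -20.0 - 1e-9

    def test_tibia_landmark_below_distal_end_keeps_all(self):
        mesh = aligned_block(-100, 0)
        out = cut_partial_tibia(mesh, np.array([0.0, -150.0, 0.0]))
        assert out.n_vertices == mesh.n_vertices

    def test_tibia_landmark_above_proximal_end_rejected(self):
        mesh = aligned_block(-100, 0)
        with pytest.raises(ValueError, match="empty"):
            cut_partial_tibia(mesh, np.array([0.0, 10.0, 0.0]))


class TestRegionalICP:
    def test_recovers_known_rotation(self, icosphere_coarse):
        src = TriangleMesh(icosphere_coarse.vertices + np.array([30.0, 0, 0]), icosphere_coarse.faces)
        R5 = rotation_about_axis([0.0, 0, 1.0], np.deg2rad(5.0))
        tgt = TriangleMesh(src.vertices @ R5.T, src.faces)
        (R, t), moved, rms = rigid_align_regions(src, tgt, np.arange(src.n_vertices))
        angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        assert abs(angle - 5.0) < 0.1
        assert rms < 1e-6

    def test_identity_for_identical_meshes(self, icosphere_coarse):
        (R, t), _, rms = rigid_align_regions(icosphere_coarse, icosphere_coarse, np.arange(40))
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0, atol=1e-9)
        assert rms < 1e-12

    def test_collinear_region_rejected(self, icosphere_coarse):
        src = TriangleMesh(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]), np.array([[0, 1, 2], [1, 2, 3]]))
        with pytest.raises(DegenerateFitError, match="collinear"):
            rigid_align_regions(src, icosphere_coarse, np.arange(4))
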