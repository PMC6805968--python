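"""Mesh container, PLY I/O and surface-distance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from meshreg.mesh_core import (MeshFormatError, MeshValidationError,
                               SurfaceSampling, TriMesh,
                               directed_mean_distance, distance_report,
                               hausdorff_distance, mean_bidirectional_distance,
                               nearest_point_on_surface, points_inside,
                               read_ply, validate_mesh, write_ply)
from conftest import (brute_force_closest, brute_force_directed_max,
                      brute_force_directed_mean, make_icosphere,
                      make_tetrahedron, random_blob)

VERTEX_SAMPLING = SurfaceSampling(0.0, True)


# ----------------------------------------------------------------------
# PLY I/O
# ----------------------------------------------------------------------

class TestPlyIO:
    def test_tetrahedron_roundtrip_exact(self, tetra, tmp_path):
        p = tmp_path / "tet.ply"
        write_ply(tetra, p)
        back = read_ply(p)
        assert back.n_vertices == 4 and back.n_faces == 4
        np.testing.assert_array_equal(back.vertices, tetra.vertices)
        np.testing.assert_array_equal(back.faces, tetra.faces)

    def test_roundtrip_preserves_full_float64_precision(self, tmp_path):
        m = random_blob(3)
        m = m.with_vertices(m.vertices + np.pi * 1e-8)
        p = tmp_path / "blob.ply"
        write_ply(m, p)
        back = read_ply(p)
        np.testing.assert_array_equal(back.vertices, m.vertices)

    def test_quad_face_rejected(self, tmp_path):
        p = tmp_path / "quad.ply"
        p.write_text(
            "ply\nformat ascii 1.0\nelement vertex 4\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 1\nproperty list uchar int vertex_indices\n"
            "end_header\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
        with pytest.raises(MeshFormatError, match="non-triangular"):
            read_ply(p)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("not a ply file\n")
        with pytest.raises(MeshFormatError):
            read_ply(p)

    def test_write_refuses_invalid_mesh(self, tetra, tmp_path):
        open_mesh = TriMesh(tetra.vertices, tetra.faces[:3])
        p = tmp_path / "bad.ply"
        with pytest.raises(MeshValidationError):
            write_ply(open_mesh, p)
        assert not p.exists()

    def test_binary_little_endian_read(self, tmp_path):
        m = make_icosphere(1, 5.0)
        p = tmp_path / "bin.ply"
        m.to_trimesh().export(p, encoding="binary")
        back = read_ply(p)
        np.testing.assert_allclose(back.vertices, m.vertices, atol=1e-5)
        np.testing.assert_array_equal(back.faces, m.faces)


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

class TestValidateMesh:
    def test_closed_meshes_pass(self, tetra):
        assert validate_mesh(tetra) == []
        assert validate_mesh(make_icosphere(2)) == []

    def test_missing_face_reports_boundary_edges(self, tetra):
        report = validate_mesh(TriMesh(tetra.vertices, tetra.faces[:3]))
        assert any("boundary edge" in d for d in report)

    def test_repeated_index_face_reports_degenerate(self, tetra):
        faces = tetra.faces.copy()
        faces[0] = [0, 0, 1]
        report = validate_mesh(TriMesh(tetra.vertices, faces))
        assert any("degenerate face" in d for d in report)

    def test_too_small_mesh(self):
        report = validate_mesh(TriMesh(np.zeros((3, 3)), np.array([[0, 1, 2]])))
        assert any("too few" in d for d in report)


# ----------------------------------------------------------------------
# Nearest point on surface
# ----------------------------------------------------------------------

class TestNearestPoint:
    def test_query_at_vertex_returns_vertex(self, sphere):
        q = sphere.vertices[17]
        point, d, face = nearest_point_on_surface(q, sphere)
        assert d == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(point, q, atol=1e-12)
        assert 17 in sphere.faces[face]

    def test_origin_to_unit_icosphere_matches_brute_force(self):
        m = make_icosphere(2, 1.0)
        _, d, _ = nearest_point_on_surface(np.zeros(3), m)
        expected = brute_force_closest(np.zeros((1, 3)), m)[0]
        assert d == pytest.approx(expected, abs=1e-12)
        assert d < 1.0  # chord sag pulls the surface inside the sphere

    def test_offset_along_face_normal(self, sphere):
        tri = sphere.triangles[40]
        centroid = tri.mean(axis=0)
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        n /= np.linalg.norm(n)
        q = centroid + 2.0 * n
        point, d, face = nearest_point_on_surface(q, sphere)
        assert d == pytest.approx(2.0, abs=1e-9)
        assert face == 40
        np.testing.assert_allclose(point, centroid, atol=1e-9)

    def test_random_queries_match_brute_force(self, sphere):
        rng = np.random.default_rng(0)
        q = rng.normal(scale=25.0, size=(60, 3))
        _, d, _ = sphere.proximity().query(q)
        np.testing.assert_allclose(d, brute_force_closest(q, sphere), atol=1e-9)


class TestPointsInside:
    def test_sphere_interior_and_exterior(self, sphere):
        assert points_inside(sphere, np.zeros((1, 3)))[0]
        assert not points_inside(sphere, np.array([[100.0, 0, 0]]))[0]


# ----------------------------------------------------------------------
# Distances vs independent brute force
# ----------------------------------------------------------------------

class TestDistances:
    def test_identical_meshes_are_zero(self, sphere):
        r = distance_report(sphere, sphere)
        assert r.mean_bidirectional == pytest.approx(0.0, abs=1e-12)
        assert r.hausdorff == pytest.approx(0.0, abs=1e-12)

    def test_translated_sphere_matches_brute_force(self):
        a = make_icosphere(2, 1.0)
        b = make_icosphere(2, 1.0, center=(0, 0, 3.0))
        s = SurfaceSampling(2.0, True)
        got = directed_mean_distance(a, b, s)
        assert got == pytest.approx(brute_force_directed_mean(a, b, s), abs=1e-9)
        assert hausdorff_distance(a, b, s) == pytest.approx(
            max(brute_force_directed_max(a, b, s),
                brute_force_directed_max(b, a, s)), abs=1e-9)

    def test_nested_spheres_asymmetry(self):
        small = make_icosphere(2, 1.0)
        large = make_icosphere(2, 2.0)
        s = SurfaceSampling(2.0, True)
        d_sl = directed_mean_distance(small, large, s)
        d_ls = directed_mean_distance(large, small, s)
        assert d_sl != pytest.approx(d_ls, abs=1e-6)
        assert d_sl == pytest.approx(brute_force_directed_mean(small, large, s), abs=1e-9)
        assert d_ls == pytest.approx(brute_force_directed_mean(large, small, s), abs=1e-9)
        assert mean_bidirectional_distance(small, large, s) == pytest.approx(
            0.5 * (d_sl + d_ls), abs=1e-12)

    def test_symmetry_and_hausdorff_dominates(self):
        pairs = [(random_blob(i), random_blob(i + 100)) for i in range(5)]
        for a, b in pairs:
            mbd = mean_bidirectional_distance(a, b)
            assert mbd == pytest.approx(mean_bidirectional_distance(b, a), abs=1e-12)
            h = hausdorff_distance(a, b)
            assert h == pytest.approx(hausdorff_distance(b, a), abs=1e-12)
            assert h >= mbd >= 0

    def test_triangle_inequality_spot_check(self):
        a, b, c = random_blob(1), random_blob(2), random_blob(3)
        s = SurfaceSampling(1.0, True)
        assert hausdorff_distance(a, c, s) <= (
            hausdorff_distance(a, b, s) + hausdorff_distance(b, c, s) + 1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), angle=st.floats(0, np.pi),
           tx=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, seed, angle, tx):
        """Applying one rigid transform to both meshes preserves distances."""
        a, b = random_blob(seed), random_blob(seed + 1)
        R = Rotation.from_rotvec(angle * np.array([0.3, -0.5, 0.81])).as_matrix()
        t = np.array([tx, 2.0, -1.0])
        a2 = a.with_vertices(a.vertices @ R.T + t)
        b2 = b.with_vertices(b.vertices @ R.T + t)
        assert mean_bidirectional_distance(a2, b2, VERTEX_SAMPLING) == pytest.approx(
            mean_bidirectional_distance(a, b, VERTEX_SAMPLING), abs=1e-6)
        assert hausdorff_distance(a2, b2, VERTEX_SAMPLING) == pytest.approx(
            hausdorff_distance(a, b, VERTEX_SAMPLING), abs=1e-6)


class TestSampling:
    def test_sampling_is_deterministic_and_dense_enough(self, sphere):
        s = SurfaceSampling(1.0, True)
        p1, p2 = s.sample(sphere), s.sample(sphere)
        np.testing.assert_array_equal(p1, p2)
        assert len(p1) >= sphere.n_vertices + sphere.area  # >= 1 sample/mm^2

    def test_zero_density_gives_vertices_only(self, sphere):
        np.testing.assert_array_equal(VERTEX_SAMPLING.sample(sphere),
                                      sphere.vertices)

    def test_face_samples_lie_on_surface(self, sphere):
        pts = SurfaceSampling(0.5, False).sample(sphere)
        _, d, _ = sphere.proximity().query(pts)
        assert d.max() < 1e-9
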