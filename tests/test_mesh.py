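"""Mesh structure, sphere generation, solid angles and file round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strecg.mesh import (
    MeshValidationError,
    SingularGeometryError,
    TriangleMesh,
    generate_sphere_mesh,
    read_mesh,
    solid_angle,
    solid_angles_batch,
    write_mesh,
)

FOUR_PI = 4.0 * np.pi


class TestSphereGeneration:
    def test_study_mesh_counts(self):
        m = generate_sphere_mesh(1.0, 184)
        assert (m.node_count, m.triangle_count, m.edge_count) == (184, 364, 546)
        assert m.euler_characteristic() == 2

    @pytest.mark.parametrize("radius,nodes", [(1.5, 184), (1.0, 64), (2.7, 257)])
    def test_vertices_on_sphere_and_closed(self, radius, nodes):
        m = generate_sphere_mesh(radius, nodes)
        np.testing.assert_allclose(np.linalg.norm(m.vertices, axis=1), radius,
                                   rtol=0, atol=radius * 1e-15)
        assert m.euler_characteristic() == 2
        assert m.triangle_count == 2 * nodes - 4
        assert m.signed_volume() > 0

    def test_generation_is_deterministic(self):
        a = generate_sphere_mesh(1.0, 96)
        b = generate_sphere_mesh(1.0, 96)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.triangles, b.triangles)

    def test_invalid_requests(self):
        with pytest.raises(ValueError):
            generate_sphere_mesh(-1.0, 64)
        with pytest.raises(ValueError):
            generate_sphere_mesh(1.0, 3)

    def test_neighbor_symmetry_and_edge_lengths(self, sphere64):
        for i in range(sphere64.node_count):
            for j in sphere64.neighbor(i):
                assert i in sphere64.neighbor(j)
                assert sphere64.edge_length(i, j) > 0
                assert sphere64.edge_length(i, j) == sphere64.edge_length(j, i)


class TestSolidAngle:
    def test_octant_triangle_from_origin(self):
        # the coordinate-plane unit triangle spans one octant: 4pi / 8
        tri = np.eye(3)
        assert solid_angle([0.0, 0.0, 0.0], tri) == pytest.approx(np.pi / 2, abs=1e-14)

    def test_orientation_flips_sign(self):
        tri = np.eye(3)
        assert solid_angle([0, 0, 0], tri[::-1]) == pytest.approx(-np.pi / 2, abs=1e-14)

    @given(st.tuples(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)))
    def test_closure_interior_point(self, point):
        mesh = generate_sphere_mesh(1.0, 64)
        total = solid_angles_batch(np.array([point]), mesh).sum()
        assert abs(total - FOUR_PI) < 1e-9

    @given(st.tuples(st.floats(1.5, 8.0), st.floats(0, 2 * np.pi), st.floats(-1, 1)))
    def test_closure_exterior_point(self, sph):
        r, phi, z = sph
        p = r * np.array([np.sqrt(1 - z**2) * np.cos(phi),
                          np.sqrt(1 - z**2) * np.sin(phi), z])
        mesh = generate_sphere_mesh(1.0, 64)
        assert abs(solid_angles_batch(p[None], mesh).sum()) < 1e-9

    def test_point_on_triangle_is_singular(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(SingularGeometryError):
            solid_angle([0.2, 0.2, 0.0], tri)
        with pytest.raises(SingularGeometryError):
            solid_angle([1.0, 0.0, 0.0], tri)


class TestMeshIO:
    def test_off_round_trip_is_bitwise(self, tmp_path, sphere64):
        path = tmp_path / "s.off"
        write_mesh(sphere64, path)
        back = read_mesh(path)
        assert np.array_equal(back.vertices, sphere64.vertices)
        assert np.array_equal(back.triangles, sphere64.triangles)

    def test_ply_round_trip(self, tmp_path, sphere64):
        path = tmp_path / "s.ply"
        write_mesh(sphere64, path)
        back = read_mesh(path)
        np.testing.assert_allclose(back.vertices, sphere64.vertices, atol=1e-6)
        assert np.array_equal(back.triangles, sphere64.triangles)

    def test_one_based_off_variant(self, tmp_path):
        tet = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
            np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]))
        path = tmp_path / "one.off"
        with open(path, "w") as fh:
            fh.write("OFF\n4 4 0\n")
            for v in tet.vertices:
                fh.write("%g %g %g\n" % tuple(v))
            for t in tet.triangles:
                fh.write("3 %d %d %d\n" % tuple(t + 1))  # 1-based dialect
        back = read_mesh(path, one_based=True)
        assert np.array_equal(back.triangles, tet.triangles)

    def test_open_mesh_rejected_with_boundary_edges(self, tmp_path):
        # single triangle: every edge is a boundary edge
        path = tmp_path / "open.off"
        with open(path, "w") as fh:
            fh.write("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
        with pytest.raises(MeshValidationError) as exc:
            read_mesh(path)
        assert len(exc.value.edges) == 3

    def test_degenerate_triangle_rejected(self):
        tris = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        good = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]), tris)
        good.validate()  # the tetrahedron is fine
        # vertex 3 collapsed onto the 0-1 edge: triangle (0, 1, 3) has zero area
        sliver = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.0, 0.0]]), tris)
        with pytest.raises(MeshValidationError, match="degenerate"):
            sliver.validate()
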