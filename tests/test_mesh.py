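"""Mesh generation, merging, volume audits, and order conversion."""

import numpy as np
import pytest

from spinefe import mesh as msh


@pytest.fixture(scope="module")
def unit_cube():
    return msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": 1, "ly": 1, "lz": 1}, 1.0))


class TestPrimitives:
    def test_box_volume_exact(self):
        m = msh.generate_primitive_mesh(
            msh.ShapeSpec("box", {"lx": 10, "ly": 10, "lz": 10}, 5.0)
        )
        v = msh.enclosed_volume(m.surface_sets["boundary"], m.nodes)
        assert v == pytest.approx(1000.0, abs=1e-9)

    def test_fusiform_shell_watertight(self):
        m = msh.generate_primitive_mesh(
            msh.ShapeSpec("fusiform_shell", {"length": 200, "max_radius": 20}, 5.0)
        )
        assert msh.surface_is_watertight(m.surface_sets["closed"])

    def test_cavity_wall_watertight(self):
        m = msh.generate_primitive_mesh(
            msh.ShapeSpec("cavity_wall", {"length": 150, "max_radius": 50}, 8.0)
        )
        assert msh.surface_is_watertight(m.surface_sets["closed"])

    def test_cylinder_volume_within_1_percent(self):
        m = msh.generate_primitive_mesh(
            msh.ShapeSpec("cylinder", {"radius": 10, "height": 10}, 1.0)
        )
        v = msh.enclosed_volume(m.surface_sets["boundary"], m.nodes)
        ref = np.pi * 100 * 10
        assert abs(v - ref) / ref < 0.01

    def test_deterministic(self):
        spec = msh.ShapeSpec("cylinder", {"radius": 8, "height": 12}, 3.0)
        a = msh.generate_primitive_mesh(spec)
        b = msh.generate_primitive_mesh(spec)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(
            a.block("cylinder").connectivity, b.block("cylinder").connectivity
        )

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            msh.ShapeSpec("box", {"lx": -1, "ly": 1, "lz": 1}, 0.5)

    def test_rejects_oversized_edge(self):
        with pytest.raises(ValueError):
            msh.ShapeSpec("box", {"lx": 1, "ly": 1, "lz": 1}, 2.0)

    def test_solid_tets_positive_volume(self, unit_cube):
        conn = unit_cube.block("box").connectivity
        x = unit_cube.nodes[conn]
        vols = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
        assert np.all(vols > 0)


class TestMerge:
    def test_two_cubes_sharing_face(self, unit_cube):
        # brute-force oracle: coordinate deduplication of 8 + 8 nodes
        other = unit_cube.translated((1, 0, 0))
        stacked = np.vstack([unit_cube.nodes, other.nodes])
        expected = len(np.unique(np.round(stacked, 9), axis=0))
        merged = msh.merge_coincident_nodes([unit_cube, other], 1e-6, names=["a", "b"])
        assert merged.n_nodes == expected == 12

    def test_disjoint_meshes_concatenate(self, unit_cube):
        other = unit_cube.translated((10, 0, 0))
        merged = msh.merge_coincident_nodes([unit_cube, other], 1e-6, names=["a", "b"])
        assert merged.n_nodes == 2 * unit_cube.n_nodes
        np.testing.assert_array_equal(
            merged.block("a_box").connectivity, unit_cube.block("box").connectivity
        )

    def test_zero_tolerance_exact_coincidence(self, unit_cube):
        other = unit_cube.translated((1, 0, 0))
        m0 = msh.merge_coincident_nodes([unit_cube, other], 0.0, names=["a", "b"])
        m1 = msh.merge_coincident_nodes([unit_cube, other], 1e-6, names=["a", "b"])
        assert m0.n_nodes == m1.n_nodes == 12

    def test_merge_idempotent(self, unit_cube):
        other = unit_cube.translated((1, 0, 0))
        merged = msh.merge_coincident_nodes([unit_cube, other], 1e-6)
        again = msh.merge_coincident_nodes([merged], 1e-6)
        assert again.n_nodes == merged.n_nodes
        np.testing.assert_allclose(again.nodes, merged.nodes)

    def test_same_source_duplicates_rejected(self):
        bad = msh.Mesh(
            np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            [msh.ElementBlock("m", "tri3_membrane", [[1, 2, 3]])],
        )
        with pytest.raises(ValueError, match="same source"):
            msh.merge_coincident_nodes([bad], 1e-6)

    def test_watertightness_preserved(self):
        shell = msh.generate_primitive_mesh(
            msh.ShapeSpec("fusiform_shell", {"length": 100, "max_radius": 15}, 6.0)
        )
        box = msh.generate_primitive_mesh(
            msh.ShapeSpec("box", {"lx": 10, "ly": 10, "lz": 10}, 5.0)
        ).translated((100, 0, 0))
        merged = msh.merge_coincident_nodes([shell, box], 1e-6, names=["s", "b"])
        assert msh.surface_is_watertight(merged.surface_sets["s_closed"])


class TestEnclosedVolume:
    def test_unit_cube_exact(self, unit_cube):
        v = msh.enclosed_volume(unit_cube.surface_sets["boundary"], unit_cube.nodes)
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_from_below(self):
        s = msh.icosphere(1.0, 3)
        v = msh.enclosed_volume(s.surface_sets["closed"], s.nodes)
        ref = 4 * np.pi / 3
        assert v < ref
        assert (ref - v) / ref < 0.01

    def test_translation_invariance(self, unit_cube):
        moved = unit_cube.translated((100, 100, 100))
        v0 = msh.enclosed_volume(unit_cube.surface_sets["boundary"], unit_cube.nodes)
        v1 = msh.enclosed_volume(moved.surface_sets["boundary"], moved.nodes)
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_rejects_open_surface(self, unit_cube):
        facets = unit_cube.surface_sets["boundary"][:-1]
        with pytest.raises(ValueError, match="watertight"):
            msh.enclosed_volume(facets, unit_cube.nodes)

    def test_rejects_inward_orientation(self, unit_cube):
        flipped = unit_cube.surface_sets["boundary"][:, [0, 2, 1]]
        with pytest.raises(ValueError, match="inward"):
            msh.enclosed_volume(flipped, unit_cube.nodes)

    def test_cylinder_convergence(self):
        # discretization deficit decreases monotonically with refinement
        errs = []
        for edge in (4.0, 2.0, 1.0):
            m = msh.generate_primitive_mesh(
                msh.ShapeSpec("cylinder", {"radius": 10, "height": 10}, edge)
            )
            v = msh.enclosed_volume(m.surface_sets["boundary"], m.nodes)
            errs.append(abs(v - np.pi * 1000) / (np.pi * 1000))
        assert errs[0] > errs[1] > errs[2]


class TestVolumeDiscrepancy:
    def test_zero(self):
        assert msh.volume_discrepancy(1000.0, 1000.0) == 0.0

    def test_reported_worst_case_value(self):
        assert msh.volume_discrepancy(938.3, 1000.0) == pytest.approx(6.17, abs=1e-12)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            msh.volume_discrepancy(1.0, 0.0)


class TestQuadraticConversion:
    def test_single_tet(self):
        m = msh.Mesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            [msh.ElementBlock("t", "tet4", [[0, 1, 2, 3]])],
        )
        q = msh.convert_to_quadratic(m)
        assert q.n_nodes == 10
        assert q.block("t").kind == "tet10"

    def test_two_tets_sharing_face(self):
        nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
        conn = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
        # brute-force unique-edge count oracle
        edges = set()
        for tet in conn:
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.add(tuple(sorted((tet[i], tet[j]))))
        m = msh.Mesh(nodes, [msh.ElementBlock("t", "tet4", conn)])
        q = msh.convert_to_quadratic(m)
        assert q.n_nodes == 5 + len(edges) == 14

    def test_volume_unchanged(self):
        m = msh.generate_primitive_mesh(
            msh.ShapeSpec("cylinder", {"radius": 8, "height": 10}, 3.0)
        )
        v0 = msh.enclosed_volume(m.surface_sets["boundary"], m.nodes)
        q = msh.convert_to_quadratic(m)
        bs = msh.boundary_surface(q.nodes, q.block("cylinder").connectivity)
        v1 = msh.enclosed_volume(bs, q.nodes)
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_rejects_membrane_only(self):
        m = msh.icosphere(1.0, 1)
        with pytest.raises(ValueError, match="tet4"):
            msh.convert_to_quadratic(m)

    def test_shared_mid_edge_nodes(self):
        m = msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": 2, "ly": 1, "lz": 1}, 1.0))
        q = msh.convert_to_quadratic(m)
        # every mid-edge node appears once: count unique edges by brute force
        conn = m.block("box").connectivity
        edges = set()
        for tet in conn:
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.add(tuple(sorted((tet[i], tet[j]))))
        assert q.n_nodes == m.n_nodes + len(edges)
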