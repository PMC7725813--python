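"""Solver and extractor verification: patch test, tangent consistency,
beam/Lamé oracles, equilibrium, strain objectivity."""

import numpy as np
import pytest
import scipy.sparse as sp

from spinefe import engine as eng
from spinefe import mesh as msh
from spinefe.materials import MaterialLaw


def _box_with_sets(lx, ly, lz, edge):
    m = msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": lx, "ly": ly, "lz": lz}, edge))
    n = m.nodes
    m.node_sets["x0"] = np.nonzero(np.abs(n[:, 0]) < 1e-9)[0]
    m.node_sets["x1"] = np.nonzero(np.abs(n[:, 0] - lx) < 1e-9)[0]
    m.node_sets["boundary"] = np.unique(m.surface_sets["boundary"])
    return m


class TestPatchTest:
    @pytest.mark.parametrize("order", [1, 2])
    def test_constant_strain_exact(self, order):
        m = _box_with_sets(2, 2, 2, 1.0)
        if order == 2:
            m = msh.convert_to_quadratic(m)
            bsurf = msh.boundary_surface(m.nodes, m.block("box").connectivity)
            # include mid-edge nodes of boundary faces
            conn = m.block("box").connectivity
            bn = set(np.unique(bsurf))
            edge_map = [(0, 1, 4), (1, 2, 5), (0, 2, 6), (0, 3, 7), (1, 3, 8), (2, 3, 9)]
            for row in conn:
                for i, j, k in edge_map:
                    if int(row[i]) in bn and int(row[j]) in bn:
                        bn.add(int(row[k]))
            m.node_sets["boundary"] = np.array(sorted(bn))
        A = np.array([[0.01, 0.002, 0.0], [0.001, -0.005, 0.003], [0.0, 0.002, 0.004]])
        ids = m.node_sets["boundary"]
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(
            dirichlet=[eng.PrescribedDisplacementBC("boundary", m.nodes[ids] @ A.T)],
            n_load_steps=1,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        np.testing.assert_allclose(sol.u, m.nodes @ A.T, atol=1e-12)
        sig = eng.block_stress(sol, "box")
        assert np.abs(sig - sig[0]).max() < 1e-10

    def test_zero_load(self):
        m = _box_with_sets(2, 2, 2, 1.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("boundary")])
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        assert np.abs(sol.u).max() == 0.0
        assert np.abs(sol.reactions).max() < 1e-12


class TestTangentConsistency:
    @pytest.mark.parametrize(
        "law",
        [
            MaterialLaw("linear_elastic", 100.0, 0.3),
            MaterialLaw("neo_hookean_incompressible", 5.0, 0.45),
            MaterialLaw("neo_hookean_incompressible", 5.0, 0.499),
        ],
        ids=["svk", "nh", "nh-nodal-pressure"],
    )
    def test_solid_fd(self, law):
        rng = np.random.default_rng(0)
        m = msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": 1, "ly": 1, "lz": 1}, 1.0))
        model = eng.Model(m, {"box": law})
        asm = eng._Assembler(model, eng.LoadCase())
        n = m.n_nodes
        u = 0.03 * rng.standard_normal(3 * n)
        _, trip, _, _, _ = asm.assemble(u, 1.0, True)
        K = sp.csr_matrix((trip[2], (trip[0], trip[1])), shape=(3 * n, 3 * n)).toarray()
        h = 1e-7
        cols = rng.choice(3 * n, 12, replace=False)
        for j in cols:
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            Rp, *_ = asm.assemble(up, 1.0, False)
            Rm, *_ = asm.assemble(um, 1.0, False)
            np.testing.assert_allclose(
                K[:, j], (Rp - Rm) / (2 * h), atol=1e-5 * max(1.0, np.abs(K).max())
            )

    def test_mixed_model_fd(self):
        # solid + membrane + bar + incompressible cavity in one tangent
        rng = np.random.default_rng(1)
        box = msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": 1, "ly": 1, "lz": 1}, 1.0))
        sph = msh.icosphere(1.0, 1)
        sph.blocks[0].name = "shell"
        sph.surface_sets = {"closed": sph.surface_sets["closed"]}
        sph = sph.translated((4, 0, 0))
        bar = msh.Mesh(
            np.array([[8.0, 0, 0], [9, 0, 0]]),
            [msh.ElementBlock("rod", "bar2", [[0, 1]])],
        )
        mm = msh.merge_coincident_nodes([box, sph, bar], 1e-9)
        from spinefe.cavity import CavitySpec

        model = eng.Model(
            mm,
            {
                "box": MaterialLaw("neo_hookean_incompressible", 1.0, 0.499),
                "shell": MaterialLaw("linear_elastic", 2.0, 0.3, thickness=0.1),
                "rod": MaterialLaw("linear_elastic", 10.0, 0.3),
            },
            [CavitySpec("ball", mm.surface_sets["closed"], "incompressible")],
            {"rod": 0.5},
        )
        asm = eng._Assembler(model, eng.LoadCase())
        nd = model.n_dofs
        u = 0.02 * rng.standard_normal(nd)
        _, trip, _, _, _ = asm.assemble(u, 1.0, True)
        K = sp.csr_matrix((trip[2], (trip[0], trip[1])), shape=(nd, nd)).toarray()
        h = 1e-7
        cols = rng.choice(nd, 15, replace=False)
        for j in cols:
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            Rp, *_ = asm.assemble(up, 1.0, False)
            Rm, *_ = asm.assemble(um, 1.0, False)
            fd = (Rp - Rm) / (2 * h)
            np.testing.assert_allclose(K[:, j], fd, atol=1e-6 * max(1.0, np.abs(K).max()))
        # multiplier coupling renders the tangent symmetric
        np.testing.assert_allclose(K, K.T, atol=1e-9 * np.abs(K).max())


class TestReactions:
    @pytest.fixture(scope="class")
    def bar_solution(self):
        m = _box_with_sets(10, 2, 2, 2.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 1000.0, 0.0)})
        lc = eng.LoadCase(
            dirichlet=[eng.FixedBC("x0")],
            nodal_forces=[eng.NodalForce("x1", (100.0, 0, 0))],
            n_load_steps=2,
        )
        return eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=2))

    def test_uniaxial_reaction(self, bar_solution):
        r = eng.reaction_force(bar_solution, "x0")
        np.testing.assert_allclose(r, [-100.0, 0.0, 0.0], atol=1e-8)

    def test_global_equilibrium(self, bar_solution):
        total = bar_solution.reactions.sum(axis=0) + bar_solution.external_force.sum(axis=0)
        assert np.abs(total).max() < 1e-8

    def test_rejects_unconstrained_set(self, bar_solution):
        with pytest.raises(ValueError, match="constrained"):
            eng.reaction_force(bar_solution, "x1")

    def test_symmetric_supports_share_load(self):
        m = _box_with_sets(8, 2, 2, 2.0)
        n = m.nodes
        m.node_sets["mid"] = np.nonzero(np.abs(n[:, 0] - 4) < 1e-9)[0]
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 1000.0, 0.3)})
        lc = eng.LoadCase(
            dirichlet=[eng.FixedBC("x0"), eng.FixedBC("x1")],
            nodal_forces=[eng.NodalForce("mid", (-10.0, 0, 0))],
            n_load_steps=1,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        r0 = eng.reaction_force(sol, "x0")
        r1 = eng.reaction_force(sol, "x1")
        # axial mid-span load on a both-ends-fixed bar: equal shares
        assert r0[0] == pytest.approx(r1[0], rel=5e-3)
        assert r0[0] + r1[0] == pytest.approx(10.0, rel=1e-9)


class TestBendingMoment:
    def test_arithmetic(self):
        assert eng.bending_moment(np.array([0, 100.0, 0]), 75.0) == pytest.approx(7.5)

    def test_zero_force(self):
        assert eng.bending_moment(np.array([5.0, 0.0, 3.0]), 50.0) == 0.0

    def test_linearity_in_arm(self):
        r = np.array([0, 40.0, 0])
        assert eng.bending_moment(r, 100.0) == pytest.approx(2 * eng.bending_moment(r, 50.0))

    def test_rejects_negative_arm(self):
        with pytest.raises(ValueError):
            eng.bending_moment(np.array([0, 1.0, 0]), -1.0)


class TestBeamOracle:
    def test_cantilever_tip_deflection(self):
        # slender cantilever vs Euler-Bernoulli P L^3 / (3 E I), tet10
        L, b, h, E, P = 100.0, 5.0, 5.0, 1000.0, 0.2
        m = msh.generate_primitive_mesh(msh.ShapeSpec("box", {"lx": L, "ly": b, "lz": h}, 2.5))
        mq = msh.convert_to_quadratic(m)
        n = mq.nodes
        mq.node_sets["root"] = np.nonzero(np.abs(n[:, 0]) < 1e-9)[0]
        mq.node_sets["tip"] = np.nonzero(np.abs(n[:, 0] - L) < 1e-9)[0]
        model = eng.Model(mq, {"box": MaterialLaw("linear_elastic", E, 0.0)})
        lc = eng.LoadCase(
            dirichlet=[eng.FixedBC("root")],
            nodal_forces=[eng.NodalForce("tip", (0, 0, P))],
            n_load_steps=1,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        tip = sol.u[mq.node_sets["tip"], 2].mean()
        ref = P * L**3 / (3 * E * (b * h**3 / 12))
        assert tip == pytest.approx(ref, rel=0.05)


class TestLameOracle:
    def test_inner_surface_normal_stress(self):
        # thick-walled cylinder under internal pressure: NS at the bore = p
        a, b, hgt, p = 10.0, 20.0, 3.0, 0.01
        nodes, tets = msh.extruded_annulus(a, b, 0.0, hgt, 1.0)
        bfaces = msh.boundary_surface(nodes, tets)
        x = nodes[bfaces]
        nvec = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        fc = x.mean(axis=1)
        rf = np.hypot(fc[:, 0], fc[:, 2])
        bore = bfaces[(rf < a * 1.02) & (np.abs(nvec[:, 1]) < 0.5)][:, [0, 2, 1]]
        m = msh.Mesh(nodes, [msh.ElementBlock("wall", "tet4", tets)])
        m.surface_sets["bore"] = bore
        m.node_sets["ends"] = np.nonzero(
            (np.abs(nodes[:, 1]) < 1e-9) | (np.abs(nodes[:, 1] - hgt) < 1e-9)
        )[0]
        m.node_sets["z0"] = np.nonzero(np.abs(nodes[:, 2]) < 1e-9)[0]
        m.node_sets["x0"] = np.nonzero(np.abs(nodes[:, 0]) < 1e-9)[0]
        model = eng.Model(m, {"wall": MaterialLaw("linear_elastic", 1000.0, 0.3)})
        lc = eng.LoadCase(
            dirichlet=[
                eng.FixedBC("ends", (1,), (0.0,)),
                eng.FixedBC("z0", (2,), (0.0,)),
                eng.FixedBC("x0", (0,), (0.0,)),
            ],
            surface_pressures=[eng.SurfacePressure("bore", p)],
            n_load_steps=1,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        ns = eng.surface_average_normal_stress(sol, "bore", block="wall")
        assert ns == pytest.approx(p, rel=0.02)

    def test_hydrostatic_block_any_surface(self):
        # uniformly pressurised annulus: NS equals the applied pressure
        nodes, tets = msh.extruded_annulus(10.0, 20.0, 0.0, 6.0, 3.0)
        bfaces = msh.boundary_surface(nodes, tets)[:, [0, 2, 1]]
        m = msh.Mesh(nodes, [msh.ElementBlock("wall", "tet4", tets)])
        m.surface_sets["all"] = bfaces
        m.node_sets["z0"] = np.nonzero(np.abs(nodes[:, 2]) < 1e-9)[0]
        m.node_sets["x0"] = np.nonzero(np.abs(nodes[:, 0]) < 1e-9)[0]
        m.node_sets["ymid"] = np.nonzero(np.abs(nodes[:, 1] - 3.0) < 1e-9)[0]
        model = eng.Model(m, {"wall": MaterialLaw("linear_elastic", 1000.0, 0.3)})
        p = 0.02
        lc = eng.LoadCase(
            dirichlet=[
                eng.FixedBC("ymid", (1,), (0.0,)),
                eng.FixedBC("z0", (2,), (0.0,)),
                eng.FixedBC("x0", (0,), (0.0,)),
            ],
            surface_pressures=[eng.SurfacePressure("all", p)],
            n_load_steps=1,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        sig = eng.block_stress(sol, "wall")
        assert np.abs(sig - (-p * np.eye(3))).max() < 1e-10
        ns = eng.surface_average_normal_stress(sol, "all", block="wall")
        assert ns == pytest.approx(p, rel=1e-6)

    def test_stress_free_body_zero(self):
        m = _box_with_sets(4, 2, 2, 2.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("x0")], n_load_steps=1)
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        ns = eng.surface_average_normal_stress(sol, "boundary", block="box")
        assert abs(ns) < 1e-12

    def test_empty_surface_rejected(self):
        m = _box_with_sets(4, 2, 2, 2.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("x0")], n_load_steps=1)
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        with pytest.raises(ValueError, match="empty"):
            eng.surface_average_normal_stress(sol, np.zeros((0, 3), dtype=int))


class TestStrainExtraction:
    def test_rigid_rotation_objective(self):
        m = _box_with_sets(4, 2, 2, 2.0)
        m.node_sets["all"] = np.arange(m.n_nodes)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(
            dirichlet=[eng.RigidRotationBC("all", (0, 0, 1), (2.0, 1.0, 1.0), 35.0)],
            n_load_steps=2,
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=2))
        assert eng.max_principal_strain(sol, "box") == pytest.approx(0.0, abs=1e-10)

    def test_uniaxial_stretch_green_lagrange(self):
        m = _box_with_sets(4, 2, 2, 2.0)
        m.node_sets["all"] = np.arange(m.n_nodes)
        lam = 1.1
        vals = np.zeros((m.n_nodes, 3))
        vals[:, 0] = (lam - 1) * m.nodes[:, 0]
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(
            dirichlet=[eng.PrescribedDisplacementBC("all", vals)], n_load_steps=1
        )
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        assert eng.max_principal_strain(sol, "box") == pytest.approx(
            (lam**2 - 1) / 2, rel=1e-10
        )

    def test_unknown_block(self):
        m = _box_with_sets(4, 2, 2, 2.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("x0")], n_load_steps=1)
        sol = eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))
        with pytest.raises(KeyError):
            eng.max_principal_strain(sol, "nope")


class TestSolverErrors:
    def test_singular_without_constraints(self):
        m = _box_with_sets(2, 2, 2, 1.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(nodal_forces=[eng.NodalForce("x1", (1.0, 0, 0))])
        with pytest.raises(eng.SingularSystemError):
            eng.solve_static(model, lc, eng.SolverOptions(n_load_steps=1))

    def test_schedule_validation(self):
        m = _box_with_sets(2, 2, 2, 1.0)
        model = eng.Model(m, {"box": MaterialLaw("linear_elastic", 100.0, 0.3)})
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("x0")], schedule=[0.5, 0.2])
        with pytest.raises(ValueError, match="increasing"):
            eng.solve_static(model, lc)
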