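"""Synthetic assemblies: tissue tables, build invariants, force cases."""

import numpy as np
import pytest

from spinefe import anatomy as anat
from spinefe import engine as eng
from spinefe import mesh as msh


class TestDefaultMaterials:
    def test_lumbar_table_values(self):
        t = anat.default_materials("lumbar_test")
        assert t["vertebra"].E == 12000.0 and t["vertebra"].nu == 0.3
        assert t["ivd"].E == 42.7 and t["ivd"].nu == 0.499
        assert t["psoas"].E == 0.52 and t["psoas"].nu == 0.499
        assert t["psoas"].thickness == 2.73
        assert t["tendon"].E == 1000.0
        assert t["annulus"].E == 8.0 and t["annulus"].nu == 0.45
        assert t["nucleus_shell"].E == 1.0 and t["nucleus_shell"].nu == 0.49
        assert t["nucleus_shell"].thickness == 1.0

    def test_full_spine_table_values(self):
        t = anat.default_materials("full_spine_test")
        assert t["tlf"].E == 450.0 and t["tlf"].nu == 0.499
        assert t["abdominal_wall"].E == pytest.approx(0.025)
        assert t["abdominal_wall"].nu == 0.45
        assert t["abdominal_wall"].thickness == 9.7
        assert t["multifidus"].E == pytest.approx(0.03687)
        assert t["longissimus"].thickness == 4.03
        assert t["intertransversarius"].thickness == 1.0

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            anat.default_materials("cervical")


class TestMuscleForceCases:
    def test_case_0(self):
        c = anat.muscle_force_case(0)
        assert c.forces == {
            "longissimus": 210.0,
            "multifidus": 71.0,
            "psoas": 275.0,
            "intertransversarius": 25.0,
        }
        assert c.expected_t1_load == 382.0

    def test_case_1(self):
        c = anat.muscle_force_case(1)
        assert c.forces == {
            "longissimus": 30.0,
            "multifidus": 15.0,
            "psoas": 40.0,
            "intertransversarius": 5.0,
        }

    def test_case_5(self):
        c = anat.muscle_force_case(5)
        assert c.forces["longissimus"] == 198.0
        assert c.forces["psoas"] == 260.0
        assert c.expected_t1_load == 346.0

    def test_rejects_unknown(self):
        with pytest.raises(ValueError):
            anat.muscle_force_case(6)


@pytest.fixture(scope="module")
def lumbar_full():
    return anat.build_lumbar_model(
        anat.AnatomyParams(), include_psoas=True, two_phase_ivd5=True
    )


class TestLumbarBuild:
    def test_block_layout(self, lumbar_full):
        names = lumbar_full.mesh.block_names()
        for lvl in ("L1", "L2", "L3", "L4", "L5", "sacrum", "annulus5", "nucleus5"):
            assert lvl in names

    def test_merge_is_noop(self, lumbar_full):
        merged = msh.merge_coincident_nodes([lumbar_full.mesh], 1e-6)
        assert merged.n_nodes == lumbar_full.mesh.n_nodes

    def test_cavities_watertight_with_positive_volume(self, lumbar_full):
        for c in lumbar_full.cavities:
            assert msh.surface_is_watertight(c.facets)
            assert lumbar_full.reference_volumes[c.name] > 0

    def test_all_blocks_materialized(self, lumbar_full):
        for b in lumbar_full.mesh.blocks:
            assert b.name in lumbar_full.materials

    def test_solvable_under_zero_load(self, lumbar_full):
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("sacrum")], n_load_steps=1)
        sol = eng.solve_static(
            lumbar_full, lc, eng.SolverOptions(n_load_steps=1, stabilization=1e-8)
        )
        assert np.abs(sol.u).max() < 1e-9
        for st in sol.cavity_states.values():
            assert st.pressure == pytest.approx(0.0, abs=1e-10)

    def test_nucleus_material_present(self, lumbar_full):
        law = lumbar_full.materials["nucleus5"]
        assert law.E == 1.0 and law.nu == 0.49 and law.thickness == 1.0

    def test_part_volumes_near_parametric_targets(self, lumbar_full):
        params = lumbar_full.info["params"]
        refs = anat.analytic_part_volumes(params)
        bdata = {bd.name: bd for bd in eng._build_block_data(lumbar_full)}
        v_l3 = bdata["L3"].volumes().sum()
        assert abs(v_l3 - refs["L3"]) / refs["L3"] < 0.2

    def test_two_phase_requires_lumbosacral_disc(self):
        params = anat.AnatomyParams(include_lumbosacral_ivd=False)
        with pytest.raises(ValueError):
            anat.build_lumbar_model(params, two_phase_ivd5=True)


class TestFullSpineBuild:
    @pytest.fixture(scope="class")
    def bare(self):
        return anat.build_full_spine_model(anat.AnatomyParams(edge_length=7.0))

    def test_counts(self, bare):
        assert len(bare.info["vertebrae"]) == 17
        assert len(bare.info["ivds"]) == 16

    def test_bare_has_no_cavities(self, bare):
        assert bare.cavities == []

    def test_full_model_cavities(self):
        model = anat.build_full_spine_model(
            anat.AnatomyParams(edge_length=7.0, muscle_edge_length=12.0),
            muscles=True,
            tlf=True,
            abdominal_cavity=True,
        )
        names = {c.name for c in model.cavities}
        assert "abdomen" in names
        assert sum(1 for n in names if n != "abdomen") == 10  # 5 bilateral pairs
        for c in model.cavities:
            assert msh.surface_is_watertight(c.facets)
        assert any(b.name == "tlf_sheet" for b in model.mesh.blocks)
        assert model.info["tlf_anchor_levels"]


class TestFlexionDrive:
    def test_predictor_matches_targets_on_driven_sets(self, lumbar_full):
        bc, pred = anat.lumbar_flexion_bc(lumbar_full, 30.0)
        lc = eng.LoadCase(dirichlet=[eng.FixedBC("sacrum"), bc])
        mask, target = eng._prescribed(lumbar_full, lc)
        for s in (0.3, 1.0):
            tv = target(s)
            up = pred(s)
            n = lumbar_full.mesh.n_nodes
            for lvl in ("L1", "L3", "L5"):
                ids = lumbar_full.mesh.node_sets[lvl]
                want = tv[: 3 * n].reshape(n, 3)[ids]
                np.testing.assert_allclose(up[ids], want, atol=1e-9)

    def test_zero_angle_identity(self, lumbar_full):
        bc, pred = anat.lumbar_flexion_bc(lumbar_full, 25.0)
        assert np.abs(pred(0.0)).max() < 1e-12
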