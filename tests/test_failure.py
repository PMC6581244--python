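"""Strain-limit failure criterion, capacity scaling and epiphysis limits."""

import numpy as np
import pytest

from infantfem import anatomy as an
from infantfem import failure as fl
from infantfem import materials as mat
from infantfem import mesh as mm
from infantfem import solver as sv


def _scaled_materials(mats, factor):
    out = mat.MaterialField(
        kind=mats.kind.copy(), E=mats.E.copy(), nu=mats.nu.copy(),
        C10=mats.C10.copy(), D1=mats.D1.copy(),
    )
    epi = out.kind == mat.KIND_NEO_PORO
    out.E[epi] *= factor
    out.C10[epi] *= factor
    out.D1[epi] /= factor
    return out


@pytest.fixture(scope="module")
def shaft_setup(phantom_4mo, mesh_4mo, materials_4mo, frame_4mo):
    """Shared geometry for the degenerate-epiphysis limit studies."""
    _, _, lm = phantom_4mo
    mesh = mesh_4mo
    sub, elem_ids, node_map = mm.extract_region_submesh(mesh, mm.REGION_DIAPHYSIS)
    mats_sub = mat.MaterialField(
        kind=materials_4mo.kind[elem_ids], E=materials_4mo.E[elem_ids],
        nu=materials_4mo.nu[elem_ids], C10=materials_4mo.C10[elem_ids],
        D1=materials_4mo.D1[elem_ids],
    )
    epi_nodes = np.unique(mesh.connectivity[mesh.element_region == mm.REGION_EPIPHYSIS])
    dia_nodes = np.unique(mesh.connectivity[mesh.element_region == mm.REGION_DIAPHYSIS])
    iface = np.intersect1d(epi_nodes, dia_nodes)
    fixed = np.flatnonzero(
        np.abs((mesh.node_coords - lm.point2) @ frame_4mo.X) <= 3.0
    )
    return {
        "lm": lm, "mesh": mesh, "sub": sub, "node_map": node_map,
        "mats_sub": mats_sub, "iface": iface, "fixed": fixed,
        "fixed_sub": node_map[fixed][node_map[fixed] >= 0],
        "dia_nodes": dia_nodes,
    }


class TestStrainExtrema:
    def test_zero_load_field(self, mesh_4mo):
        sol = sv.SolutionField(
            np.zeros((mesh_4mo.n_nodes, 3)), np.zeros((mesh_4mo.n_elements, 6)),
            np.zeros((mesh_4mo.n_elements, 3)),
        )
        e1, e3, _, _ = fl.strain_extrema(sol, np.ones(mesh_4mo.n_elements, bool))
        assert e1 == 0.0 and e3 == 0.0

    def test_imposed_uniaxial_strain(self, single_tet):
        mf = mat.uniform_material(single_tet, 100.0, 0.0)
        x = single_tet.node_coords
        pres = {(n, c): (0.01 * x[n, 0] if c == 0 else 0.0)
                for n in range(single_tet.n_nodes) for c in range(3)}
        sol = sv.solve_static(single_tet, mf, sv.BoundaryConditions(prescribed=pres))
        e1, _, _, _ = fl.strain_extrema(sol, np.ones(1, bool))
        assert abs(e1 - 0.01) < 1e-12

    def test_empty_mask_rejected(self, torsion_4mo):
        _, sol = torsion_4mo
        with pytest.raises(ValueError, match="empty"):
            fl.strain_extrema(sol, np.zeros(len(sol.element_strain), bool))

    def test_torsion_extremum_on_outer_surface(self):
        mesh = mm.structured_cylinder_mesh(5.0, 40.0, 8, 8)
        mf = mat.uniform_material(mesh, 5000.0, 0.3)
        x = mesh.node_coords
        fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
        end = np.flatnonzero(np.abs(x[:, 0] - 40.0) < 1e-9)
        c = sv.RigidCoupling(end, np.array([40.0, 0, 0]), moment=np.array([500.0, 0, 0]))
        sol = sv.StaticSolver(mesh, mf).solve(
            sv.BoundaryConditions(fixed_nodes=fixed, couplings=[c])
        )
        cen = mesh.element_centroids()
        mid = np.abs(cen[:, 0] - 20.0) < 8.0
        _, _, i1, _ = fl.strain_extrema(sol, mid)
        r = np.hypot(cen[:, 1], cen[:, 2])
        assert r[i1] > 0.8 * r[mid].max()


class TestLoadToFail:
    def test_probe_load_invariance(self, phantom_4mo, mesh_4mo, frame_4mo, solver_4mo):
        _, _, lm = phantom_4mo
        crit = fl.FailureCriterion()
        caps = []
        for mag in (500.0, 2000.0):
            bcs = an.make_load_case(frame_4mo, lm, mesh_4mo, "torsion", magnitude=mag)
            sol = solver_4mo.solve(bcs)
            caps.append(fl.load_to_fail(mesh_4mo, sol, crit, mag).load_to_fail)
        assert abs(caps[0] - caps[1]) <= 1e-8 * caps[1]

    def test_scaling_identity(self, mesh_4mo, torsion_4mo):
        _, sol = torsion_4mo
        crit = fl.FailureCriterion()
        res = fl.load_to_fail(mesh_4mo, sol, crit, 2000.0)
        mask = fl.criterion_mask(mesh_4mo, crit)
        e1, e3, _, _ = fl.strain_extrema(sol, mask)
        expect = 2000.0 * min(crit.tensile_limit / e1,
                              crit.compressive_limit / abs(e3))
        assert res.load_to_fail == pytest.approx(expect, rel=1e-12)
        assert res.limiting_mode in ("tension", "compression")

    def test_masking_monotonicity(self, mesh_4mo, torsion_4mo):
        _, sol = torsion_4mo
        dia = fl.load_to_fail(mesh_4mo, sol, fl.FailureCriterion(), 2000.0)
        allm = fl.load_to_fail(
            mesh_4mo, sol, fl.FailureCriterion(region_mask="all"), 2000.0
        )
        assert allm.load_to_fail <= dia.load_to_fail

    def test_zero_strain_flagged_infinite(self, mesh_4mo):
        sol = sv.SolutionField(
            np.zeros((mesh_4mo.n_nodes, 3)), np.zeros((mesh_4mo.n_elements, 6)),
            np.zeros((mesh_4mo.n_elements, 3)),
        )
        res = fl.load_to_fail(mesh_4mo, sol, fl.FailureCriterion(), 100.0)
        assert np.isinf(res.load_to_fail)

    def test_bisection_matches_linear_scaling_at_small_strain(self):
        mesh = mm.structured_box_mesh((20, 4, 4), (5, 2, 2))
        mf = mat.uniform_material(mesh, 800.0, 0.2, kind=mat.KIND_NEO_PORO)
        mf.kind[:] = mat.KIND_NEO_PORO
        x = mesh.node_coords
        fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
        end = np.flatnonzero(np.abs(x[:, 0] - 20.0) < 1e-9)
        f = np.tile([0.0, 0.02, 0.0], (end.size, 1))
        bcs = sv.BoundaryConditions(fixed, end, f)
        crit = fl.FailureCriterion(region_mask="all")
        lin = fl.load_to_fail(
            mesh, sv.solve_static(mesh, mf, bcs), crit, 1.0
        )
        nonlin = fl.load_to_fail_nonlinear(mesh, mf, bcs, crit, 1.0)
        assert abs(nonlin.load_to_fail - lin.load_to_fail) / lin.load_to_fail < 0.02


class TestEpiphysisLimits:
    def test_rigid_epiphysis_equals_rigid_section_oracle(
        self, shaft_setup, materials_4mo, frame_4mo
    ):
        s = shaft_setup
        T = 2000.0
        crit = fl.FailureCriterion()
        stiff = _scaled_materials(materials_4mo, 1e8)
        patch = np.flatnonzero(
            np.linalg.norm(s["mesh"].node_coords - s["lm"].point1, axis=1) <= 3.0
        )
        bcs = sv.BoundaryConditions(
            fixed_nodes=s["fixed"],
            couplings=[sv.RigidCoupling(patch, s["lm"].point1,
                                        moment=T * frame_4mo.X)],
        )
        full = sv.StaticSolver(s["mesh"], stiff).solve(bcs)
        cap_full = fl.load_to_fail(s["mesh"], full, crit, T).load_to_fail
        iface_sub = s["node_map"][s["iface"]]
        bcs_o = sv.BoundaryConditions(
            fixed_nodes=s["fixed_sub"],
            couplings=[sv.RigidCoupling(iface_sub, s["lm"].point1,
                                        moment=T * frame_4mo.X)],
        )
        oracle = sv.StaticSolver(s["sub"], s["mats_sub"]).solve(bcs_o)
        cap_o = fl.load_to_fail(
            s["sub"], oracle, fl.FailureCriterion(exclude_interface_layer=False),
            T, exclude_nodes=iface_sub,
        ).load_to_fail
        assert abs(cap_full - cap_o) / cap_o < 0.01

    def test_soft_epiphysis_equals_free_end_oracle(
        self, shaft_setup, materials_4mo, frame_4mo
    ):
        s = shaft_setup
        T = 2000.0
        crit = fl.FailureCriterion()
        soft = _scaled_materials(materials_4mo, 1e-8)
        t_n = (s["mesh"].node_coords - frame_4mo.origin) @ frame_4mo.X
        t_if = t_n[s["iface"]].mean()
        on_dia = np.isin(np.arange(s["mesh"].n_nodes), s["dia_nodes"])
        sec = np.flatnonzero(on_dia & (np.abs(t_n - (t_if + 15.0)) <= 1.5))
        ref = s["mesh"].node_coords[sec].mean(axis=0)
        bcs = sv.BoundaryConditions(
            fixed_nodes=s["fixed"],
            couplings=[sv.RigidCoupling(sec, ref, moment=T * frame_4mo.X)],
        )
        full = sv.StaticSolver(s["mesh"], soft).solve(bcs)
        cap_full = fl.load_to_fail(s["mesh"], full, crit, T,
                                   exclude_nodes=sec).load_to_fail
        sec_sub = s["node_map"][sec]
        bcs_o = sv.BoundaryConditions(
            fixed_nodes=s["fixed_sub"],
            couplings=[sv.RigidCoupling(sec_sub, ref, moment=T * frame_4mo.X)],
        )
        oracle = sv.StaticSolver(s["sub"], s["mats_sub"]).solve(bcs_o)
        cap_o = fl.load_to_fail(
            s["sub"], oracle,
            fl.FailureCriterion(exclude_interface_layer=False), T,
            exclude_nodes=np.concatenate([sec_sub, s["node_map"][s["iface"]]]),
        ).load_to_fail
        assert abs(cap_full - cap_o) / cap_o < 0.01


def test_transition_concentration_reported(mesh_4mo, torsion_4mo):
    _, sol = torsion_4mo
    rep = fl.transition_concentration(mesh_4mo, sol, slab_width=5.0)
    assert rep["n_transition_elements"] > 0
    assert rep["transition_max_eps1"] > rep["shaft_median_eps1"]
    assert rep["concentrated"]
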