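"""Linear and hyperelastic solver: oracles, invariances, convergence."""

import numpy as np
import pytest

from infantfem import materials as mat
from infantfem import mesh as mm
from infantfem import solver as sv
from infantfem import verification as vf


def _duffy_rule(n=8):
    """Tensor Gauss-Legendre on the reference tetrahedron (Duffy map)."""
    xg, wg = np.polynomial.legendre.leggauss(n)
    x = 0.5 * (xg + 1.0)
    w = 0.5 * wg
    pts, wts = [], []
    for iu, u in enumerate(x):
        for iv, v in enumerate(x):
            for iw, wq in enumerate(x):
                xi = u
                eta = v * (1 - u)
                zeta = wq * (1 - u) * (1 - v)
                jac = (1 - u) ** 2 * (1 - v)
                pts.append((1 - xi - eta - zeta, xi, eta, zeta))
                wts.append(w[iu] * w[iv] * w[iw] * jac)
    return np.array(pts), np.array(wts)


def _tet10_shape(bary):
    """Hand-coded textbook TET10 shape functions (dtype-preserving)."""
    L0, L1, L2, L3 = (bary[..., i] for i in range(4))
    cols = [L0 * (2 * L0 - 1), L1 * (2 * L1 - 1), L2 * (2 * L2 - 1),
            L3 * (2 * L3 - 1), 4 * L0 * L1, 4 * L1 * L2, 4 * L2 * L0,
            4 * L0 * L3, 4 * L1 * L3, 4 * L2 * L3]
    return np.stack(cols, axis=-1)


def _complex_step_gradients(bary):
    """dN/d(xi,eta,zeta) via complex-step differentiation of N itself."""
    h = 1e-30
    out = np.zeros(bary.shape[:-1] + (10, 3))
    for k in range(3):  # xi, eta, zeta = L1, L2, L3; L0 = 1 - sum
        b = bary.astype(complex).copy()
        b[..., k + 1] += 1j * h
        b[..., 0] -= 1j * h
        out[..., k] = _tet10_shape(b).imag / h
    return out


def test_single_tet_stiffness_vs_bruteforce(single_tet):
    """Assembly equals an independent dense-quadrature B-matrix integration."""
    E, nu = 1.0, 0.0
    mf = mat.uniform_material(single_tet, E, nu)
    K = sv.assemble_linear(single_tet, mf).toarray()
    pts, wts = _duffy_rule(8)
    dN = _complex_step_gradients(pts)  # reference == physical for this tet
    D = np.zeros((6, 6))
    D[:3, :3] = np.eye(3) * E  # nu = 0: lambda = 0, 2 mu = E
    D[3:, 3:] = np.eye(3) * E / 2.0
    Ko = np.zeros((30, 30))
    for q in range(len(wts)):
        B = np.zeros((6, 30))
        g = dN[q]
        B[0, 0::3] = g[:, 0]
        B[1, 1::3] = g[:, 1]
        B[2, 2::3] = g[:, 2]
        B[3, 0::3], B[3, 1::3] = g[:, 1], g[:, 0]
        B[4, 1::3], B[4, 2::3] = g[:, 2], g[:, 1]
        B[5, 0::3], B[5, 2::3] = g[:, 2], g[:, 0]
        Ko += wts[q] * B.T @ D @ B
    # map the element-local (edge-ordered) oracle onto global node numbering
    perm = single_tet.connectivity[0]
    dof = (perm[:, None] * 3 + np.arange(3)).ravel()
    Kg = np.zeros((30, 30))
    Kg[np.ix_(dof, dof)] = Ko
    assert np.abs(K - Kg).max() < 1e-12


def test_rigid_body_null_modes(mesh_4mo, materials_4mo, solver_4mo):
    K = solver_4mo.K
    scale = np.abs(K).max()
    t = np.tile([1.0, 0.0, 0.0], mesh_4mo.n_nodes)
    assert np.abs(K @ t).max() <= 1e-10 * scale
    rot = np.cross(np.array([0.2, -0.5, 1.0]), mesh_4mo.node_coords).ravel()
    assert np.abs(K @ rot).max() <= 1e-10 * scale * np.abs(rot).max()


def test_linear_patch_test_to_1e10():
    r = vf.linear_patch_test()
    assert r["max_displacement_error"] < 1e-10
    assert r["max_strain_error"] < 1e-10


def test_quadratic_patch_test():
    r = vf.quadratic_patch_test()
    assert r["max_displacement_error"] < 1e-10


def test_under_constrained_rejected(single_tet):
    mf = mat.uniform_material(single_tet, 1.0, 0.2)
    with pytest.raises(ValueError, match="constrain"):
        sv.solve_static(single_tet, mf, sv.BoundaryConditions())


def test_linearity_in_load(single_tet):
    mf = mat.uniform_material(single_tet, 100.0, 0.25)
    loaded = np.array([3])
    f = np.array([[0.1, -0.2, 0.3]])
    fixed = np.array([0, 1, 2])
    s1 = sv.solve_static(single_tet, mf, sv.BoundaryConditions(fixed, loaded, f))
    s2 = sv.solve_static(single_tet, mf, sv.BoundaryConditions(fixed, loaded, 3.0 * f))
    assert np.allclose(3.0 * s1.nodal_displacements, s2.nodal_displacements,
                       rtol=1e-12, atol=1e-15)
    assert np.allclose(3.0 * s1.element_strain, s2.element_strain,
                       rtol=1e-12, atol=1e-18)


def test_frame_invariance_under_rotation():
    mesh = mm.structured_box_mesh((4, 2, 2), (4, 2, 2))
    mf = mat.uniform_material(mesh, 500.0, 0.3)
    x = mesh.node_coords
    fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
    loaded = np.flatnonzero(np.abs(x[:, 0] - 4.0) < 1e-9)
    f = np.tile([0.0, 0.05, 0.02], (loaded.size, 1))
    sol = sv.solve_static(mesh, mf, sv.BoundaryConditions(fixed, loaded, f))
    # rotate everything by a random rotation
    rng = np.random.default_rng(11)
    A = rng.normal(size=(3, 3))
    Q = np.linalg.qr(A)[0]
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    mesh_r = mm.TetMesh10(x @ Q.T, mesh.connectivity, mesh.element_region)
    sol_r = sv.solve_static(
        mesh_r, mf, sv.BoundaryConditions(fixed, loaded, f @ Q.T)
    )
    assert np.allclose(sol_r.nodal_displacements, sol.nodal_displacements @ Q.T,
                       rtol=1e-9, atol=1e-12)
    assert np.allclose(sol_r.element_principal_strains,
                       sol.element_principal_strains, rtol=1e-7, atol=1e-10)


class TestPrincipalStrains:
    def test_diagonal(self):
        t = np.diag([0.01, 0.0, -0.01])
        assert np.allclose(sv.principal_strains(t), [0.01, 0.0, -0.01])

    def test_pure_shear(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 0.01
        assert np.allclose(sv.principal_strains(t), [0.01, 0.0, -0.01])

    def test_random_tensor_against_eigendecomposition(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(40, 3, 3))
        T = 0.5 * (A + A.transpose(0, 2, 1))
        mine = sv.principal_strains(T)
        ref = np.sort(np.linalg.eigvals(T).real, axis=1)[:, ::-1]
        assert np.abs(mine - ref).max() < 1e-12

    def test_solution_invariant(self, torsion_4mo):
        _, sol = torsion_4mo
        ev = np.linalg.eigvalsh(sol.strain_tensors())[:, ::-1]
        assert np.abs(ev - sol.element_principal_strains).max() < 1e-14
        d = np.diff(sol.element_principal_strains, axis=1)
        assert np.all(d <= 1e-15)


class TestHyperelastic:
    def test_small_strain_matches_linear(self, single_tet):
        E, nu = 100.0, 0.2
        mf = mat.uniform_material(single_tet, E, nu, kind=mat.KIND_NEO_PORO)
        lam = 1.001
        x = single_tet.node_coords
        pres = {}
        for n in range(single_tet.n_nodes):
            pres[(n, 0)] = float((lam - 1) * x[n, 0])
            pres[(n, 1)] = float(-nu * (lam - 1) * x[n, 1])
            pres[(n, 2)] = float(-nu * (lam - 1) * x[n, 2])
        bcs = sv.BoundaryConditions(prescribed=pres)
        hyper = sv.solve_static(single_tet, mf, bcs, mode="hyperelastic")
        assert hyper.converged
        lin = sv.solve_static(single_tet, mf, bcs, mode="linearised")
        rel = np.abs(
            hyper.element_principal_strains - lin.element_principal_strains
        ).max() / np.abs(lin.element_principal_strains).max()
        assert rel < 5e-3

    def test_moderate_stretch_differs_from_linear(self):
        mesh = mm.structured_box_mesh((2, 1, 1), (2, 1, 1))
        mf = mat.uniform_material(mesh, 10.0, 0.2, kind=mat.KIND_NEO_PORO)
        x = mesh.node_coords
        fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
        end = np.flatnonzero(np.abs(x[:, 0] - 2.0) < 1e-9)
        f = np.tile([0.08, 0, 0], (end.size, 1))
        bcs = sv.BoundaryConditions(fixed, end, f)
        hyper = sv.solve_static(mesh, mf, bcs, mode="hyperelastic")
        assert hyper.converged and hyper.newton_iterations >= 2
        lin = sv.solve_static(mesh, mf, bcs)
        e_h = hyper.element_principal_strains[:, 0].max()
        e_l = lin.element_principal_strains[:, 0].max()
        assert abs(e_h - e_l) / e_l > 0.005  # geometric nonlinearity visible

    def test_nonconvergence_flagged(self, single_tet):
        mf = mat.uniform_material(single_tet, 1.0, 0.2, kind=mat.KIND_NEO_PORO)
        bcs = sv.BoundaryConditions(
            fixed_nodes=np.array([0, 1, 2]),
            loaded_nodes=np.array([3]),
            nodal_forces=np.array([[0.0, 0.0, 5.0]]),
        )
        try:
            sol = sv.solve_static(single_tet, mf, bcs, mode="hyperelastic",
                                  max_iter=1)
            assert not sol.converged
        except FloatingPointError:
            pass  # element inversion is an acceptable hard failure here


def test_rigid_coupling_transmits_requested_wrench():
    mesh = mm.structured_box_mesh((10, 2, 2), (8, 2, 2))
    mf = mat.uniform_material(mesh, 1000.0, 0.3)
    x = mesh.node_coords
    fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
    end = np.flatnonzero(np.abs(x[:, 0] - 10.0) < 1e-9)
    F, M = np.array([1.0, 2.0, -1.0]), np.array([5.0, 0.0, 3.0])
    ref = np.array([10.0, 1.0, 1.0])
    c = sv.RigidCoupling(end, ref, force=F, moment=M)
    sol = sv.StaticSolver(mesh, mf).solve(
        sv.BoundaryConditions(fixed_nodes=fixed, couplings=[c])
    )
    # reaction at the fixed face balances the applied wrench
    K = sv.assemble_linear(mesh, mf)
    r = (K @ sol.nodal_displacements.ravel()).reshape(-1, 3)
    Freact = r[fixed].sum(axis=0)
    Mreact = np.cross(x[fixed] - ref, r[fixed]).sum(axis=0)
    assert np.allclose(Freact, -F, rtol=1e-8, atol=1e-10)
    assert np.allclose(Mreact, -M, rtol=1e-8, atol=1e-9)
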