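"""Static FE solver on 10-node tetrahedral meshes.

Units: mm, N, MPa. Three analysis modes:

* ``linearised`` (default) — small-strain isotropic elasticity; Neo-Hookean
  records are linearised by recovering (E, nu) from (C10, D1).
* ``hyperelastic`` — total-Lagrangian Newton iteration on the compressible
  Neo-Hookean energy W = C10 (I1bar - 3) + (1/D1)(J - 1)^2; linear-elastic
  records are given the Neo-Hookean parameters matching their (E, nu),
  which coincides with linear elasticity in the small-strain limit.
* ``solve_poroelastic`` — linear Biot u-p formulation (quadratic u, linear
  p, backward Euler in time) for consolidation of the fluid-saturated
  ossifying region.

Dirichlet constraints are eliminated; rigid (kinematic) couplings tie a
node patch to a 6-DOF virtual reference point, as used for load
application through a rigid section.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import RULES, RULE_DEGREE2, QuadratureRule, shape_gradients
from .materials import (
    KIND_NEO_PORO,
    MaterialField,
    modulus_from_neo_hookean,
    neo_hookean_from_modulus,
)
from .mesh import TetMesh10

VOIGT_SHEAR_HALF = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])


@dataclass
class RigidCoupling:
    """Kinematic tie of a node set to a virtual 6-DOF reference point."""

    node_ids: np.ndarray
    ref_point: np.ndarray
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    moment: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class BoundaryConditions:
    """Fixed/loaded node sets, nodal forces and optional couplings.

    ``nodal_forces`` rows correspond to ``loaded_nodes``. ``applied_moment``
    is bookkeeping for the requested resultant (axis, magnitude in N mm).
    ``prescribed`` maps (node, component) -> displacement value (mm).
    """

    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], np.int64))
    loaded_nodes: np.ndarray = field(default_factory=lambda: np.array([], np.int64))
    nodal_forces: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    applied_moment: Optional[Tuple[np.ndarray, float]] = None
    prescribed: Dict[Tuple[int, int], float] = field(default_factory=dict)
    couplings: List[RigidCoupling] = field(default_factory=list)

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, np.int64)
        self.loaded_nodes = np.asarray(self.loaded_nodes, np.int64)
        self.nodal_forces = np.atleast_2d(np.asarray(self.nodal_forces, float))
        if self.loaded_nodes.size and self.nodal_forces.shape[0] != self.loaded_nodes.size:
            raise ValueError("nodal_forces must align with loaded_nodes")
        if np.intersect1d(self.fixed_nodes, self.loaded_nodes).size:
            raise ValueError("fixed and loaded node sets must be disjoint")

    def resultant(self, about: np.ndarray, coords: np.ndarray):
        """Total force and moment of the nodal force set about ``about``."""
        if self.loaded_nodes.size == 0:
            return np.zeros(3), np.zeros(3)
        F = self.nodal_forces.sum(axis=0)
        r = coords[self.loaded_nodes] - np.asarray(about)
        M = np.cross(r, self.nodal_forces).sum(axis=0)
        return F, M


@dataclass
class SolutionField:
    """Displacements plus element-averaged strain measures."""

    nodal_displacements: np.ndarray  # (N, 3) mm
    element_strain: np.ndarray  # (M, 6) Voigt, engineering shears
    element_principal_strains: np.ndarray  # (M, 3) descending
    converged: bool = True
    newton_iterations: int = 0

    def strain_tensors(self) -> np.ndarray:
        """Element strains as (M, 3, 3) symmetric tensors."""
        e = self.element_strain
        T = np.zeros((e.shape[0], 3, 3))
        T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = e[:, 0], e[:, 1], e[:, 2]
        T[:, 0, 1] = T[:, 1, 0] = 0.5 * e[:, 3]
        T[:, 1, 2] = T[:, 2, 1] = 0.5 * e[:, 4]
        T[:, 0, 2] = T[:, 2, 0] = 0.5 * e[:, 5]
        return T


def principal_strains(tensor: np.ndarray) -> np.ndarray:
    """Sorted (descending) eigenvalues of symmetric strain tensor(s)."""
    t = np.asarray(tensor, float)
    single = t.ndim == 2
    vals = np.linalg.eigvalsh(np.atleast_3d(t).reshape(-1, 3, 3))[:, ::-1]
    return vals[0] if single else vals


def _effective_linear_moduli(materials: MaterialField):
    """(E, nu) per element with Neo-Hookean records linearised via C10/D1."""
    E = materials.E.copy()
    nu = materials.nu.copy()
    m = materials.kind == KIND_NEO_PORO
    if np.any(m):
        E[m], nu[m] = modulus_from_neo_hookean(materials.C10[m], materials.D1[m])
    return E, nu


def _element_geometry(mesh: TetMesh10, rule: QuadratureRule):
    """Per-quadrature-point dN/dx and w*detJ for all elements."""
    dN = shape_gradients(rule.points)  # (q, 10, 3)
    x = mesh.node_coords[mesh.connectivity]  # (M, 10, 3)
    nq = rule.points.shape[0]
    dNdx = np.empty((nq, mesh.n_elements, 10, 3))
    wdet = np.empty((nq, mesh.n_elements))
    for q in range(nq):
        J = np.einsum("mia,ib->mab", x, dN[q])
        det = np.linalg.det(J)
        if np.any(det <= 0):
            raise ValueError("non-positive Jacobian during assembly")
        Jinv = np.linalg.inv(J)
        dNdx[q] = np.einsum("ia,mab->mib", dN[q], Jinv)
        wdet[q] = rule.weights[q] * det
    return dNdx, wdet


def _b_matrices(dNdx_q: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices (M, 6, 30) at one quadrature point."""
    M = dNdx_q.shape[0]
    B = np.zeros((M, 6, 30))
    gx, gy, gz = dNdx_q[:, :, 0], dNdx_q[:, :, 1], dNdx_q[:, :, 2]
    B[:, 0, 0::3] = gx
    B[:, 1, 1::3] = gy
    B[:, 2, 2::3] = gz
    B[:, 3, 0::3] = gy
    B[:, 3, 1::3] = gx
    B[:, 4, 1::3] = gz
    B[:, 4, 2::3] = gy
    B[:, 5, 0::3] = gz
    B[:, 5, 2::3] = gx
    return B


def _d_matrices(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((E.shape[0], 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def element_dofs(mesh: TetMesh10) -> np.ndarray:
    conn = mesh.connectivity
    return (conn[:, :, None] * 3 + np.arange(3)).reshape(mesh.n_elements, 30)


def assemble_linear(
    mesh: TetMesh10, materials: MaterialField, rule: str = "degree2"
) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N, symmetric PSD before constraints)."""
    qrule = RULES[rule]
    E, nu = _effective_linear_moduli(materials)
    D = _d_matrices(E, nu)
    dNdx, wdet = _element_geometry(mesh, qrule)
    M = mesh.n_elements
    Ke = np.zeros((M, 30, 30))
    for q in range(qrule.points.shape[0]):
        B = _b_matrices(dNdx[q])
        DB = np.einsum("mst,mtj->msj", D, B)
        Ke += wdet[q][:, None, None] * np.einsum("msi,msj->mij", B, DB)
    dofs = element_dofs(mesh)
    rows = np.repeat(dofs, 30, axis=1).ravel()
    cols = np.tile(dofs, (1, 30)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def _element_strains(mesh, materials, u, rule: QuadratureRule):
    """Volume-averaged small strains (M, 6) from a displacement vector."""
    dNdx, wdet = _element_geometry(mesh, rule)
    ue = u.reshape(-1, 3)[mesh.connectivity].reshape(mesh.n_elements, 30)
    acc = np.zeros((mesh.n_elements, 6))
    for q in range(rule.points.shape[0]):
        B = _b_matrices(dNdx[q])
        acc += wdet[q][:, None] * np.einsum("msj,mj->ms", B, ue)
    return acc / wdet.sum(axis=0)[:, None]


def _build_coupling_transform(mesh: TetMesh10, bcs: BoundaryConditions):
    """Sparse map T from (retained structural + 6/coupling) dofs to full dofs."""
    n = 3 * mesh.n_nodes
    slave = np.zeros(n, bool)
    for c in bcs.couplings:
        ids = np.asarray(c.node_ids, np.int64)
        d = (ids[:, None] * 3 + np.arange(3)).ravel()
        if np.any(slave[d]):
            raise ValueError("node appears in two couplings")
        slave[d] = True
    retained = np.flatnonzero(~slave)
    n_red = retained.size + 6 * len(bcs.couplings)
    red_of_full = -np.ones(n, np.int64)
    red_of_full[retained] = np.arange(retained.size)
    rows, cols, vals = [retained], [np.arange(retained.size)], [np.ones(retained.size)]
    base = retained.size
    for c in bcs.couplings:
        ids = np.asarray(c.node_ids, np.int64)
        r = mesh.node_coords[ids] - np.asarray(c.ref_point, float)
        for i in range(3):
            rows.append(ids * 3 + i)
            cols.append(np.full(ids.size, base + i))
            vals.append(np.ones(ids.size))
        # u_s = u_ref + theta x r  =>  d u_s_i / d theta_j = -eps_ijk r_k
        eps = np.zeros((3, 3, 3))
        eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1
        eps[0, 2, 1] = eps[1, 0, 2] = eps[2, 1, 0] = -1
        coef = np.einsum("ijk,nk->nij", eps, r)  # (n, i, j): theta_j coefficient
        for i in range(3):
            for j in range(3):
                rows.append(ids * 3 + i)
                cols.append(np.full(ids.size, base + 3 + j))
                vals.append(coef[:, i, j])
        base += 6
    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n_red),
    ).tocsr()
    return T, red_of_full, retained.size


def _external_forces(mesh: TetMesh10, bcs: BoundaryConditions) -> np.ndarray:
    f = np.zeros(3 * mesh.n_nodes)
    if bcs.loaded_nodes.size:
        np.add.at(
            f.reshape(-1, 3), bcs.loaded_nodes, bcs.nodal_forces
        )
    return f


class StaticSolver:
    """Linear(ised) static solver with factorisation reuse across load cases."""

    def __init__(self, mesh: TetMesh10, materials: MaterialField, rule: str = "degree2"):
        self.mesh = mesh
        self.materials = materials
        self.rule = RULES[rule]
        self.K = assemble_linear(mesh, materials, rule)
        self._cache = {}

    def _factor(self, key, K_ff):
        if key not in self._cache:
            self._cache[key] = spla.splu(K_ff.tocsc(), permc_spec="MMD_AT_PLUS_A")
        return self._cache[key]

    def solve(self, bcs: BoundaryConditions) -> SolutionField:
        mesh = self.mesh
        n = 3 * mesh.n_nodes
        f = _external_forces(mesh, bcs)

        T, red_of_full, n_struct = _build_coupling_transform(mesh, bcs)
        K_r = (T.T @ self.K @ T).tocsr()
        f_r = T.T @ f
        for k, c in enumerate(bcs.couplings):
            base = n_struct + 6 * k
            f_r[base : base + 3] += np.asarray(c.force, float)
            f_r[base + 3 : base + 6] += np.asarray(c.moment, float)

        pres_vals = np.zeros(K_r.shape[0])
        pres_mask = np.zeros(K_r.shape[0], bool)
        for node in bcs.fixed_nodes:
            for i in range(3):
                d = red_of_full[node * 3 + i]
                if d < 0:
                    raise ValueError("fixed node cannot belong to a rigid coupling")
                pres_mask[d] = True
        for (node, comp), val in bcs.prescribed.items():
            d = red_of_full[node * 3 + comp]
            if d < 0:
                raise ValueError("prescribed node cannot belong to a rigid coupling")
            pres_mask[d] = True
            pres_vals[d] = val
        free = np.flatnonzero(~pres_mask)
        if free.size == K_r.shape[0]:
            raise ValueError("under-constrained system: no Dirichlet constraints")
        K_ff = K_r[free][:, free]
        rhs = f_r[free] - K_r[free][:, np.flatnonzero(pres_mask)] @ pres_vals[pres_mask]
        key = (hash(pres_mask.tobytes()), len(bcs.couplings),
               tuple(int(c.node_ids[0]) for c in bcs.couplings))
        try:
            lu = self._factor(key, K_ff)
            u_f = lu.solve(rhs)
        except RuntimeError as exc:  # singular factorisation
            raise ValueError(f"singular system (under-constrained?): {exc}") from exc
        if not np.all(np.isfinite(u_f)):
            raise ValueError("singular system: non-finite solution")
        u_r = pres_vals.copy()
        u_r[free] = u_f
        u = T @ u_r
        strains = _element_strains(mesh, self.materials, u, self.rule)
        tens = SolutionField(u.reshape(-1, 3), strains, np.zeros((mesh.n_elements, 3)))
        tens.element_principal_strains = principal_strains(tens.strain_tensors())
        return tens


def solve_static(
    mesh: TetMesh10,
    materials: MaterialField,
    bcs: BoundaryConditions,
    mode: str = "linearised",
    rule: str = "degree2",
    newton_tol: float = 1e-8,
    max_iter: int = 30,
) -> SolutionField:
    """One-shot static solve; see :class:`StaticSolver` for factor reuse."""
    if mode == "linearised":
        return StaticSolver(mesh, materials, rule).solve(bcs)
    if mode == "hyperelastic":
        return _solve_hyperelastic(mesh, materials, bcs, rule, newton_tol, max_iter)
    raise ValueError(f"unknown mode {mode!r}")


# --- hyperelastic (total Lagrangian Neo-Hookean) ---------------------------


def _nh_parameters(materials: MaterialField):
    C10 = materials.C10.copy()
    D1 = materials.D1.copy()
    lin = materials.kind != KIND_NEO_PORO
    if np.any(lin):
        C10[lin], D1[lin] = neo_hookean_from_modulus(
            materials.E[lin], materials.nu[lin]
        )
    return C10, D1


def _nh_qp_forces(ue, dNdx_q, wdet_q, C10, D1):
    """Internal nodal forces (M, 10, 3) of one quadrature point.

    ``ue`` is (M, 10, 3) element displacements; reference-configuration
    gradients ``dNdx_q`` (M, 10, 3) and weights ``wdet_q`` (M,).
    """
    gradU = np.einsum("mia,mib->mab", ue, dNdx_q)  # du_a/dX_b
    F = gradU + np.eye(3)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise FloatingPointError("element inversion during Newton iteration")
    Bt = np.einsum("mab,mcb->mac", F, F)  # F F^T
    Jm23 = J ** (-2.0 / 3.0)
    Bbar = Jm23[:, None, None] * Bt
    trB = np.trace(Bbar, axis1=1, axis2=2)
    dev = Bbar - (trB / 3.0)[:, None, None] * np.eye(3)
    sigma = (2.0 * C10 / J)[:, None, None] * dev
    sigma += ((2.0 / D1) * (J - 1.0))[:, None, None] * np.eye(3)
    Finv = np.linalg.inv(F)
    P = J[:, None, None] * np.einsum("mab,mcb->mac", sigma, Finv)  # J sigma F^-T
    return wdet_q[:, None, None] * np.einsum("mib,mab->mia", dNdx_q, P)


def _nh_internal_forces(ue, dNdx, wdet, C10, D1):
    f = np.zeros_like(ue)
    for q in range(dNdx.shape[0]):
        f += _nh_qp_forces(ue, dNdx[q], wdet[q], C10, D1)
    return f


def _solve_hyperelastic(mesh, materials, bcs, rule, tol, max_iter):
    if bcs.couplings:
        raise NotImplementedError("rigid couplings are linearised-mode only")
    qrule = RULES[rule]
    dNdx, wdet = _element_geometry(mesh, qrule)
    dNdx = np.ascontiguousarray(dNdx)
    C10, D1 = _nh_parameters(materials)
    conn = mesh.connectivity
    n = 3 * mesh.n_nodes
    f_ext = _external_forces(mesh, bcs)

    pres_mask = np.zeros(n, bool)
    pres_vals = np.zeros(n)
    for node in bcs.fixed_nodes:
        pres_mask[node * 3 : node * 3 + 3] = True
    for (node, comp), val in bcs.prescribed.items():
        pres_mask[node * 3 + comp] = True
        pres_vals[node * 3 + comp] = val
    free = np.flatnonzero(~pres_mask)
    if free.size == n:
        raise ValueError("under-constrained system: no Dirichlet constraints")

    u = pres_vals.copy()
    dofs = element_dofs(mesh)
    rows = np.repeat(dofs, 30, axis=1).ravel()
    cols = np.tile(dofs, (1, 30)).ravel()
    scale = max(np.linalg.norm(f_ext), 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ue = u.reshape(-1, 3)[conn]
        f_int = np.zeros(n)
        fe = _nh_internal_forces(ue, dNdx, wdet, C10, D1)
        np.add.at(f_int.reshape(-1, 3), conn.ravel(), fe.reshape(-1, 3))
        r = f_ext - f_int
        rn = np.linalg.norm(r[free])
        if rn <= tol * scale:
            converged = True
            break
        Kt = _nh_tangent(ue, dNdx, wdet, C10, D1)
        K = sp.coo_matrix((Kt.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        K_ff = K[free][:, free].tocsc()
        du = spla.splu(K_ff, permc_spec="MMD_AT_PLUS_A").solve(r[free])
        u[free] += du

    strains = _green_lagrange_strains(mesh, u, qrule, dNdx, wdet)
    sol = SolutionField(u.reshape(-1, 3), strains, np.zeros((mesh.n_elements, 3)),
                        converged=converged, newton_iterations=it)
    sol.element_principal_strains = principal_strains(sol.strain_tensors())
    return sol


def _nh_tangent(ue, dNdx, wdet, C10, D1, h: float = 1e-7):
    """Element tangent stiffness by central differencing of internal forces."""
    M = ue.shape[0]
    step = h * max(1.0, float(np.abs(ue).max()))
    Kt = np.empty((M, 30, 30))
    for k in range(30):
        i, a = divmod(k, 3)
        up = ue.copy()
        up[:, i, a] += step
        fp = _nh_internal_forces(up, dNdx, wdet, C10, D1)
        um = ue.copy()
        um[:, i, a] -= step
        fm = _nh_internal_forces(um, dNdx, wdet, C10, D1)
        Kt[:, :, k] = ((fp - fm) / (2 * step)).reshape(M, 30)
    return Kt


def _green_lagrange_strains(mesh, u, rule, dNdx, wdet):
    """Volume-averaged Green-Lagrange strain in Voigt form (eng. shears)."""
    ue = u.reshape(-1, 3)[mesh.connectivity]
    acc = np.zeros((mesh.n_elements, 6))
    for q in range(dNdx.shape[0]):
        gradU = np.einsum("mia,mib->mab", ue, dNdx[q])
        F = gradU + np.eye(3)
        Egl = 0.5 * (np.einsum("mab,mac->mbc", F, F) - np.eye(3))
        v = np.stack(
            [Egl[:, 0, 0], Egl[:, 1, 1], Egl[:, 2, 2],
             2 * Egl[:, 0, 1], 2 * Egl[:, 1, 2], 2 * Egl[:, 0, 2]], axis=1
        )
        acc += wdet[q][:, None] * v
    return acc / wdet.sum(axis=0)[:, None]


# --- linear poroelasticity (u-p, backward Euler) ---------------------------


@dataclass
class PoroResult:
    """Transient consolidation history."""

    times: np.ndarray
    displacements: np.ndarray  # (T, N, 3)
    pore_pressure: np.ndarray  # (T, N) at corner nodes, nan elsewhere
    undrained: SolutionField
    drained: SolutionField

    def solution_at(self, k: int, mesh, materials, rule=RULE_DEGREE2) -> SolutionField:
        u = self.displacements[k].ravel()
        strains = _element_strains(mesh, materials, u, rule)
        s = SolutionField(self.displacements[k], strains, np.zeros((strains.shape[0], 3)))
        s.element_principal_strains = principal_strains(s.strain_tensors())
        return s


def _poro_matrices(mesh: TetMesh10, materials: MaterialField, mobility: float,
                   rule: QuadratureRule):
    """K (3N x 3N), coupling Q (3N x N) and conductivity H (N x N).

    Pressure uses linear interpolation on the corner nodes; mid-edge
    pressure dofs do not exist (rows stay empty and are constrained out).
    """
    K = assemble_linear(mesh, materials, "degree2")
    dN = shape_gradients(rule.points)
    x = mesh.node_coords[mesh.connectivity]
    M = mesh.n_elements
    n = mesh.n_nodes
    Qe = np.zeros((M, 30, 4))
    He = np.zeros((M, 4, 4))
    # linear (P1) shape functions are the barycentric coordinates
    for q in range(rule.points.shape[0]):
        J = np.einsum("mia,ib->mab", x, dN[q])
        det = np.linalg.det(J)
        Jinv = np.linalg.inv(J)
        dNdx = np.einsum("ia,mab->mib", dN[q], Jinv)  # (M, 10, 3)
        # P1 gradients: dL/dxi for L1..L3 is I, L0 = -sum
        dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        dLdx = np.einsum("ia,mab->mib", dL, Jinv)  # (M, 4, 3)
        Np = rule.points[q]  # (4,) barycentric values
        w = rule.weights[q] * det
        # Q_(i,a),j = int dN_i/dx_a * L_j
        Qe += w[:, None, None] * np.einsum(
            "mia,j->miaj", dNdx, Np
        ).reshape(M, 30, 4)
        He += w[:, None, None] * mobility * np.einsum("mia,mja->mij", dLdx, dLdx)
    udofs = element_dofs(mesh)
    pdofs = mesh.connectivity[:, :4]
    rows = np.repeat(udofs, 4, axis=1).ravel()
    cols = np.tile(pdofs, (1, 30)).ravel()
    Q = sp.coo_matrix((Qe.ravel(), (rows, cols)), shape=(3 * n, n)).tocsr()
    hr = np.repeat(pdofs, 4, axis=1).ravel()
    hc = np.tile(pdofs, (1, 4)).ravel()
    H = sp.coo_matrix((He.ravel(), (hr, hc)), shape=(n, n)).tocsr()
    return K, Q, H


def solve_poroelastic(
    mesh: TetMesh10,
    materials: MaterialField,
    bcs: BoundaryConditions,
    times: np.ndarray,
    mobility_mm4_Ns: float,
    drained_nodes: np.ndarray,
) -> PoroResult:
    """Backward-Euler consolidation under constant load.

    ``times`` must be strictly increasing and positive (s); ``drained_nodes``
    carry p = 0 (free-draining boundary), all other boundaries are
    impermeable. The state at t = 0+ is the undrained (incompressible)
    response; t -> infinity approaches the drained static solution.
    """
    times = np.asarray(times, float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] <= 0:
        raise ValueError("times must be positive and strictly increasing")
    if mobility_mm4_Ns <= 0:
        raise ValueError("permeability/mobility must be positive")
    rule = RULE_DEGREE2
    K, Q, H = _poro_matrices(mesh, materials, mobility_mm4_Ns, rule)
    n = mesh.n_nodes
    f = _external_forces(mesh, bcs)

    fixed_u = np.zeros(3 * n, bool)
    for node in bcs.fixed_nodes:
        fixed_u[3 * node : 3 * node + 3] = True
    for (node, comp) in bcs.prescribed:
        if bcs.prescribed[(node, comp)] != 0.0:
            raise NotImplementedError("poroelastic mode supports only zero Dirichlet")
        fixed_u[3 * node + comp] = True
    free_u = np.flatnonzero(~fixed_u)

    corner = np.zeros(n, bool)
    corner[np.unique(mesh.connectivity[:, :4])] = True
    p_active = corner.copy()
    p_active[np.asarray(drained_nodes, np.int64)] = False
    free_p = np.flatnonzero(p_active)

    Kff = K[free_u][:, free_u]
    Qfp = Q[free_u][:, free_p]
    Hpp = H[free_p][:, free_p]
    ff = f[free_u]

    def step_matrix(dt):
        return sp.bmat([[Kff, -Qfp], [-Qfp.T, -dt * Hpp]], format="csc")

    nu_f, np_f = free_u.size, free_p.size
    # undrained response: dt = 0 enforces the incompressibility constraint
    lu0 = spla.splu(step_matrix(0.0))
    x0 = lu0.solve(np.concatenate([ff, np.zeros(np_f)]))
    u = x0[:nu_f]
    us, ps = [], []
    t_prev = 0.0
    lu = None
    dt_prev = None
    for t in times:
        dt = t - t_prev
        if lu is None or abs(dt - dt_prev) > 1e-12 * max(dt, dt_prev):
            lu = spla.splu(step_matrix(dt))
            dt_prev = dt
        rhs = np.concatenate([ff, -(Qfp.T @ u)])
        x = lu.solve(rhs)
        u = x[:nu_f]
        us.append(u.copy())
        ps.append(x[nu_f:].copy())
        t_prev = t

    disp = np.zeros((times.size, 3 * n))
    disp[:, free_u] = np.asarray(us)
    press = np.full((times.size, n), np.nan)
    press[:, corner] = 0.0
    press[:, free_p] = np.asarray(ps)

    def _field(uvec):
        strains = _element_strains(mesh, materials, uvec, rule)
        s = SolutionField(uvec.reshape(-1, 3), strains, np.zeros((strains.shape[0], 3)))
        s.element_principal_strains = principal_strains(s.strain_tensors())
        return s

    u_und = np.zeros(3 * n)
    u_und[free_u] = x0[:nu_f]
    u_dr = np.zeros(3 * n)
    u_dr[free_u] = spla.splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A").solve(ff)
    return PoroResult(
        times=times,
        displacements=disp.reshape(times.size, n, 3),
        pore_pressure=press,
        undrained=_field(u_und),
        drained=_field(u_dr),
    )
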