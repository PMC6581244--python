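"""Solver verification benchmarks with closed-form oracles.

These are the standard credibility checks for a small-strain TET10 code:
constant/quadratic patch tests, Saint-Venant torsion of a circular
cylinder, Timoshenko cantilever bending, and Terzaghi one-dimensional
consolidation for the poroelastic mode. Each returns a dictionary with
the computed and reference values plus relative errors; mesh sizes
default to the smallest that comfortably meets the published tolerance
of each benchmark.
"""

from __future__ import annotations

import numpy as np

from . import materials as mat
from . import mesh as mm
from . import solver as sv


def linear_patch_test(seed: int = 0, E: float = 1000.0, nu: float = 0.3) -> dict:
    """Constant-strain patch test on a randomly perturbed box mesh.

    A linear displacement field prescribed on the boundary must be
    reproduced exactly in the interior by quadratic elements.
    """
    mesh = _perturbed_box(seed)
    mf = mat.uniform_material(mesh, E, nu)
    rng = np.random.default_rng(seed + 1)
    A = rng.normal(0, 1e-3, (3, 3))
    uexact = mesh.node_coords @ A.T
    bnodes = np.unique(mm.boundary_faces(mesh))
    pres = {(int(n), c): float(uexact[n, c]) for n in bnodes for c in range(3)}
    sol = sv.solve_static(mesh, mf, sv.BoundaryConditions(prescribed=pres))
    eps = 0.5 * (A + A.T)
    ev = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                   2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
    return {
        "max_displacement_error": float(np.abs(sol.nodal_displacements - uexact).max()),
        "max_strain_error": float(np.abs(sol.element_strain - ev).max()),
    }


def quadratic_patch_test(seed: int = 0, E: float = 1000.0) -> dict:
    """Pure-bending (quadratic) patch test at nu = 0."""
    mesh = _perturbed_box(seed)
    mf = mat.uniform_material(mesh, E, 0.0)
    k = 1e-3
    X = mesh.node_coords
    uexact = np.stack(
        [k * X[:, 0] * X[:, 1], -0.5 * k * X[:, 0] ** 2, np.zeros(len(X))], axis=1
    )
    bnodes = np.unique(mm.boundary_faces(mesh))
    pres = {(int(n), c): float(uexact[n, c]) for n in bnodes for c in range(3)}
    sol = sv.solve_static(mesh, mf, sv.BoundaryConditions(prescribed=pres))
    return {
        "max_displacement_error": float(np.abs(sol.nodal_displacements - uexact).max()),
    }


def _perturbed_box(seed):
    mesh = mm.structured_box_mesh((2, 2, 2), (3, 3, 3))
    rng = np.random.default_rng(seed)
    conn4 = mesh.connectivity[:, :4]
    corner_ids = np.unique(conn4)
    x = mesh.node_coords
    interior = np.all((x > 0.2) & (x < 1.8), axis=1)
    pert = interior & np.isin(np.arange(mesh.n_nodes), corner_ids)
    x2 = x.copy()
    x2[pert] += rng.normal(0, 0.05, (int(pert.sum()), 3))
    renum = -np.ones(mesh.n_nodes, np.int64)
    renum[corner_ids] = np.arange(corner_ids.size)
    return mm.promote_to_quadratic(x2[corner_ids], renum[conn4], mesh.element_region)


def torsion_benchmark(
    n_across: int = 10,
    n_axial: int = 10,
    radius: float = 6.0,
    length: float = 60.0,
    E: float = 10000.0,
    nu: float = 0.3,
    torque: float = 2000.0,
) -> dict:
    """Saint-Venant torsion of a circular cylinder.

    The surface shear strain of the outermost mid-length elements is
    compared with gamma = T r / (G J), J being the polar moment of the
    discrete cross-section. Maximum principal strain equals gamma / 2.
    """
    mesh = mm.structured_cylinder_mesh(radius, length, n_across, n_axial)
    mf = mat.uniform_material(mesh, E, nu)
    G = E / (2 * (1 + nu))
    x = mesh.node_coords
    fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
    end = np.flatnonzero(np.abs(x[:, 0] - length) < 1e-9)
    c = sv.RigidCoupling(end, np.array([length, 0.0, 0.0]),
                         moment=np.array([torque, 0.0, 0.0]))
    sol = sv.StaticSolver(mesh, mf).solve(
        sv.BoundaryConditions(fixed_nodes=fixed, couplings=[c])
    )
    vols = mm.element_volumes(mesh)
    cen = mesh.element_centroids()
    r2 = cen[:, 1] ** 2 + cen[:, 2] ** 2
    J = float((r2 * vols).sum() / length)
    rc = np.sqrt(r2)
    mid = np.abs(cen[:, 0] - length / 2) < length / 6
    sel = mid & (rc > rc[mid].max() - 1e-6)
    eps1 = sol.element_principal_strains[sel, 0]
    pred = torque * rc[sel] / (G * J) / 2.0
    rel = np.abs(eps1 - pred) / pred
    return {
        "surface_eps1": float(eps1.mean()),
        "closed_form_eps1": float(pred.mean()),
        "rel_err_max": float(rel.max()),
        "n_elements": mesh.n_elements,
        "extremal_at_max_radius": bool(
            rc[np.argmax(sol.element_principal_strains[:, 0] * mid)] > 0.8 * radius
        ),
    }


def cantilever_benchmark(
    n_axial: int = 24,
    n_section: int = 4,
    side: float = 6.0,
    length: float = 60.0,
    E: float = 10000.0,
    nu: float = 0.3,
    load: float = 50.0,
) -> dict:
    """Tip-loaded square cantilever vs Timoshenko beam theory.

    delta = P L^3 / (3 E I) + P L / (kappa G A), with the rectangular-section
    shear coefficient kappa = 10 (1 + nu) / (12 + 11 nu).
    """
    mesh = mm.structured_box_mesh((length, side, side), (n_axial, n_section, n_section))
    mf = mat.uniform_material(mesh, E, nu)
    x = mesh.node_coords
    fixed = np.flatnonzero(np.abs(x[:, 0]) < 1e-9)
    end = np.flatnonzero(np.abs(x[:, 0] - length) < 1e-9)
    c = sv.RigidCoupling(end, np.array([length, side / 2, side / 2]),
                         force=np.array([0.0, load, 0.0]))
    sol = sv.StaticSolver(mesh, mf).solve(
        sv.BoundaryConditions(fixed_nodes=fixed, couplings=[c])
    )
    G = E / (2 * (1 + nu))
    I = side ** 4 / 12.0
    kappa = 10 * (1 + nu) / (12 + 11 * nu)
    A = side * side
    delta = load * length ** 3 / (3 * E * I) + load * length / (kappa * G * A)
    tip = float(sol.nodal_displacements[end, 1].mean())
    return {
        "tip_deflection": tip,
        "beam_theory": float(delta),
        "rel_err": float(abs(tip - delta) / delta),
        "n_elements": mesh.n_elements,
    }


def terzaghi_benchmark(
    n_depth: int = 32,
    depth: float = 10.0,
    E: float = 10.0,
    nu: float = 0.2,
    mobility: float = 1e-2,
    n_steps: int = 300,
    T_range=(0.05, 1.5),
    n_check: int = 20,
) -> dict:
    """1D consolidation of a laterally confined column, drained at the top.

    The degree-of-consolidation history U(T) is compared with the Terzaghi
    series at ``n_check`` log-spaced dimensionless times T = c_v t / H^2,
    c_v = mobility * M_oed.
    """
    mesh = mm.structured_box_mesh((1.0, 1.0, depth), (1, 1, n_depth),
                                  region=mm.REGION_EPIPHYSIS)
    mf = mat.uniform_material(mesh, E, nu, kind=mat.KIND_NEO_PORO)
    x = mesh.node_coords
    tol = 1e-9
    pres = {}
    for n in np.flatnonzero((np.abs(x[:, 0]) < tol) | (np.abs(x[:, 0] - 1) < tol)):
        pres[(int(n), 0)] = 0.0
    for n in np.flatnonzero((np.abs(x[:, 1]) < tol) | (np.abs(x[:, 1] - 1) < tol)):
        pres[(int(n), 1)] = 0.0
    for n in np.flatnonzero(np.abs(x[:, 2]) < tol):
        pres[(int(n), 2)] = 0.0
    faces = mm.boundary_faces(mesh)
    xc = x[faces].mean(axis=1)
    top = faces[np.abs(xc[:, 2] - depth) < tol]
    fvec = mm.surface_traction_forces(mesh, top, np.array([0.0, 0.0, -1.0]))
    loaded = np.flatnonzero(np.abs(fvec).sum(axis=1) > 0)
    bcs = sv.BoundaryConditions(loaded_nodes=loaded, nodal_forces=fvec[loaded],
                                prescribed=pres)
    drained = np.flatnonzero(np.abs(x[:, 2] - depth) < tol)
    M_oed = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
    cv = mobility * M_oed
    Tpts = np.geomspace(T_range[0], T_range[1], n_check)
    times_out = Tpts * depth ** 2 / cv
    t_end = 8.0 * depth ** 2 / cv  # long-time (fully drained) limit check
    grid = np.geomspace(times_out[0] / 30.0, times_out[-1], n_steps)
    grid = np.unique(np.concatenate([grid, times_out,
                                     np.linspace(times_out[-1], t_end, 12)[1:]]))
    res = sv.solve_poroelastic(mesh, mf, bcs, grid, mobility, drained)
    topm = np.abs(x[:, 2] - depth) < tol
    s = -res.displacements[:, topm, 2].mean(axis=1)
    s0 = -res.undrained.nodal_displacements[topm, 2].mean()
    sinf = -res.drained.nodal_displacements[topm, 2].mean()
    U = (s - s0) / (sinf - s0)
    idx = np.searchsorted(grid, times_out)
    m = np.arange(500)
    Mm = np.pi * (2 * m + 1) / 2
    Uth = np.array([1 - np.sum(2 / Mm ** 2 * np.exp(-(Mm ** 2) * T)) for T in Tpts])
    err = np.abs(U[idx] - Uth)
    # long-time drained limit and undrained incompressibility diagnostics;
    # the drained face drains instantly, giving a resolution-limited
    # volumetric boundary layer there, so incompressibility of the
    # undrained instant is assessed over the deeper 80% of the column
    interior = mesh.element_centroids()[:, 2] <= 0.8 * depth
    vol_und = res.undrained.element_strain[interior, :3].sum(axis=1)
    long_rel = abs(s[-1] - sinf) / sinf
    return {
        "U_max_abs_err": float(err.max()),
        "T_checked": Tpts.tolist(),
        "long_time_rel_err": float(long_rel),
        "undrained_max_volumetric_strain": float(np.abs(vol_und).max()),
        "drained_volumetric_scale": float(np.abs(
            res.drained.element_strain[:, :3].sum(axis=1)).max()),
    }
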