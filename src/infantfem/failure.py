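"""Principal-strain failure criterion and moment/force-to-fail estimates.

Capacity is defined by the elastic strain limits of bone: 0.73% in
tension on the maximum principal strain and 1.04% in compression on the
minimum principal strain. Only the diaphysis is assessed (the ossifying
epiphysis is cartilaginous and does not fracture in this sense); by
default one element layer at the metaphyseal interface is additionally
excluded so the interface strain concentration does not contaminate the
shaft capacity. In linearised mode the capacity scales in closed form
from any probe load; in hyperelastic mode it is found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mesh import REGION_DIAPHYSIS, REGION_EPIPHYSIS, TetMesh10, element_volumes
from .solver import BoundaryConditions, SolutionField, solve_static

TENSILE_LIMIT = 0.0073
COMPRESSIVE_LIMIT = 0.0104


@dataclass(frozen=True)
class FailureCriterion:
    tensile_limit: float = TENSILE_LIMIT
    compressive_limit: float = COMPRESSIVE_LIMIT
    region_mask: str = "diaphysis_only"  # or "all"
    exclude_interface_layer: bool = True

    def __post_init__(self):
        if self.tensile_limit <= 0 or self.compressive_limit <= 0:
            raise ValueError("strain limits must be positive")
        if self.region_mask not in ("diaphysis_only", "all"):
            raise ValueError("region_mask must be 'diaphysis_only' or 'all'")


@dataclass
class FailureResult:
    limiting_element: int
    limiting_mode: str  # "tension" or "compression"
    max_tensile_strain: float
    max_compressive_strain: float  # magnitude of the most negative eps3
    load_to_fail: float
    applied_load: float


def interface_layer(mesh: TetMesh10) -> np.ndarray:
    """Diaphysis elements sharing at least one node with the epiphysis."""
    epi_nodes = np.unique(mesh.connectivity[mesh.element_region == REGION_EPIPHYSIS])
    touches = np.isin(mesh.connectivity, epi_nodes).any(axis=1)
    return touches & (mesh.element_region == REGION_DIAPHYSIS)


def criterion_mask(
    mesh: TetMesh10,
    criterion: FailureCriterion,
    exclude_nodes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean element mask over which the strain limits are evaluated.

    ``exclude_nodes`` drops elements touching those nodes (e.g. the loaded
    or fixed patches, where the point constraint concentrates strain).
    """
    if criterion.region_mask == "all":
        mask = np.ones(mesh.n_elements, bool)
    else:
        mask = mesh.element_region == REGION_DIAPHYSIS
        if criterion.exclude_interface_layer:
            mask &= ~interface_layer(mesh)
    if exclude_nodes is not None and len(exclude_nodes):
        touches = np.isin(mesh.connectivity, np.asarray(exclude_nodes)).any(axis=1)
        mask &= ~touches
    if not mask.any():
        raise ValueError("failure mask is empty")
    return mask


def strain_extrema(solution: SolutionField, mask: np.ndarray):
    """(max eps1, min eps3, argmax element, argmin element) over the mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty element mask")
    ids = np.flatnonzero(mask)
    eps1 = solution.element_principal_strains[mask, 0]
    eps3 = solution.element_principal_strains[mask, 2]
    return (
        float(eps1.max()),
        float(eps3.min()),
        int(ids[np.argmax(eps1)]),
        int(ids[np.argmin(eps3)]),
    )


def load_to_fail(
    mesh: TetMesh10,
    solution: SolutionField,
    criterion: FailureCriterion,
    applied_load: float,
    exclude_nodes: Optional[np.ndarray] = None,
) -> FailureResult:
    """Capacity by linear scaling of a converged linearised solution.

    load_to_fail = applied_load * min(limit_t / max eps1,
    limit_c / |min eps3|); the first limit reached sets the failure mode.
    """
    if not solution.converged:
        raise ValueError("solution did not converge")
    mask = criterion_mask(mesh, criterion, exclude_nodes)
    e1, e3, i1, i3 = strain_extrema(solution, mask)
    comp = abs(min(e3, 0.0))
    scale_t = criterion.tensile_limit / e1 if e1 > 0 else np.inf
    scale_c = criterion.compressive_limit / comp if comp > 0 else np.inf
    if not np.isfinite(min(scale_t, scale_c)):
        return FailureResult(-1, "none", e1, comp, np.inf, applied_load)
    if scale_t <= scale_c:
        mode, elem, scale = "tension", i1, scale_t
    else:
        mode, elem, scale = "compression", i3, scale_c
    return FailureResult(
        limiting_element=elem,
        limiting_mode=mode,
        max_tensile_strain=e1,
        max_compressive_strain=comp,
        load_to_fail=float(applied_load * scale),
        applied_load=float(applied_load),
    )


def _scale_bcs(bcs: BoundaryConditions, s: float) -> BoundaryConditions:
    out = BoundaryConditions(
        fixed_nodes=bcs.fixed_nodes,
        loaded_nodes=bcs.loaded_nodes,
        nodal_forces=bcs.nodal_forces * s,
        applied_moment=bcs.applied_moment,
        prescribed=bcs.prescribed,
    )
    return out


def load_to_fail_nonlinear(
    mesh: TetMesh10,
    materials,
    bcs: BoundaryConditions,
    criterion: FailureCriterion,
    applied_load: float,
    exclude_nodes: Optional[np.ndarray] = None,
    rel_tol: float = 0.005,
    max_bisect: int = 40,
) -> FailureResult:
    """Capacity by bisection on the load factor with hyperelastic solves.

    The probe BCs are rescaled until the first strain limit is met within
    ``rel_tol``; the linearised capacity provides the initial bracket.
    """
    mask = criterion_mask(mesh, criterion, exclude_nodes)

    def utilisation(s):
        sol = solve_static(mesh, materials, _scale_bcs(bcs, s), mode="hyperelastic")
        if not sol.converged:
            raise RuntimeError("Newton iteration failed during bisection")
        e1, e3, i1, i3 = strain_extrema(sol, mask)
        u = max(e1 / criterion.tensile_limit, abs(min(e3, 0.0)) / criterion.compressive_limit)
        return u, (e1, e3, i1, i3)

    lin = load_to_fail(
        mesh, solve_static(mesh, materials, bcs, mode="linearised"),
        criterion, applied_load, exclude_nodes,
    )
    lo, hi = 0.0, 1.5 * lin.load_to_fail / applied_load
    u_hi, _ = utilisation(hi)
    grow = 0
    while u_hi < 1.0 and grow < 8:
        lo, hi = hi, 2 * hi
        u_hi, _ = utilisation(hi)
        grow += 1
    s = hi
    info = None
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        u, info = utilisation(mid)
        if u >= 1.0:
            hi = mid
        else:
            lo = mid
        s = 0.5 * (lo + hi)
        if (hi - lo) <= rel_tol * hi:
            break
    e1, e3, i1, i3 = info
    mode = "tension" if e1 / criterion.tensile_limit >= abs(min(e3, 0.0)) / criterion.compressive_limit else "compression"
    return FailureResult(
        limiting_element=i1 if mode == "tension" else i3,
        limiting_mode=mode,
        max_tensile_strain=e1,
        max_compressive_strain=abs(min(e3, 0.0)),
        load_to_fail=float(s * applied_load),
        applied_load=float(applied_load),
    )


def strain_profile_along_axis(
    mesh: TetMesh10,
    solution: SolutionField,
    axis_origin: np.ndarray,
    axis_dir: np.ndarray,
    n_slabs: int = 30,
):
    """Per-slab max and median eps1 along an axis (metaphysis diagnostics)."""
    cen = mesh.element_centroids()
    t = (cen - np.asarray(axis_origin)) @ np.asarray(axis_dir)
    edges = np.linspace(t.min(), t.max() + 1e-9, n_slabs + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_slabs - 1)
    eps1 = solution.element_principal_strains[:, 0]
    prof_max = np.full(n_slabs, np.nan)
    prof_med = np.full(n_slabs, np.nan)
    for k in range(n_slabs):
        m = idx == k
        if m.any():
            prof_max[k] = eps1[m].max()
            prof_med[k] = np.median(eps1[m])
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, prof_max, prof_med


def transition_concentration(
    mesh: TetMesh10, solution: SolutionField, slab_width: float
) -> dict:
    """Compare eps1 in the metaphyseal transition slab with the shaft.

    The transition slab is the set of diaphysis elements within
    ``slab_width`` (mm, along the element-centroid axis) of the epiphysis
    interface; the shaft reference is the median eps1 over the remaining
    diaphysis elements.
    """
    layer = interface_layer(mesh)
    if not layer.any():
        raise ValueError("mesh has no epiphysis interface")
    cen = mesh.element_centroids()
    iface_nodes = np.unique(mesh.connectivity[layer])
    # distance of each diaphysis element centroid to the interface node cloud
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.node_coords[iface_nodes])
    d, _ = tree.query(cen)
    dia = mesh.element_region == REGION_DIAPHYSIS
    slab = dia & (d <= slab_width)
    shaft = dia & (d > slab_width)
    eps1 = solution.element_principal_strains[:, 0]
    return {
        "transition_max_eps1": float(eps1[slab].max()),
        "shaft_median_eps1": float(np.median(eps1[shaft])),
        "concentrated": bool(eps1[slab].max() > np.median(eps1[shaft])),
        "n_transition_elements": int(slab.sum()),
    }


def epiphysis_effect_report(
    mesh_full: TetMesh10,
    solution_full: SolutionField,
    mesh_bone: TetMesh10,
    solution_bone: SolutionField,
    criterion: FailureCriterion,
    applied_load: float,
    exclude_nodes_full: Optional[np.ndarray] = None,
    exclude_nodes_bone: Optional[np.ndarray] = None,
    transition_slab_width: float = 5.0,
) -> dict:
    """Diaphyseal capacity with vs without the non-ossified epiphysis.

    Both solutions must share the diaphysis geometry (checked by region
    volume); reports the two capacities, their ratio and the transition
    strain concentration of the full model.
    """
    vol_full = element_volumes(mesh_full)[mesh_full.element_region == REGION_DIAPHYSIS].sum()
    vol_bone = element_volumes(mesh_bone)[mesh_bone.element_region == REGION_DIAPHYSIS].sum()
    if abs(vol_full - vol_bone) > 0.05 * vol_bone:
        raise ValueError("diaphysis meshes are incompatible (volumes differ > 5%)")
    crit_bone = FailureCriterion(
        tensile_limit=criterion.tensile_limit,
        compressive_limit=criterion.compressive_limit,
        region_mask=criterion.region_mask,
        exclude_interface_layer=False,  # bone-only mesh has no interface
    )
    res_full = load_to_fail(mesh_full, solution_full, criterion, applied_load,
                            exclude_nodes_full)
    res_bone = load_to_fail(mesh_bone, solution_bone, crit_bone, applied_load,
                            exclude_nodes_bone)
    conc = transition_concentration(mesh_full, solution_full, transition_slab_width)
    return {
        "load_to_fail_with_epiphysis": res_full.load_to_fail,
        "load_to_fail_bone_only": res_bone.load_to_fail,
        "ratio": res_full.load_to_fail / res_bone.load_to_fail,
        "limiting_mode_with_epiphysis": res_full.limiting_mode,
        "limiting_mode_bone_only": res_bone.limiting_mode,
        "tension_first": res_full.limiting_mode == "tension",
        **conc,
    }
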