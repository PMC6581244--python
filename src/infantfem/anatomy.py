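"""Femoral anatomical coordinate frame and load-case construction.

The frame follows the long-bone convention: slice the diaphysis at 25%
and 75% of its axial extent, take the volume centroids of the two
cross-sections, and let X run through them from proximal to distal. Y is
the medial hint orthogonalised against X; Z = X x Y points anterior.
Aligning loads with this axis minimises the spurious bending moment a
shaft-parallel force would otherwise introduce.

Load cases reproduce a torsion moment about X applied at the proximal
ossification centre (Point 1) and uniaxial forces along X/Y/Z, with the
bone fully fixed at the distal landmark (Point 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import REGION_DIAPHYSIS, TetMesh10, element_volumes
from .phantom import LandmarkSet
from .solver import BoundaryConditions, RigidCoupling

DEFAULT_TORSION_NMM = 2000.0  # 2 kN mm
DEFAULT_AXIAL_N = 200.0

LOAD_KINDS = ("torsion", "axial_X", "axial_Y", "axial_Z")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal triad (X distal, Y medial, Z anterior)."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def rotation(self) -> np.ndarray:
        """Rows X, Y, Z: maps world vectors to frame components."""
        return np.stack([self.X, self.Y, self.Z])

    def validate(self, tol: float = 1e-10) -> None:
        R = self.rotation()
        if np.linalg.norm(R @ R.T - np.eye(3)) > tol:
            raise ValueError("frame is not orthonormal")
        if np.dot(np.cross(self.X, self.Y), self.Z) < 0:
            raise ValueError("frame is not right-handed")


def _axial_stations(mesh: TetMesh10, region=REGION_DIAPHYSIS):
    """Element centroids/volumes of the region plus its principal axis."""
    sel = mesh.element_region == region
    if not np.any(sel):
        raise ValueError("diaphysis region is empty")
    cen = mesh.element_centroids()[sel]
    if cen.shape[0] < 10:
        raise ValueError(
            f"degenerate cross-section geometry: only {cen.shape[0]} "
            "diaphysis elements"
        )
    vol = element_volumes(mesh)[sel]
    mean = np.average(cen, weights=vol, axis=0)
    cov = np.cov((cen - mean).T, aweights=vol)
    w, V = np.linalg.eigh(cov)
    axis = V[:, np.argmax(w)]
    return cen, vol, mean, axis


def plane_section_centroid(mesh: TetMesh10, region, axis, t0, axis_origin):
    """Exact area centroid of the plane cross-section axis . (x - o) = t0.

    Each straight-sided element is clipped against the plane; the polygon
    areas and centroids are accumulated analytically, so the centroid of a
    geometrically symmetric section is exact regardless of how the volume
    was tetrahedralised. Returns (centroid, n_intersected_elements).
    """
    axis = np.asarray(axis, float)
    sel = mesh.element_region == region
    conn = mesh.connectivity[sel][:, :4]
    x = mesh.node_coords
    d = (x[conn] - np.asarray(axis_origin)) @ axis - t0  # (M, 4) signed dists
    # nudge nodes lying exactly in the plane to one side so a plane through
    # a mesh face is cut once (slightly above the face), not lost
    scale = max(np.abs(d).max(), 1.0)
    d = np.where(np.abs(d) < 1e-9 * scale, 1e-9 * scale, d)
    crossing = ~((d > 0).all(axis=1) | (d < 0).all(axis=1))
    area_sum = 0.0
    moment_sum = np.zeros(3)
    n_cut = 0
    edges = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for e in np.flatnonzero(crossing):
        verts = []
        for a, b in edges:
            da, db = d[e, a], d[e, b]
            if (da > 0) != (db > 0):
                s = da / (da - db)
                verts.append((1 - s) * x[conn[e, a]] + s * x[conn[e, b]])
        if len(verts) < 3:
            continue
        V = np.asarray(verts)
        c0 = V.mean(axis=0)
        # order the (convex) polygon vertices by angle about the axis
        u = V[0] - c0
        u = u - (u @ axis) * axis
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        ang = np.arctan2((V - c0) @ v, (V - c0) @ u)
        V = V[np.argsort(ang)]
        n_cut += 1
        for i in range(1, len(V) - 1):
            tri_a = 0.5 * np.linalg.norm(np.cross(V[i] - V[0], V[i + 1] - V[0]))
            tri_c = (V[0] + V[i] + V[i + 1]) / 3.0
            area_sum += tri_a
            moment_sum += tri_a * tri_c
    if area_sum <= 0:
        return None, 0
    return moment_sum / area_sum, n_cut


def build_frame(
    mesh: TetMesh10,
    landmarks: LandmarkSet | None = None,
) -> AnatomicalFrame:
    """Anatomical frame from 25%/75% diaphyseal cross-section centroids.

    Cross-sections are exact plane cuts perpendicular to the principal axis
    of the diaphysis; medial/anterior hints come from the landmark set.
    """
    landmarks = landmarks if landmarks is not None else mesh.landmarks
    if landmarks is None:
        raise ValueError("landmark hints are required to orient the frame")
    cen, vol, mean, axis = _axial_stations(mesh)
    nodes = np.unique(mesh.connectivity[mesh.element_region == REGION_DIAPHYSIS])
    t_nodes = (mesh.node_coords[nodes] - mean) @ axis
    lo, hi = t_nodes.min(), t_nodes.max()
    extent = hi - lo
    centroids = []
    for frac in (0.25, 0.75):
        t0 = lo + frac * extent
        c, n_cut = plane_section_centroid(mesh, REGION_DIAPHYSIS, axis, t0, mean)
        if c is None or n_cut < 10:
            raise ValueError(
                f"degenerate cross-section at {int(frac*100)}%: {n_cut} elements"
            )
        centroids.append(c)
    c25, c75 = centroids
    X = c75 - c25
    # orient proximal -> distal using Point 2 (distal) vs Point 1 (proximal)
    if X @ (landmarks.point2 - landmarks.point1) < 0:
        X, c25, c75 = -X, c75, c25
    X = X / np.linalg.norm(X)
    Y = landmarks.medial_direction - (landmarks.medial_direction @ X) * X
    ny = np.linalg.norm(Y)
    if ny < 1e-6:
        raise ValueError("medial hint is parallel to the shaft axis")
    Y = Y / ny
    Z = np.cross(X, Y)
    frame = AnatomicalFrame(origin=c25, X=X, Y=Y, Z=Z)
    frame.validate()
    return frame


def distribute_wrench(
    points: np.ndarray, ref: np.ndarray, force: np.ndarray, moment: np.ndarray
) -> np.ndarray:
    """Minimum-norm nodal forces with resultant (force, moment about ref).

    Solves min sum|f_i|^2 subject to sum f_i = F and sum r_i x f_i = M; the
    achieved resultant is verified to 1e-9 relative.
    """
    pts = np.atleast_2d(points)
    r = pts - np.asarray(ref, float)
    n = pts.shape[0]

    def skew(v):
        return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])

    S = np.stack([skew(ri) for ri in r])  # moment rows: sum S_i f_i
    AAT = np.zeros((6, 6))
    AAT[:3, :3] = n * np.eye(3)
    Ssum = S.sum(axis=0)
    AAT[:3, 3:] = Ssum.T
    AAT[3:, :3] = Ssum
    AAT[3:, 3:] = np.einsum("nij,nkj->ik", S, S)
    b = np.concatenate([np.asarray(force, float), np.asarray(moment, float)])
    mu = np.linalg.lstsq(AAT, b, rcond=None)[0]
    f = mu[:3][None, :] + np.einsum("nij,j->ni", S.transpose(0, 2, 1), mu[3:])
    achieved = np.concatenate([f.sum(axis=0), np.einsum("nij,nj->i", S, f)])
    scale = max(np.linalg.norm(b), 1.0)
    if np.linalg.norm(achieved - b) > 1e-9 * scale:
        raise ValueError(
            "requested wrench is not realisable on this node patch "
            "(degenerate geometry?)"
        )
    return f


def _patch_near_point(coords, point, radius):
    d = np.linalg.norm(coords - np.asarray(point), axis=1)
    ids = np.flatnonzero(d <= radius)
    if ids.size == 0:
        raise ValueError("no mesh nodes within the landmark patch radius")
    return ids


def _fixed_cross_section(coords, point2, X, half_width):
    t = (coords - np.asarray(point2)) @ X
    ids = np.flatnonzero(np.abs(t) <= half_width)
    if ids.size == 0:
        raise ValueError("no mesh nodes in the fixation cross-section")
    return ids


def make_load_case(
    frame: AnatomicalFrame,
    landmarks: LandmarkSet,
    mesh: TetMesh10,
    kind: str,
    magnitude: float | None = None,
    patch_radius: float = 3.0,
    fixation_half_width: float = 3.0,
    distribution: str = "couple",
) -> BoundaryConditions:
    """Boundary conditions for one of the four experiment load cases.

    ``torsion``: moment about frame X through Point 1 (default 2000 N mm),
    realised as a zero-net-force couple on the node patch around Point 1.
    ``axial_X/Y/Z``: force along the named frame axis at Point 1 (default
    200 N). Point 2 is fixed over a full cross-section slab, which keeps
    the distal constraint free of single-point singularities.
    ``distribution`` "couple" spreads the wrench as a minimum-norm static
    equivalent force set; "rigid" ties the patch to a reference point at
    Point 1 (kinematic coupling).
    """
    if kind not in LOAD_KINDS:
        raise ValueError(f"unknown load kind {kind!r}; expected one of {LOAD_KINDS}")
    coords = mesh.node_coords
    fixed = _fixed_cross_section(coords, landmarks.point2, frame.X, fixation_half_width)
    loaded = _patch_near_point(coords, landmarks.point1, patch_radius)
    loaded = np.setdiff1d(loaded, fixed)
    if loaded.size == 0:
        raise ValueError("load patch and fixation overlap entirely")
    if kind == "torsion":
        mag = DEFAULT_TORSION_NMM if magnitude is None else float(magnitude)
        force = np.zeros(3)
        moment = mag * frame.X
        applied = (frame.X, mag)
    else:
        mag = DEFAULT_AXIAL_N if magnitude is None else float(magnitude)
        axis = {"axial_X": frame.X, "axial_Y": frame.Y, "axial_Z": frame.Z}[kind]
        force = mag * axis
        moment = np.zeros(3)
        applied = None
    if distribution == "rigid":
        coupling = RigidCoupling(loaded, np.asarray(landmarks.point1, float),
                                 force=force, moment=moment)
        return BoundaryConditions(
            fixed_nodes=fixed, applied_moment=applied, couplings=[coupling]
        )
    if distribution != "couple":
        raise ValueError("distribution must be 'couple' or 'rigid'")
    f = distribute_wrench(coords[loaded], landmarks.point1, force, moment)
    return BoundaryConditions(
        fixed_nodes=fixed, loaded_nodes=loaded, nodal_forces=f, applied_moment=applied
    )
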