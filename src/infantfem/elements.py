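"""Quadratic tetrahedral (TET10) reference element: shape functions and quadrature.

Node convention (shared with the Abaqus C3D10 and VTK quadratic-tetra layouts):
corner nodes 0-3, mid-edge nodes 4-9 on edges
(0,1), (1,2), (2,0), (0,3), (1,3), (2,3).

Reference coordinates are barycentric (L0, L1, L2, L3) with
L0 = 1 - xi - eta - zeta, L1 = xi, L2 = eta, L3 = zeta; the reference
tetrahedron has volume 1/6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: mid-edge node -> (corner, corner)
EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

REFERENCE_VOLUME = 1.0 / 6.0


@dataclass(frozen=True)
class QuadratureRule:
    """Volume quadrature on the reference tetrahedron.

    ``points`` are barycentric coordinates (n, 4); ``weights`` sum to the
    reference volume 1/6.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self):  # light sanity, not validation of exactness
        if self.points.shape[1] != 4:
            raise ValueError("quadrature points must be barycentric (n, 4)")


def _perm_rule(groups) -> QuadratureRule:
    pts, wts = [], []
    for bary, w in groups:
        seen = set()
        bary = tuple(bary)
        # all distinct permutations
        from itertools import permutations

        for p in permutations(bary):
            if p in seen:
                continue
            seen.add(p)
            pts.append(p)
            wts.append(w)
    return QuadratureRule(np.asarray(pts, float), np.asarray(wts, float))


# degree-2, 4 points (Hammer); exact for quadratic monomials
_A = 0.5854101966249685
_B = 0.1381966011250105
RULE_DEGREE2 = _perm_rule([((_A, _B, _B, _B), 1.0 / 24.0)])

# degree-3, 5 points (Hammer, with negative centre weight)
RULE_DEGREE3 = _perm_rule(
    [
        ((0.25, 0.25, 0.25, 0.25), -2.0 / 15.0),
        ((0.5, 1.0 / 6.0, 1.0 / 6.0, 1.0 / 6.0), 3.0 / 40.0),
    ]
)

RULES = {"degree2": RULE_DEGREE2, "degree3": RULE_DEGREE3}


def shape_functions(bary: np.ndarray) -> np.ndarray:
    """TET10 shape functions at barycentric points.

    Parameters
    ----------
    bary : (..., 4) array of barycentric coordinates.

    Returns
    -------
    (..., 10) array of shape-function values.
    """
    L = np.asarray(bary, float)
    N = np.empty(L.shape[:-1] + (10,))
    for i in range(4):
        N[..., i] = L[..., i] * (2.0 * L[..., i] - 1.0)
    for k, (a, b) in enumerate(EDGES):
        N[..., 4 + k] = 4.0 * L[..., a] * L[..., b]
    return N


def shape_gradients(bary: np.ndarray) -> np.ndarray:
    """Gradients dN/d(xi, eta, zeta) of the TET10 shape functions.

    Returns an (..., 10, 3) array; the reference coordinates are
    (xi, eta, zeta) = (L1, L2, L3).
    """
    L = np.asarray(bary, float)
    # dL/dxi: rows L0..L3, cols xi,eta,zeta
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    dN = np.zeros(L.shape[:-1] + (10, 3))
    for i in range(4):
        dN[..., i, :] = (4.0 * L[..., i, None] - 1.0) * dL[i]
    for k, (a, b) in enumerate(EDGES):
        dN[..., 4 + k, :] = 4.0 * (L[..., a, None] * dL[b] + L[..., b, None] * dL[a])
    return dN


def subdivided_rule(rule: QuadratureRule, levels: int = 1) -> QuadratureRule:
    """Composite rule: apply ``rule`` on each child of a uniform 1:8 subdivision.

    Used for dense in-element sampling (e.g. image integration); ``levels``
    rounds of subdivision multiply the point count by 8 each time.
    """
    pts, wts = rule.points, rule.weights
    for _ in range(levels):
        new_pts, new_wts = [], []
        # children of the 1:8 red refinement, as barycentric affine maps:
        # corners of each child expressed in parent barycentric coords
        c = np.eye(4)
        m = {}
        for i in range(4):
            for j in range(i + 1, 4):
                m[(i, j)] = 0.5 * (c[i] + c[j])
        children = [
            [c[0], m[(0, 1)], m[(0, 2)], m[(0, 3)]],
            [m[(0, 1)], c[1], m[(1, 2)], m[(1, 3)]],
            [m[(0, 2)], m[(1, 2)], c[2], m[(2, 3)]],
            [m[(0, 3)], m[(1, 3)], m[(2, 3)], c[3]],
            # octahedron split into 4 tets about diagonal m01-m23
            [m[(0, 1)], m[(1, 2)], m[(0, 2)], m[(2, 3)]],
            [m[(0, 1)], m[(0, 2)], m[(0, 3)], m[(2, 3)]],
            [m[(0, 1)], m[(0, 3)], m[(1, 3)], m[(2, 3)]],
            [m[(0, 1)], m[(1, 3)], m[(1, 2)], m[(2, 3)]],
        ]
        for corners in children:
            A = np.asarray(corners)  # (4 child corners, 4 parent bary)
            new_pts.append(pts @ A)
            new_wts.append(wts / 8.0)
        pts = np.concatenate(new_pts)
        wts = np.concatenate(new_wts)
    return QuadratureRule(pts, wts)
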