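"""CT-intensity to constitutive-parameter mapping.

Bone elements receive an integrated average Young's modulus: the
HU -> density -> modulus law is applied pointwise at in-element sample
points interpolated from the image, then volume-averaged (the "V3"
ordering used by Bonemat-style tools). Ossifying-epiphysis elements are
porohyperelastic: a compressible Neo-Hookean solid whose (C10, D1) follow
from the element's own image-derived modulus,

    C10 = E / (4 (1 + nu)),        D1 = 6 (1 - 2 nu) / E,

i.e. the standard identification mu = 2 C10, kappa = 2 / D1, plus
literature poroelastic constants (permeability and void ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .elements import RULE_DEGREE2, subdivided_rule
from .mesh import REGION_EPIPHYSIS, TetMesh10
from .phantom import LABELS, VoxelImage

KIND_LINEAR = 0
KIND_NEO_PORO = 1

#: Literature poroelastic constants for the ossifying region.
PERMEABILITY_M4_NS = 0.00455  # Darcy mobility k/mu, m^2/(Pa s) == m^4/(N s)
VOID_RATIO = 4.50
NU_EPIPHYSIS = 0.20
NU_BONE = 0.30  # standard cortical-bone value; diaphysis Poisson ratio

#: unit conversion for the solver's N-mm-MPa system
MOBILITY_MM4_PER_NS = PERMEABILITY_M4_NS * 1e12


@dataclass(frozen=True)
class CalibrationLaw:
    """HU -> apparent density -> Young's modulus calibration.

    rho = rho_intercept + rho_slope * HU  (g/cm^3), floored at rho_floor;
    E = modulus_coeff * rho ** modulus_exp (MPa), clamped to
    [clamp_min, clamp_max]. Default coefficients follow the common
    density power-law convention and are calibrated so the built-in
    phantom presets span the expected infant modulus range
    (cartilaginous epiphysis ~0.5 GPa up to cortical ~17 GPa).
    """

    rho_intercept: float = 0.1  # g/cm^3
    rho_slope: float = 0.0008  # g/cm^3 per HU
    modulus_coeff: float = 6850.0  # MPa
    modulus_exp: float = 1.49
    clamp_min: float = 50.0  # MPa
    clamp_max: float = 18000.0  # MPa
    rho_floor: float = 0.01  # g/cm^3

    def __post_init__(self):
        if self.rho_slope <= 0 or self.modulus_coeff <= 0 or self.modulus_exp <= 0:
            raise ValueError("calibration coefficients must be positive")
        if not self.clamp_min < self.clamp_max:
            raise ValueError("clamp_min must be below clamp_max")

    def density(self, hu):
        return np.maximum(self.rho_intercept + self.rho_slope * np.asarray(hu, float),
                          self.rho_floor)

    def modulus(self, hu):
        """Pointwise law E(HU) in MPa, clamped."""
        E = self.modulus_coeff * self.density(hu) ** self.modulus_exp
        return np.clip(E, self.clamp_min, self.clamp_max)


DEFAULT_LAW = CalibrationLaw()


@dataclass
class MaterialField:
    """Per-element constitutive records for one mesh."""

    kind: np.ndarray  # KIND_LINEAR or KIND_NEO_PORO
    E: np.ndarray  # MPa
    nu: np.ndarray
    C10: np.ndarray  # MPa (nan for linear records)
    D1: np.ndarray  # 1/MPa (nan for linear records)
    permeability: float = PERMEABILITY_M4_NS  # as printed, m^4/(N s)
    void_ratio: float = VOID_RATIO

    def __post_init__(self):
        if np.any(~np.isfinite(self.E)) or np.any(self.E <= 0):
            raise ValueError("every element needs a finite positive modulus")
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")
        self.validate_neo_hookean()

    def validate_neo_hookean(self, rtol: float = 1e-12) -> None:
        """Check C10/D1 consistency with (E, nu) for porohyperelastic records."""
        m = self.kind == KIND_NEO_PORO
        if not np.any(m):
            return
        C10, D1 = neo_hookean_from_modulus(self.E[m], self.nu[m])
        if not (np.allclose(C10, self.C10[m], rtol=rtol)
                and np.allclose(D1, self.D1[m], rtol=rtol)):
            raise ValueError("C10/D1 inconsistent with (E, nu)")

    @property
    def n_elements(self) -> int:
        return self.E.shape[0]


def neo_hookean_from_modulus(E, nu):
    """(C10, D1) of the compressible Neo-Hookean model from (E, nu).

    C10 = E / (4(1+nu)) [MPa], D1 = 6(1-2nu)/E [1/MPa]. nu must be in
    [0, 0.5): at nu = 0.5 the compressibility parameter D1 is undefined.
    """
    E = np.asarray(E, float)
    nu = np.asarray(nu, float)
    if np.any(E <= 0):
        raise ValueError("E must be positive")
    if np.any((nu < 0) | (nu >= 0.5)):
        raise ValueError("nu must lie in [0, 0.5); D1 undefined at nu = 0.5")
    C10 = E / (4.0 * (1.0 + nu))
    D1 = 6.0 * (1.0 - 2.0 * nu) / E
    return C10, D1


def modulus_from_neo_hookean(C10, D1):
    """Invert the Neo-Hookean identification: (C10, D1) -> (E, nu)."""
    C10 = np.asarray(C10, float)
    D1 = np.asarray(D1, float)
    mu = 2.0 * C10
    kappa = 2.0 / D1
    E = 9.0 * kappa * mu / (3.0 * kappa + mu)
    nu = (3.0 * kappa - 2.0 * mu) / (2.0 * (3.0 * kappa + mu))
    return E, nu


_SAMPLE_RULE = subdivided_rule(RULE_DEGREE2, levels=1)  # 32 points, degree 2
_FINE_SAMPLE_RULE = subdivided_rule(RULE_DEGREE2, levels=3)  # 2048 points
#: elements whose sampled HU span exceeds this are re-integrated with the
#: fine rule; the span is shift-invariant, so adding a constant to the image
#: never changes which elements refine (keeps the mapping monotone in HU)
HU_REFINE_SPAN = 400.0


def _masked_interpolate(image: VoxelImage, points: np.ndarray):
    """Trilinear HU interpolation restricted to non-background voxels.

    Returns (values, valid): background voxels get zero weight; ``valid`` is
    False where no labelled voxel supports the point.
    """
    sp = np.asarray(image.spacing)
    g = (points - np.asarray(image.origin)) / sp - 0.5
    i0 = np.floor(g).astype(np.int64)
    f = g - i0
    shape = np.asarray(image.labels.shape)
    vals = np.zeros(points.shape[0])
    wsum = np.zeros(points.shape[0])
    mask = (image.labels != LABELS["background"]).astype(float)
    for bit in range(8):
        off = np.array([(bit >> k) & 1 for k in range(3)])
        idx = np.clip(i0 + off, 0, shape - 1)
        w = np.prod(np.where(off, f, 1.0 - f), axis=1)
        m = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        hu = image.intensities[idx[:, 0], idx[:, 1], idx[:, 2]]
        vals += w * m * hu
        wsum += w * m
    valid = wsum > 1e-12
    vals[valid] /= wsum[valid]
    return vals, valid


def _element_sample_points(mesh: TetMesh10, elems: np.ndarray, rule=_SAMPLE_RULE):
    """World coordinates of the sampling-rule points, per element."""
    bary = rule.points  # (q, 4)
    corners = mesh.node_coords[mesh.connectivity[elems][:, :4]]  # (m, 4, 3)
    return np.einsum("qa,mak->mqk", bary, corners)


def element_moduli(
    image: VoxelImage,
    mesh: TetMesh10,
    law: CalibrationLaw = DEFAULT_LAW,
    elems: Optional[np.ndarray] = None,
    average_hu_first: bool = False,
) -> np.ndarray:
    """Integrated average modulus (MPa) for the given elements.

    Default ordering applies the law pointwise and averages the moduli; the
    ``average_hu_first`` flag (sensitivity studies only) averages HU before
    applying the law.
    """
    if elems is None:
        elems = np.arange(mesh.n_elements)
    elems = np.asarray(elems)
    lo = np.asarray(image.origin)
    hi = lo + np.asarray(image.spacing) * np.asarray(image.labels.shape)
    centroids = mesh.node_coords[mesh.connectivity[elems][:, :4]].mean(axis=1)
    outside = np.any((centroids < lo) | (centroids > hi), axis=1)
    if np.any(outside):
        raise ValueError(
            f"elements outside image bounds: {elems[outside][:10].tolist()}"
        )

    def integrate_chunk(sub_elems, rule):
        pts = _element_sample_points(mesh, sub_elems, rule)
        m, q, _ = pts.shape
        vals, valid = _masked_interpolate(image, pts.reshape(-1, 3))
        vals = vals.reshape(m, q)
        valid = valid.reshape(m, q)
        w = np.broadcast_to(rule.weights, (m, q)) * valid
        wsum = w.sum(axis=1)
        dead = wsum <= 0
        if np.any(dead):
            raise ValueError(
                f"elements with no labelled support: {sub_elems[dead][:10].tolist()}"
            )
        masked = np.where(valid, vals, np.nan)
        span = np.nanmax(masked, axis=1) - np.nanmin(masked, axis=1)
        if average_hu_first:
            E = law.modulus((w * vals).sum(axis=1) / wsum)
        else:
            E = (w * law.modulus(vals)).sum(axis=1) / wsum
        return E, span

    def integrate(sub_elems, rule):
        # bounded memory: at most ~2e6 sample points in flight
        step = max(1, 2_000_000 // rule.points.shape[0])
        Es, spans = [], []
        for k in range(0, sub_elems.size, step):
            E_k, s_k = integrate_chunk(sub_elems[k : k + step], rule)
            Es.append(E_k)
            spans.append(s_k)
        return np.concatenate(Es), np.concatenate(spans)

    E, span = integrate(elems, _SAMPLE_RULE)
    steep = span > HU_REFINE_SPAN
    if np.any(steep):
        E[steep], _ = integrate(elems[steep], _FINE_SAMPLE_RULE)
    return E


def element_modulus(
    image: VoxelImage, mesh: TetMesh10, elem: int, law: CalibrationLaw = DEFAULT_LAW,
    **kw,
) -> float:
    """Integrated average modulus (MPa) of a single element."""
    return float(element_moduli(image, mesh, law, np.array([elem]), **kw)[0])


def build_material_field(
    image: VoxelImage,
    mesh: TetMesh10,
    law: CalibrationLaw = DEFAULT_LAW,
    nu_bone: float = NU_BONE,
    nu_epiphysis: float = NU_EPIPHYSIS,
    average_hu_first: bool = False,
) -> MaterialField:
    """Per-element material records for a whole mesh.

    Diaphysis elements become isotropic linear elastic (image-derived E,
    ``nu_bone``); ossifying-epiphysis elements become Neo-Hookean/poroelastic
    with (C10, D1) from their own image-derived modulus.
    """
    E = element_moduli(image, mesh, law, average_hu_first=average_hu_first)
    M = mesh.n_elements
    kind = np.where(mesh.element_region == REGION_EPIPHYSIS, KIND_NEO_PORO, KIND_LINEAR)
    nu = np.where(kind == KIND_NEO_PORO, nu_epiphysis, nu_bone)
    C10 = np.full(M, np.nan)
    D1 = np.full(M, np.nan)
    epi = kind == KIND_NEO_PORO
    if np.any(epi):
        C10[epi], D1[epi] = neo_hookean_from_modulus(E[epi], nu[epi])
    return MaterialField(kind=kind, E=E, nu=nu, C10=C10, D1=D1)


def uniform_material(
    mesh: TetMesh10, E: float, nu: float, kind: int = KIND_LINEAR
) -> MaterialField:
    """Homogeneous material field (verification problems)."""
    M = mesh.n_elements
    Ea = np.full(M, float(E))
    nua = np.full(M, float(nu))
    C10 = np.full(M, np.nan)
    D1 = np.full(M, np.nan)
    kinds = np.full(M, kind)
    if kind == KIND_NEO_PORO:
        C10, D1 = neo_hookean_from_modulus(Ea, nua)
    return MaterialField(kind=kinds, E=Ea, nu=nua, C10=C10, D1=D1)
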