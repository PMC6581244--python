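"""Parametric voxel phantoms of the developing infant femur.

The generator emulates what segmentation of paired CT/MRI examinations
provides to the downstream analysis: a CT-intensity (HU-like) volume, a
region-label volume (cortical shell, trabecular core, ossifying proximal
epiphysis) and the anatomical landmarks used for loading and fixation.
Geometry is a straight hollow diaphyseal cylinder plus an ellipsoidal
proximal epiphysis attached along a tilted neck axis; the two built-in
presets reproduce the overall dimensions of a 4-month-old and a
7-month-old femur (proximal-distal length, epiphysis volume and
cross-sectional area, total bone volume).

Units: geometric parameters in cm, voxel spacing and transition width in
mm, intensities in HU. All voxel-grid coordinates are mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

LABELS = {"background": 0, "cortical": 1, "trabecular": 2, "ossifying_epiphysis": 3}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

CM3_PER_MM3 = 1e-3


@dataclass(frozen=True)
class FemurParams:
    """Parameter set for one synthetic femur."""

    length_prox_dist: float  # cm, proximal epiphysis tip -> distal shaft end
    shaft_outer_radius: float  # cm
    shaft_cortical_thickness: float  # cm
    neck_shaft_angle: float = 155.0  # degrees
    epiphysis_semi_axes: Tuple[float, float, float] = (0.5, 0.8, 0.8)  # cm; [0] on neck axis
    epiphysis_volume_target: Optional[float] = None  # cm^3, rescales semi-axes
    anteversion_angle: float = 10.0  # degrees
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    hu_cortical_peak: float = 2200.0
    hu_trabecular: float = 500.0
    hu_epiphysis: float = 100.0
    transition_width: float = 3.0  # mm
    noise_sd: float = 30.0  # HU
    seed: int = 0
    overlap_depth: float = 0.2  # cm, epiphysis penetration into the metaphysis

    def __post_init__(self):
        if self.length_prox_dist <= 0:
            raise ValueError("length must be positive")
        if not 0 < self.shaft_cortical_thickness < self.shaft_outer_radius:
            raise ValueError("0 < cortical thickness < outer radius required")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.transition_width < 0:
            raise ValueError("transition width must be non-negative")
        if any(a <= 0 for a in self.epiphysis_semi_axes):
            raise ValueError("epiphysis semi-axes must be positive")
        # the cortical shell must be resolvable on the grid
        if 10.0 * self.shaft_cortical_thickness < 2.0 * max(self.voxel_spacing):
            raise ValueError(
                "voxel spacing too coarse: cortical thickness "
                f"{self.shaft_cortical_thickness} cm spans fewer than 2 voxels "
                f"at spacing {max(self.voxel_spacing)} mm"
            )

    def resolved_semi_axes(self) -> Tuple[float, float, float]:
        """Semi-axes after optional isotropic rescale to the volume target (cm)."""
        a, b, c = self.epiphysis_semi_axes
        if self.epiphysis_volume_target is None:
            return (a, b, c)
        v = 4.0 / 3.0 * np.pi * a * b * c
        s = (self.epiphysis_volume_target / v) ** (1.0 / 3.0)
        out = (a * s, b * s, c * s)
        v2 = 4.0 / 3.0 * np.pi * out[0] * out[1] * out[2]
        assert abs(v2 - self.epiphysis_volume_target) <= 0.01 * self.epiphysis_volume_target
        return out


@dataclass
class VoxelImage:
    """HU-like intensity grid with a companion region-label grid (mm coords)."""

    intensities: np.ndarray
    labels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.intensities.shape != self.labels.shape:
            raise ValueError("intensities and labels must share shape")
        extra = set(np.unique(self.labels)) - set(LABELS.values())
        if extra:
            raise ValueError(f"unknown label codes {sorted(extra)}")
        mask = self.labels != LABELS["background"]
        if not np.all(np.isfinite(self.intensities[mask])):
            raise ValueError("non-finite intensity inside labelled region")

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centres(self, idx: np.ndarray) -> np.ndarray:
        sp = np.asarray(self.spacing)
        return np.asarray(self.origin) + (idx + 0.5) * sp


@dataclass
class LandmarkSet:
    """Loading/fixation landmarks and laterality hints (mm, unit vectors)."""

    point1: np.ndarray  # proximal ossification centre
    point2: np.ndarray  # distal fixation point
    medial_direction: np.ndarray
    anterior_direction: np.ndarray

    def __post_init__(self):
        self.point1 = np.asarray(self.point1, float)
        self.point2 = np.asarray(self.point2, float)
        self.medial_direction = np.asarray(self.medial_direction, float)
        self.anterior_direction = np.asarray(self.anterior_direction, float)
        for v in (self.medial_direction, self.anterior_direction):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("direction hints must be unit vectors")
        if abs(self.medial_direction @ self.anterior_direction) > 1e-9:
            raise ValueError("medial and anterior hints must be orthogonal")


def preset(name: str) -> FemurParams:
    """Built-in parameterisations ``"4mo"`` and ``"7mo"``.

    Shaft radii/cortical thicknesses are model choices (not reported for the
    source subjects) calibrated so that total volume, epiphysis volume and
    epiphyseal cross-sectional area reproduce the reference dimensions.
    """
    key = name.replace("preset_", "")
    if key == "4mo":
        return FemurParams(
            length_prox_dist=10.55,
            shaft_outer_radius=0.6261,
            shaft_cortical_thickness=0.25,
            epiphysis_semi_axes=(0.4346, 0.8253, 0.8253),
            hu_epiphysis=125.0,
            seed=40,
        )
    if key == "7mo":
        return FemurParams(
            length_prox_dist=13.28,
            shaft_outer_radius=0.8482,
            shaft_cortical_thickness=0.30,
            epiphysis_semi_axes=(1.7604, 1.0357, 1.0357),
            hu_epiphysis=80.0,
            seed=70,
        )
    raise ValueError(f"unknown preset {name!r}; use '4mo' or '7mo'")


def neck_axis(params: FemurParams) -> np.ndarray:
    """Unit vector from the metaphyseal attachment into the epiphysis.

    The shaft axis is +x (proximal at low x); the neck tilts by
    (180 deg - neck-shaft angle) towards medial (+y) and rotates by the
    anteversion angle about the shaft axis towards anterior (+z).
    """
    phi = np.deg2rad(180.0 - params.neck_shaft_angle)
    psi = np.deg2rad(params.anteversion_angle)
    u = np.array(
        [-np.cos(phi), np.sin(phi) * np.cos(psi), np.sin(phi) * np.sin(psi)]
    )
    return u / np.linalg.norm(u)


def _geometry(params: FemurParams):
    """Internal mm-unit geometry: shaft extents, ellipsoid centre and frame."""
    L = params.length_prox_dist * 10.0
    a, b, c = (s * 10.0 for s in params.resolved_semi_axes())
    delta = params.overlap_depth * 10.0
    u1 = neck_axis(params)
    # complete {u1, u2, u3} to an orthonormal triad for the ellipsoid axes
    ref = np.array([0.0, 0.0, 1.0])
    u2 = np.cross(u1, ref)
    u2 /= np.linalg.norm(u2)
    u3 = np.cross(u1, u2)
    # proximal extent of the ellipsoid along -x from its centre
    ext_x = np.sqrt((a * u1[0]) ** 2 + (b * u2[0]) ** 2 + (c * u3[0]) ** 2)
    # place the proximal tip of the epiphysis at x = 0, distal shaft end at L
    x_start = ext_x - u1[0] * (a - delta)  # u1[0] < 0, so the centre lands at x = ext_x
    centre_local = np.array([x_start, 0.0, 0.0]) + u1 * (a - delta)
    return {
        "L": L,
        "x_start": x_start,
        "r_out": params.shaft_outer_radius * 10.0,
        "r_in": (params.shaft_outer_radius - params.shaft_cortical_thickness) * 10.0,
        "axes": (a, b, c),
        "frame": np.stack([u1, u2, u3]),
        "centre": centre_local,
    }


def generate_femur(params: FemurParams) -> tuple[VoxelImage, LandmarkSet]:
    """Voxelise the parametric femur; deterministic for a fixed seed."""
    g = _geometry(params)
    sp = np.asarray(params.voxel_spacing, float)
    margin = 2.0 * sp
    reach = np.linalg.norm(g["centre"][1:]) + max(g["axes"])
    half_yz = max(g["r_out"], reach) + np.array([margin[1], margin[2]])
    lo = np.array([-margin[0], -half_yz[0], -half_yz[1]])
    hi = np.array([g["L"] + margin[0], half_yz[0], half_yz[1]])
    shape = np.ceil((hi - lo) / sp).astype(int)

    idx = np.indices(shape).reshape(3, -1).T
    X = lo + (idx + 0.5) * sp  # world = local here (origin at lo)

    labels = np.zeros(shape, np.uint8).reshape(-1)
    rho = np.hypot(X[:, 1], X[:, 2])
    in_shaft = (X[:, 0] >= g["x_start"]) & (X[:, 0] <= g["L"]) & (rho <= g["r_out"])
    labels[in_shaft & (rho > g["r_in"])] = LABELS["cortical"]
    labels[in_shaft & (rho <= g["r_in"])] = LABELS["trabecular"]
    rel = (X - g["centre"]) @ g["frame"].T  # coords in ellipsoid axes
    axes = np.asarray(g["axes"])
    in_epi = np.sum((rel / axes) ** 2, axis=1) <= 1.0
    labels[in_epi] = LABELS["ossifying_epiphysis"]

    hu = np.zeros(labels.shape)
    hu[labels.reshape(-1) == LABELS["cortical"]] = params.hu_cortical_peak
    hu[labels.reshape(-1) == LABELS["trabecular"]] = params.hu_trabecular
    hu[labels.reshape(-1) == LABELS["ossifying_epiphysis"]] = params.hu_epiphysis
    # linear metaphyseal ramp across the interface plane x = x_start
    w = params.transition_width
    if w > 0:
        s = X[:, 0] - g["x_start"]
        in_ramp = (np.abs(s) <= w / 2.0) & (labels != LABELS["background"])
        lam = (s[in_ramp] + w / 2.0) / w
        mineralised = np.where(
            labels[in_ramp] == LABELS["cortical"], params.hu_cortical_peak, params.hu_trabecular
        )
        hu[in_ramp] = (1.0 - lam) * params.hu_epiphysis + lam * mineralised

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        non_bg = labels != LABELS["background"]
        hu[non_bg] += rng.normal(0.0, params.noise_sd, int(non_bg.sum()))

    labels = labels.reshape(shape)
    hu = hu.reshape(shape)
    # image coordinates start at the grid corner; translate the geometry
    # (landmarks) into that frame rather than storing a negative origin
    image = VoxelImage(hu, labels, tuple(sp), origin=(0.0, 0.0, 0.0))
    offset = -lo
    landmarks = LandmarkSet(
        point1=g["centre"] + offset,
        point2=np.array([g["L"] - 5.0, 0.0, 0.0]) + offset,
        medial_direction=np.array([0.0, 1.0, 0.0]),
        anterior_direction=np.array([0.0, 0.0, 1.0]),
    )
    _check_connected(labels)
    return image, landmarks


def _check_connected(labels: np.ndarray) -> None:
    for name in ("cortical", "ossifying_epiphysis"):
        mask = labels == LABELS[name]
        if mask.any():
            _, n = ndimage.label(mask)
            if n != 1:
                raise RuntimeError(f"{name} region is disconnected ({n} components)")
    union = labels != LABELS["background"]
    _, n = ndimage.label(union)
    if n != 1:
        raise RuntimeError(f"labelled domain is disconnected ({n} components)")


def voxel_volume_of_label(image: VoxelImage, label) -> float:
    """Volume of a labelled region in cm^3 (voxel count x voxel volume)."""
    import warnings

    code = LABELS[label] if isinstance(label, str) else int(label)
    count = int(np.count_nonzero(image.labels == code))
    if count == 0:
        warnings.warn(f"label {label!r} absent from image; volume 0", stacklevel=2)
    return count * image.voxel_volume_mm3() * CM3_PER_MM3


def total_labelled_volume(image: VoxelImage) -> float:
    """Volume of all non-background voxels in cm^3."""
    count = int(np.count_nonzero(image.labels != LABELS["background"]))
    return count * image.voxel_volume_mm3() * CM3_PER_MM3


def epiphysis_cross_section_area(
    image: VoxelImage, centre: np.ndarray, axis: np.ndarray
) -> float:
    """Epiphyseal cross-sectional area (cm^2) in the plane through ``centre``
    perpendicular to ``axis`` (typically the neck axis through Point 1)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    idx = np.argwhere(image.labels == LABELS["ossifying_epiphysis"])
    if idx.size == 0:
        raise ValueError("no ossifying epiphysis in image")
    pts = image.voxel_centres(idx)
    t = (pts - np.asarray(centre, float)) @ axis
    slab = float(min(image.spacing))
    inside = np.abs(t) <= slab / 2.0
    area_mm2 = inside.sum() * image.voxel_volume_mm3() / slab
    return area_mm2 / 100.0


def save_phantom(
    image: VoxelImage, landmarks: LandmarkSet, params: FemurParams, outdir
) -> dict:
    """Write NIfTI volumes plus a JSON sidecar; returns the file map."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    files = {}
    for name, arr in (("intensities", image.intensities.astype(np.float32)),
                      ("labels", image.labels.astype(np.uint8))):
        p = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), p)
        files[name] = str(p)
    sidecar = {
        "spacing_mm": list(image.spacing),
        "origin_mm": list(image.origin),
        "landmarks": {
            "point1": landmarks.point1.tolist(),
            "point2": landmarks.point2.tolist(),
            "medial_direction": landmarks.medial_direction.tolist(),
            "anterior_direction": landmarks.anterior_direction.tolist(),
        },
        "params": dataclasses.asdict(params),
        "seed": params.seed,
    }
    p = outdir / "phantom.json"
    p.write_text(json.dumps(sidecar, indent=2))
    files["sidecar"] = str(p)
    return files


def load_phantom(outdir) -> tuple[VoxelImage, LandmarkSet, FemurParams]:
    """Read back what :func:`save_phantom` wrote."""
    import nibabel as nib

    outdir = Path(outdir)
    meta = json.loads((outdir / "phantom.json").read_text())
    hu = np.asarray(nib.load(outdir / "intensities.nii.gz").dataobj, float)
    labels = np.asarray(nib.load(outdir / "labels.nii.gz").dataobj).astype(np.uint8)
    image = VoxelImage(hu, labels, tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]))
    lm = meta["landmarks"]
    landmarks = LandmarkSet(
        np.array(lm["point1"]), np.array(lm["point2"]),
        np.array(lm["medial_direction"]), np.array(lm["anterior_direction"]),
    )
    prm = meta["params"]
    prm["epiphysis_semi_axes"] = tuple(prm["epiphysis_semi_axes"])
    prm["voxel_spacing"] = tuple(prm["voxel_spacing"])
    params = FemurParams(**prm)
    return image, landmarks, params
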