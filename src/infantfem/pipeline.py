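"""End-to-end pipeline: phantom -> mesh -> materials -> solve -> failure.

Each run resolves its configuration, executes the stages in order, writes
every intermediate product to the output directory and finishes with a
manifest (file checksums, stage wall times, versions). Outputs are
deterministic for a fixed seed in linearised mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from . import __version__
from .anatomy import build_frame, make_load_case
from .failure import (
    FailureCriterion,
    criterion_mask,
    epiphysis_effect_report,
    load_to_fail,
    strain_profile_along_axis,
)
from .io import write_mesh_statistics, write_vtu
from .materials import CalibrationLaw, build_material_field
from .mesh import REGION_DIAPHYSIS, TetMesh10, mesh_from_labels
from .phantom import (
    LABELS,
    FemurParams,
    generate_femur,
    preset,
    save_phantom,
    total_labelled_volume,
    voxel_volume_of_label,
)
from .solver import RigidCoupling, BoundaryConditions, StaticSolver

CASE_ALIASES = {"torsion": "torsion", "fx": "axial_X", "fy": "axial_Y", "fz": "axial_Z"}


@dataclass
class RunConfig:
    """Serialisable description of one pipeline run."""

    preset: Optional[str] = "4mo"
    params: dict = field(default_factory=dict)  # FemurParams overrides
    target_edge: float = 2.5  # mm
    law: dict = field(default_factory=dict)  # CalibrationLaw overrides
    mode: str = "linearised"
    load_cases: List[str] = field(default_factory=lambda: ["torsion"])
    criterion: dict = field(default_factory=dict)
    compare_bone_only: bool = False
    outdir: str = "run_output"
    seed: int = 0

    def femur_params(self) -> FemurParams:
        base = preset(self.preset) if self.preset else FemurParams(**self.params)
        overrides = dict(self.params)
        overrides["seed"] = self.seed
        if self.preset:
            base = dataclasses.replace(base, **overrides)
        return base

    def calibration_law(self) -> CalibrationLaw:
        return CalibrationLaw(**self.law)

    def failure_criterion(self) -> FailureCriterion:
        return FailureCriterion(**self.criterion)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _bone_only_image(image):
    """Copy of the phantom with the ossifying epiphysis removed."""
    import copy

    img = copy.deepcopy(image)
    epi = img.labels == LABELS["ossifying_epiphysis"]
    img.labels[epi] = LABELS["background"]
    img.intensities[epi] = 0.0
    return img


def proximal_section_coupling(
    mesh: TetMesh10, frame, wrench_force, wrench_moment, half_width: float = 3.0
):
    """Rigid coupling of the proximal diaphyseal cross-section.

    Used to load bone-only models the way a reference-point coupling would:
    the exposed proximal section is tied rigidly and the wrench applied at
    its centroid.
    """
    dia_nodes = np.unique(mesh.connectivity[mesh.element_region == REGION_DIAPHYSIS])
    t = (mesh.node_coords[dia_nodes] - frame.origin) @ frame.X
    sel = dia_nodes[t <= t.min() + half_width]
    ref = mesh.node_coords[sel].mean(axis=0)
    return RigidCoupling(sel, ref, force=np.asarray(wrench_force, float),
                         moment=np.asarray(wrench_moment, float)), sel


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "stages": [], "files": {}, "results": {}}
    t_all = time.time()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                status = "failed" if exc_type else "completed"
                manifest["stages"].append(
                    {"name": name, "status": status,
                     "wall_time_s": round(time.time() - self.t0, 3)}
                )
                if exc_type:
                    manifest["failed_stage"] = name
                    _write_manifest(manifest, outdir)
                return False

        return _Ctx()

    try:
        with stage("phantom"):
            params = config.femur_params()
            image, landmarks = generate_femur(params)
            files = save_phantom(image, landmarks, params, outdir / "phantom")
            manifest["results"]["phantom"] = {
                "total_volume_cm3": total_labelled_volume(image),
                "epiphysis_volume_cm3": voxel_volume_of_label(
                    image, "ossifying_epiphysis"
                ),
            }

        with stage("mesh"):
            mesh = mesh_from_labels(image, config.target_edge, landmarks)
            write_mesh_statistics(mesh, outdir / "mesh_stats.json")
            manifest["results"]["mesh"] = {
                "n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements,
            }

        with stage("materials"):
            law = config.calibration_law()
            mats = build_material_field(image, mesh, law)
            write_vtu(
                mesh, outdir / "mesh_materials.vtu",
                cell_data={"E_MPa": mats.E, "C10_MPa": np.nan_to_num(mats.C10),
                           "D1_per_MPa": np.nan_to_num(mats.D1)},
            )
            manifest["results"]["materials"] = {
                "E_min_MPa": float(mats.E.min()), "E_max_MPa": float(mats.E.max()),
            }

        with stage("solve"):
            if config.mode != "linearised":
                raise NotImplementedError(
                    "pipeline orchestration is linearised-mode; call solve_static "
                    "directly for hyperelastic studies"
                )
            frame = build_frame(mesh, landmarks)
            solver = StaticSolver(mesh, mats)
            solutions = {}
            for case in config.load_cases:
                kind = CASE_ALIASES.get(case, case)
                bcs = make_load_case(frame, landmarks, mesh, kind)
                sol = solver.solve(bcs)
                solutions[case] = (kind, bcs, sol)
                write_vtu(
                    mesh, outdir / f"solution_{case}.vtu",
                    point_data={"displacement_mm": sol.nodal_displacements},
                    cell_data={"eps1": sol.element_principal_strains[:, 0],
                               "eps3": sol.element_principal_strains[:, 2]},
                )

        with stage("failure"):
            criterion = config.failure_criterion()
            report = {}
            for case, (kind, bcs, sol) in solutions.items():
                applied = (bcs.applied_moment[1] if kind == "torsion"
                           else float(np.linalg.norm(bcs.nodal_forces.sum(axis=0))))
                res = load_to_fail(mesh, sol, criterion, applied)
                mask = criterion_mask(mesh, criterion)
                centres, pmax, pmed = strain_profile_along_axis(
                    mesh, sol, frame.origin, frame.X
                )
                report[case] = {
                    "applied_load": res.applied_load,
                    "load_to_fail": res.load_to_fail,
                    "units": "N mm" if kind == "torsion" else "N",
                    "limiting_mode": res.limiting_mode,
                    "max_tensile_strain": res.max_tensile_strain,
                    "max_compressive_strain": res.max_compressive_strain,
                    "utilisation_profile": {
                        "axial_position_mm": centres.tolist(),
                        "slab_max_eps1": pmax.tolist(),
                        "slab_median_eps1": pmed.tolist(),
                    },
                }
            if config.compare_bone_only and "torsion" in solutions:
                report["epiphysis_effect"] = _compare_bone_only(
                    config, image, landmarks, mesh, mats, solutions["torsion"][2],
                    criterion,
                )
            (outdir / "failure_report.json").write_text(json.dumps(report, indent=2))
            manifest["results"]["failure"] = {
                c: {k: v for k, v in r.items() if not isinstance(v, dict)}
                for c, r in report.items()
            }
    finally:
        config.to_yaml(outdir / "config_resolved.yaml")

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
    manifest["wall_time_s"] = round(time.time() - t_all, 3)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest, outdir):
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _compare_bone_only(config, image, landmarks, mesh_full, mats_full, sol_full,
                       criterion):
    """Torsion capacity of the shaft with vs without the epiphysis."""
    from .anatomy import DEFAULT_TORSION_NMM

    img_bone = _bone_only_image(image)
    mesh_bone = mesh_from_labels(img_bone, config.target_edge, landmarks)
    mats_bone = build_material_field(img_bone, mesh_bone, config.calibration_law())
    frame_bone = build_frame(mesh_bone, landmarks)
    coupling, coupled = proximal_section_coupling(
        mesh_bone, frame_bone, np.zeros(3), DEFAULT_TORSION_NMM * frame_bone.X
    )
    bcs_bone = BoundaryConditions(
        fixed_nodes=np.setdiff1d(
            _fixed_like_full(mesh_bone, landmarks, frame_bone), coupled
        ),
        couplings=[coupling],
    )
    sol_bone = StaticSolver(mesh_bone, mats_bone).solve(bcs_bone)
    return epiphysis_effect_report(
        mesh_full, sol_full, mesh_bone, sol_bone, criterion,
        DEFAULT_TORSION_NMM, exclude_nodes_bone=coupled,
        transition_slab_width=2 * config.target_edge,
    )


def _fixed_like_full(mesh, landmarks, frame, half_width: float = 3.0):
    t = (mesh.node_coords - landmarks.point2) @ frame.X
    return np.flatnonzero(np.abs(t) <= half_width)
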