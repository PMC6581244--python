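# infantfem

Finite-element analysis of the developing infant femur.

In infants the femoral head is largely non-ossified cartilage, invisible to
CT, so most published FE models of infant femora are bone-only models of the
diaphysis. `infantfem` implements the complete analysis chain needed to ask
what that omission costs: a parametric synthetic femur (mineralised shaft
plus ossifying proximal epiphysis, with a CT-like intensity field), 10-node
tetrahedral meshing, image-based material mapping, static FE solvers, and a
principal-strain failure criterion for the shaft. It is aimed at
musculoskeletal biomechanics researchers who want a fully scripted,
deposit-free test bed for paediatric whole-bone models.

## Model summary

* **Geometry** — voxel phantom: hollow cortical cylinder with trabecular
  core, ellipsoidal proximal epiphysis on a tilted neck axis, and a smooth
  HU ramp across the metaphyseal transition. Two presets (`4mo`, `7mo`)
  match published overall dimensions of a 4- and a 7-month-old femur
  (lengths 10.55/13.28 cm, epiphysis volumes 1.24/7.91 cm³, total volumes
  13.13/30.79 cm³).
* **Materials** — per-element integrated average modulus
  E = c·ρ(HU)^d (Bonemat-style, pointwise-then-average); diaphysis
  isotropic linear elastic (ν = 0.3), ossifying region porohyperelastic:
  compressible Neo-Hookean W = C10(Ī₁−3) + (1/D1)(J−1)² with
  C10 = E/(4(1+ν)), D1 = 6(1−2ν)/E, ν = 0.20, plus literature permeability
  (0.00455 m⁴/N·s) and void ratio (4.50).
* **Loads** — anatomical frame from the 25%/75% diaphyseal cross-section
  centroids; torsion of 2 kN·mm about the shaft axis or 200 N uniaxial
  loads at the proximal ossification centre (Point 1), fully fixed at the
  distal landmark (Point 2).
* **Failure** — moment/force-to-fail when the first diaphyseal element
  reaches 0.73 % principal strain in tension or 1.04 % in compression.

Solvers: small-strain TET10 elasticity (direct sparse factorisation),
total-Lagrangian Neo-Hookean Newton iteration, and a linear Biot u–p
consolidation mode verified against the Terzaghi series solution.

## Worked example

```bash
infantfem fail --preset 4mo --out run4mo --seed 0
```

or equivalently in Python:

```python
from infantfem.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(preset="4mo", load_cases=["torsion"],
                                  compare_bone_only=True, outdir="run4mo"))
print(manifest["results"]["failure"]["epiphysis_effect"])
```

Output (abridged):

```text
"torsion": {
  "applied_load": 2000.0,           # probe moment, N mm
  "load_to_fail": 13865.3,          # shaft moment to fail, N mm
  "limiting_mode": "tension",
  "max_tensile_strain": 0.001053
},
"epiphysis_effect": {
  "load_to_fail_with_epiphysis": 13865.3,
  "load_to_fail_bone_only": 13712.9,
  "ratio": 1.0111,
  "transition_max_eps1": 0.001917,
  "shaft_median_eps1": 0.000309,
  "concentrated": true
}
```

Reading: under the 2 kN·mm probe torsion the shaft would fail (first in
tension, at the 0.73 % limit) at about 13.9 kN·mm. Including the
cartilaginous epiphysis changes the diaphyseal capacity by ~1 % relative to
the bone-only model — the shaft is insensitive to the epiphysis — but the
metaphyseal transition carries a clear local strain concentration (slab
maximum ≈ 6× the shaft median), which is where epiphysis modelling matters.

Every run writes the phantom (NIfTI + JSON), the mesh and solution fields
(ASCII VTU, Abaqus INP export available), the failure report (JSON) and a
manifest with checksums and stage timings.

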