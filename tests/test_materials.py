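"""HU -> modulus mapping and Neo-Hookean parameter identification."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from infantfem import materials as mat
from infantfem import mesh as mm
from infantfem import phantom as ph


def _uniform_image(hu, shape=(12, 12, 12), spacing=1.0):
    lab = np.full(shape, ph.LABELS["cortical"], np.uint8)
    return ph.VoxelImage(np.full(shape, float(hu)), lab, (spacing,) * 3)


def _box_mesh_inside(shape, spacing, edge):
    lab = np.ones(shape, np.uint8)
    img = ph.VoxelImage(np.zeros(shape, float), lab, (spacing,) * 3)
    return mm.mesh_from_labels(img, edge, None)


class TestNeoHookeanIdentification:
    @pytest.mark.parametrize(
        "E,nu,c10,d1",
        [
            # ossifying-region stiffnesses of the two subjects
            (601.63, 0.20, 125.34, 0.0060),
            (461.23, 0.20, 96.09, 0.0078),
            (1.0, 0.0, 0.25, 6.0),
        ],
    )
    def test_printed_values(self, E, nu, c10, d1):
        C10, D1 = mat.neo_hookean_from_modulus(E, nu)
        assert round(float(C10), 2) == c10
        assert round(float(D1), 4) == d1

    def test_rejects_incompressible(self):
        with pytest.raises(ValueError, match="0.5"):
            mat.neo_hookean_from_modulus(100.0, 0.5)
        with pytest.raises(ValueError, match="positive"):
            mat.neo_hookean_from_modulus(-1.0, 0.2)

    @given(
        E=st.floats(1.0, 2e4),
        nu=st.floats(0.0, 0.49),
    )
    def test_round_trip_identity(self, E, nu):
        C10, D1 = mat.neo_hookean_from_modulus(E, nu)
        E2, nu2 = mat.modulus_from_neo_hookean(C10, D1)
        assert abs(E2 - E) <= 1e-12 * E
        assert abs(nu2 - nu) <= 1e-12 * max(nu, 1e-3)


class TestElementModulus:
    def test_uniform_image_matches_pointwise_law(self):
        img = _uniform_image(800.0)
        mesh = _box_mesh_inside((12, 12, 12), 1.0, 2.0)
        law = mat.DEFAULT_LAW
        E = mat.element_moduli(img, mesh, law)
        assert np.allclose(E, law.modulus(800.0), rtol=1e-12)

    def test_two_material_interface_volume_weighted(self):
        # half-space of HU 200 against HU 1500; elements straddling the
        # interface take the volume-weighted mean of the pointwise moduli
        # (dense-sampling oracle over the element; the pointwise field is
        # the interpolated image, sharp up to the one-voxel blending band)
        shape = (16, 12, 12)
        hu = np.full(shape, 200.0)
        hu[7:] = 1500.0  # interface at x = 7 mm, inside the 4-8 mm cells
        lab = np.ones(shape, np.uint8)
        img = ph.VoxelImage(hu, lab, (1.0, 1.0, 1.0))
        mesh = _box_mesh_inside(shape, 1.0, 4.0)
        law = mat.DEFAULT_LAW
        E = mat.element_moduli(img, mesh, law)
        E_lo, E_hi = law.modulus(200.0), law.modulus(1500.0)
        xm = mesh.node_coords[mesh.connectivity[:, :4], 0]
        strad = (xm.min(axis=1) < 6.2) & (xm.max(axis=1) > 7.8)
        assert strad.any()
        rng = np.random.default_rng(5)
        from infantfem.materials import _masked_interpolate

        for e in np.flatnonzero(strad)[:12]:
            corners = mesh.node_coords[mesh.connectivity[e, :4]]
            bary = rng.dirichlet(np.ones(4), size=50000)
            pts = bary @ corners
            vals, valid = _masked_interpolate(img, pts)
            oracle = law.modulus(vals[valid]).mean()
            assert abs(E[e] - oracle) / oracle < 0.01
            # and within the sharp-mix bracket
            frac_hi = (pts[:, 0] > 7.0).mean()
            mix = frac_hi * E_hi + (1 - frac_hi) * E_lo
            assert E_lo <= E[e] <= E_hi
            assert abs(E[e] - mix) / mix < 0.06  # one-voxel blending band

    def test_monotone_in_hu(self, phantom_4mo, mesh_4mo):
        _, image, _ = phantom_4mo
        E1 = mat.element_moduli(image, mesh_4mo)
        brighter = ph.VoxelImage(
            image.intensities + 50.0, image.labels, image.spacing, image.origin
        )
        E2 = mat.element_moduli(brighter, mesh_4mo)
        assert np.all(E2 >= E1 - 1e-9)

    def test_element_outside_image_rejected(self):
        img = _uniform_image(500.0, shape=(6, 6, 6))
        mesh = _box_mesh_inside((6, 6, 6), 1.0, 3.0)
        shifted = mm.TetMesh10(
            mesh.node_coords + 100.0, mesh.connectivity, mesh.element_region
        )
        with pytest.raises(ValueError, match="outside image"):
            mat.element_moduli(img, shifted)


class TestMaterialField:
    def test_all_diaphysis_mesh_has_no_neo_hookean_records(self):
        img = _uniform_image(700.0)
        mesh = _box_mesh_inside((12, 12, 12), 1.0, 3.0)
        mf = mat.build_material_field(img, mesh)
        assert np.all(mf.kind == mat.KIND_LINEAR)
        assert np.all(np.isnan(mf.C10))

    def test_epiphysis_records_satisfy_identification(
        self, phantom_4mo, mesh_4mo, materials_4mo
    ):
        epi = materials_4mo.kind == mat.KIND_NEO_PORO
        assert epi.any()
        E_from_C10 = 4 * (1 + materials_4mo.nu[epi]) * materials_4mo.C10[epi]
        E_from_D1 = 6 * (1 - 2 * materials_4mo.nu[epi]) / materials_4mo.D1[epi]
        assert np.allclose(E_from_C10, E_from_D1, rtol=1e-10)
        assert np.allclose(E_from_C10, materials_4mo.E[epi], rtol=1e-10)

    def test_modulus_range_4mo(self, materials_4mo):
        E_GPa = materials_4mo.E / 1000.0
        assert E_GPa.min() >= 0.46
        assert E_GPa.max() <= 18.0
        assert 16.0 <= E_GPa.max() <= 18.0

    def test_epiphysis_mean_modulus_7mo(self, phantom_7mo):
        _, image, landmarks = phantom_7mo
        mesh = mm.mesh_from_labels(image, 3.0, landmarks)
        mf = mat.build_material_field(image, mesh)
        epi = mf.kind == mat.KIND_NEO_PORO
        mean_GPa = mf.E[epi].mean() / 1000.0
        assert 0.40 <= mean_GPa <= 0.65

    def test_refinement_stability_of_mean_modulus(self, phantom_4mo, mesh_4mo):
        # uniform 1:8 refinement keeps the geometry; the volume-weighted
        # mean modulus must be stable under the finer in-element sampling
        _, image, _ = phantom_4mo
        fine = mm.subdivide_uniform(mesh_4mo)
        means = []
        for mesh in (mesh_4mo, fine):
            E = mat.element_moduli(image, mesh)
            v = mm.element_volumes(mesh)
            means.append(float((E * v).sum() / v.sum()))
        assert abs(means[0] - means[1]) / means[1] < 0.01

    def test_poroelastic_constants_as_printed(self, materials_4mo):
        assert materials_4mo.permeability == 0.00455
        assert materials_4mo.void_ratio == 4.50
        epi = materials_4mo.kind == mat.KIND_NEO_PORO
        assert np.all(materials_4mo.nu[epi] == 0.20)
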