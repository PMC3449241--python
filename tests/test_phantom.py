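"""Phantom generation: shells, gyri, tensors, 10-20 positions, electrodes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hexstim as hs
from hexstim.phantom import (
    PhantomSpecificationError,
    Tissue,
    angles_from_direction,
    direction_from_angles,
    gyral_ridge_mask,
)


class TestSpherePhantom:
    def test_default_layer_spec_produces_all_six_tissues(self):
        vol = hs.generate_sphere_phantom(resolution=2.0)
        assert set(np.unique(vol.labels).tolist()) == {0, 1, 2, 3, 4, 5, 6}

    def test_all_zero_radii_gives_empty_volume(self):
        spec = tuple((c, 0.0) for c, _ in hs.DEFAULT_LAYERS)
        vol = hs.generate_sphere_phantom(layer_spec=spec, resolution=2.0)
        assert (vol.labels == Tissue.BACKGROUND).all()

    def test_decreasing_radii_rejected(self):
        with pytest.raises(PhantomSpecificationError):
            hs.generate_sphere_phantom(
                layer_spec=((Tissue.WM, 30.0), (Tissue.GM, 20.0)), resolution=2.0
            )

    def test_single_layer_voxel_count_matches_lattice_enumeration(self):
        """Labeled-voxel count equals a brute-force count of lattice points
        whose center lies within the sphere."""
        radius = 5.0
        vol = hs.generate_sphere_phantom(
            layer_spec=((Tissue.GM, radius),), resolution=1.0, margin_mm=3.0
        )
        cx, cy, cz = vol.voxel_centers()
        count = 0
        for x in cx:
            for y in cy:
                for z in cz:
                    if np.sqrt(x * x + y * y + z * z) <= radius:
                        count += 1
        assert vol.count(Tissue.GM) == count > 0

    def test_shells_are_nested_by_radius(self):
        vol = hs.generate_sphere_phantom(resolution=2.0)
        cx, cy, cz = vol.voxel_centers()
        x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
        r = np.sqrt(x * x + y * y + z * z)
        bounds = dict((c, rr) for c, rr in hs.DEFAULT_LAYERS)
        assert r[vol.labels == Tissue.WM].max() <= bounds[Tissue.WM]
        assert r[vol.labels == Tissue.GM].min() > bounds[Tissue.WM]
        assert r[vol.labels == Tissue.CSF].min() > bounds[Tissue.GM]
        assert r[vol.labels == Tissue.SKIN].min() > 81.0  # outside the skull sandwich

    def test_coarse_resolution_warns_about_vanishing_shell(self):
        with pytest.warns(UserWarning, match="thinnest shell"):
            hs.generate_sphere_phantom(resolution=4.0)

    def test_gyri_swap_csf_for_gm_only(self):
        plain = hs.generate_sphere_phantom(resolution=2.0)
        ridged = hs.generate_sphere_phantom(resolution=2.0, gyrus_spec=hs.GyrusSpec())
        assert ridged.count(Tissue.GM) > plain.count(Tissue.GM)
        assert ridged.count(Tissue.CSF) < plain.count(Tissue.CSF)
        for code in (Tissue.SKIN, Tissue.SKULL_COMPACTA, Tissue.SKULL_SPONGIOSA, Tissue.WM):
            assert ridged.count(code) == plain.count(code)
        gained = ridged.count(Tissue.GM) - plain.count(Tissue.GM)
        lost = plain.count(Tissue.CSF) - ridged.count(Tissue.CSF)
        assert gained == lost
        changed = ridged.labels != plain.labels
        assert changed.any()
        assert gyral_ridge_mask(plain, hs.GyrusSpec())[changed].all()


class TestTensorField:
    def test_unit_ratio_gives_isotropic_tensors(self, coarse_phantom):
        field = hs.generate_wm_tensor_field(coarse_phantom, anisotropy_ratio=1.0)
        eye = np.eye(3)
        scales = field.tensors[:, 0, 0]
        assert np.allclose(field.tensors, scales[:, None, None] * eye, atol=1e-14)

    def test_radial_pattern_on_x_axis(self):
        # odd-sized hand-built volume so voxel centers fall exactly on +x axis
        labels = np.full((9, 9, 9), Tissue.WM, dtype=np.int16)
        vol = hs.LabelVolume(labels, 1.0, np.zeros(3))
        field = hs.generate_wm_tensor_field(vol, anisotropy_ratio=4.0, fiber_pattern="radial")
        idx = np.argwhere(field.defined_mask)
        centers = idx * vol.voxel_size - 4.0  # grid center at (4,4,4)
        on_axis = (centers[:, 1] == 0) & (centers[:, 2] == 0) & (centers[:, 0] > 0)
        assert on_axis.any()
        for t in field.tensors[on_axis]:
            w, v = np.linalg.eigh(t)
            principal = v[:, np.argmax(w)]
            assert abs(abs(principal[0]) - 1.0) < 1e-9
            assert np.max(w) / np.min(w) == pytest.approx(4.0)

    def test_tensors_defined_exactly_on_wm(self, coarse_phantom):
        field = hs.generate_wm_tensor_field(coarse_phantom, anisotropy_ratio=2.0)
        assert (field.defined_mask == (coarse_phantom.labels == Tissue.WM)).all()

    def test_subunit_ratio_rejected(self, coarse_phantom):
        with pytest.raises(PhantomSpecificationError):
            hs.generate_wm_tensor_field(coarse_phantom, anisotropy_ratio=0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(ratio=st.floats(min_value=1.0, max_value=100.0))
    def test_tensors_spd_for_any_ratio(self, ratio):
        vol = hs.generate_sphere_phantom(
            layer_spec=((Tissue.WM, 10.0), (Tissue.GM, 14.0)), resolution=2.0, margin_mm=3.0
        )
        field = hs.generate_wm_tensor_field(vol, anisotropy_ratio=ratio, fiber_pattern="radial")
        assert field.is_spd()


class TestTenTwenty:
    def test_vertex_and_outer_ring(self):
        assert hs.ten_twenty_direction("Cz")[0] == 0.0
        assert hs.ten_twenty_direction("Oz") == (90.0, 180.0)

    def test_left_right_mirror_pairs(self):
        for left, right in (("F7", "F8"), ("P7", "P8")):
            il, al = hs.ten_twenty_direction(left)
            ir, ar = hs.ten_twenty_direction(right)
            assert il == ir
            assert al == -ar

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            hs.ten_twenty_direction("T3")

    def test_direction_angle_round_trip(self):
        for label in ("FPz", "Oz", "F7", "P8"):
            incl, az = hs.ten_twenty_direction(label)
            back = angles_from_direction(direction_from_angles(incl, az))
            assert back[0] == pytest.approx(incl, abs=1e-9)
            assert back[1] == pytest.approx(az, abs=1e-9)


class TestElectrodePlacement:
    def test_empty_montage_is_identity(self, coarse_phantom):
        out = hs.place_electrode_patches(coarse_phantom, hs.Montage(total_current=1e-3))
        assert (out.labels == coarse_phantom.labels).all()

    def test_patch_slab_thickness_and_tissue_contacts(self):
        vol = hs.generate_sphere_phantom(resolution=2.0)
        montage = hs.standard_montage("FPz-Oz")
        out = hs.place_electrode_patches(vol, montage)
        cx, cy, cz = out.voxel_centers()
        x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
        r = np.sqrt(x * x + y * y + z * z)
        for code in (Tissue.ELECTRODE_ANODE, Tissue.ELECTRODE_CATHODE):
            sel = out.labels == code
            assert sel.any()
            extent = r[sel].max() - r[sel].min() + out.voxel_size
            assert abs(extent - 4.0) <= out.voxel_size
        # brain labels untouched; only background voxels were relabeled
        changed = out.labels != vol.labels
        assert (vol.labels[changed] == Tissue.BACKGROUND).all()
        # electrode voxels touch only background, skin, or other electrode voxels
        elec = np.isin(out.labels, Tissue.ELECTRODES)
        allowed = elec | (out.labels == Tissue.BACKGROUND) | (out.labels == Tissue.SKIN)
        for axis in range(3):
            for shift in (1, -1):
                neigh_ok = np.roll(allowed, shift, axis=axis)
                sl = [slice(None)] * 3
                sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
                neigh_ok[tuple(sl)] = True
                assert neigh_ok[elec].all()

    def test_footprint_area_approximates_patch_area(self):
        """Summed outward-projected face area of the exposed electrode surface
        approximates the 7 cm x 5 cm patch within voxelization tolerance."""
        from hexstim.fem import electrode_exposed_area

        vol = hs.generate_sphere_phantom(resolution=2.0)
        out = hs.place_electrode_patches(vol, hs.standard_montage("FPz-Oz"))
        mesh = hs.voxels_to_hex_mesh(out)
        area_cm2 = electrode_exposed_area(mesh, Tissue.ELECTRODE_ANODE) * 1e4
        assert area_cm2 == pytest.approx(35.0, rel=0.10)

    def test_overlapping_patches_rejected(self):
        vol = hs.generate_sphere_phantom(resolution=4.0)
        montage = hs.Montage(
            patches=[
                hs.ElectrodePatch((90.0, 0.0), "anode"),
                hs.ElectrodePatch((90.0, 10.0), "cathode"),
            ]
        )
        with pytest.raises(PhantomSpecificationError, match="overlap"):
            hs.place_electrode_patches(vol, montage)

    def test_montage_requires_both_polarities(self):
        with pytest.raises(PhantomSpecificationError):
            hs.Montage(patches=[hs.ElectrodePatch((90.0, 0.0), "anode")])


def test_nifti_round_trip(tmp_path, coarse_phantom):
    path = tmp_path / "phantom.nii.gz"
    hs.save_label_volume(coarse_phantom, path)
    back = hs.load_label_volume(path)
    assert (back.labels == coarse_phantom.labels).all()
    assert back.voxel_size == coarse_phantom.voxel_size
    assert np.allclose(back.origin, coarse_phantom.origin)
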