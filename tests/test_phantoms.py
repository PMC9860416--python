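"""Synthetic phantom factory: geometry, DVFs, session doses, scenarios."""

import numpy as np
import pytest

from doseaccqa import (
    EDPhantomSpec,
    GaussianDVFSpec,
    GeometryError,
    RigidTransform,
    apply_dvf,
    jacobian_determinant,
    make_ed_phantom,
    make_gaussian_dvf,
    make_insert_swap_dvf,
    make_pelvis_phantom,
    make_scenario,
    synth_session_dose,
    warp_mask,
)
from doseaccqa.grid import index_to_world
from doseaccqa.phantoms import clock_position


class TestEDPhantom:
    def test_target_centroid_at_six_oclock(self, ed_phantom):
        _, structs = ed_phantom
        expected = clock_position(6, 60.0)
        assert np.abs(structs.centroid("GTV") - expected).max() <= 2.0  # one voxel

    def test_ptv_is_proper_dilation_of_gtv(self, ed_phantom):
        _, structs = ed_phantom
        gtv, ptv = structs.masks["GTV"], structs.masks["PTV"]
        assert ptv.sum() > gtv.sum()
        assert not (gtv & ~ptv).any()

    def test_structure_inventory(self, ed_phantom):
        """One target, a boost subvolume, seven OARs, a PTV, and the body."""
        _, structs = ed_phantom
        names = set(structs.names)
        assert {f"OAR{i}" for i in range(1, 8)} <= names
        assert {"GTV", "boost", "PTV", "BODY"} <= names
        assert len(names) == 11
        assert not (structs.masks["boost"] & ~structs.masks["GTV"]).any()

    def test_overlapping_inserts_rejected(self):
        spec = EDPhantomSpec(insert_clock_positions=(6, 7, 5, 9), insert_radius=18.0)
        with pytest.raises(GeometryError, match="overlap"):
            make_ed_phantom(spec)

    def test_ct_shows_inserts_regardless_of_contours(self, ed_phantom):
        ct, structs = ed_phantom
        assert ct.values[structs.masks["OAR3"]].mean() > 500  # bone-like insert
        assert ct.values.min() == -1000.0


class TestPelvisPhantom:
    def test_organs_disjoint(self):
        _, structs = make_pelvis_phantom()
        organs = ["prostate", "bladder", "rectum", "bowel", "femur_l", "femur_r"]
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                assert not (structs.masks[a] & structs.masks[b]).any(), (a, b)

    def test_structure_inventory(self):
        _, structs = make_pelvis_phantom()
        assert {"prostate", "PTV", "bladder", "rectum", "bowel",
                "femur_l", "femur_r"} <= set(structs.names)

    def test_deterministic_regeneration(self):
        ct1, _ = make_pelvis_phantom()
        ct2, _ = make_pelvis_phantom()
        assert np.array_equal(ct1.values, ct2.values)


class TestGaussianDVF:
    def geom(self):
        return make_pelvis_phantom()[0].geometry

    def test_zero_peak_gives_zero_field(self):
        d = make_gaussian_dvf(GaussianDVFSpec((0, 0, 0), 15.0, (0, 0, 0)), self.geom())
        assert not d.displacements.any()

    def test_peak_reached_at_center(self):
        geom = self.geom()
        center = tuple(index_to_world(geom, np.array([30, 30, 20])))  # a voxel center
        d = make_gaussian_dvf(GaussianDVFSpec(center, 15.0, (5.0, -3.0, 1.0)), geom)
        assert d.max_magnitude() == pytest.approx(np.linalg.norm([5.0, -3.0, 1.0]), abs=1e-9)

    def test_folding_spec_rejected(self):
        with pytest.raises(GeometryError, match="fold"):
            make_gaussian_dvf(GaussianDVFSpec((0, 0, 0), 5.0, (9.0, 0, 0)), self.geom())

    def test_default_spec_jacobian_positive(self):
        d = make_gaussian_dvf(GaussianDVFSpec((0, -20, 8), 15.0, (0, 6.7, -4.4)), self.geom())
        assert jacobian_determinant(d).values.min() > 0.0


class TestInsertSwapDVF:
    def test_no_swap_gives_near_zero_field(self, ed_phantom):
        _, structs = ed_phantom
        d = make_insert_swap_dvf(structs, structs, structs.geometry)
        assert d.max_magnitude() < 0.5

    def test_swapped_target_centroid_maps_onto_reference(self, swap_bundle):
        ref = swap_bundle.reference_structures
        for f in swap_bundle.fractions:
            warped = warp_mask(
                f.session_structures.masks["GTV"], f.session_structures.geometry,
                f.dvf, f.rigid,
            )
            c = index_to_world(ref.geometry, np.argwhere(warped).mean(axis=0))
            assert np.linalg.norm(c - ref.centroid("GTV")) < 2.0

    def test_rotation_field_volume_preserving_in_annulus(self, swap_bundle):
        d = swap_bundle.fractions[0].dvf
        det = jacobian_determinant(d)
        geom = d.geometry
        pts = geom.voxel_centers()
        r = np.hypot(pts[:, 0], pts[:, 1]).reshape(geom.shape)
        annulus = (r > 45.0) & (r < 75.0)
        annulus[:, :, :2] = annulus[:, :, -2:] = False  # exclude FD edge voxels
        assert np.abs(det.values[annulus] - 1.0).max() < 0.05
        assert det.values.min() > 0.0


class TestSessionDose:
    def test_target_mean_matches_prescription_without_noise(self, ed_phantom, ed_dose):
        _, structs = ed_phantom
        mean = ed_dose.values[structs.masks["GTV"]].mean()
        assert abs(mean - 220.0) <= 0.02 * 220.0

    def test_dose_nonnegative(self, ed_phantom):
        _, structs = ed_phantom
        dose = synth_session_dose(structs, noise_sd=5.0, seed=2)
        assert dose.values.min() >= 0.0

    def test_distal_oar_below_half_prescription(self, ed_phantom, ed_dose):
        _, structs = ed_phantom
        for name in ("OAR3", "OAR4", "OAR5", "OAR6"):
            assert ed_dose.values[structs.masks[name]].mean() < 0.5 * 220.0

    def test_prescription_must_be_positive(self, ed_phantom):
        _, structs = ed_phantom
        with pytest.raises(ValueError):
            synth_session_dose(structs, rx_per_fraction=-5.0)


class TestScenarios:
    def test_control_has_identity_transforms(self, control_bundle):
        for f in control_bundle.fractions:
            assert f.rigid.is_identity()
            assert f.dvf.max_magnitude() == 0.0

    def test_insert_swap_fraction_targets(self, swap_bundle):
        assert [f.target_hour for f in swap_bundle.fractions] == [7, 5]
        assert set(swap_bundle.swapped_structures) == {"OAR1", "OAR2"}

    def test_setup_offsets_bounded(self, swap_bundle):
        for f in swap_bundle.fractions:
            assert np.linalg.norm(f.rigid.translation) < 3.0 + 2.0 * np.deg2rad(2) * 90

    def test_same_seed_reproduces_bundle(self):
        a = make_scenario("insert_swap", 2, seed=5)
        b = make_scenario("insert_swap", 2, seed=5)
        assert np.array_equal(a.fractions[0].session_dose.values,
                              b.fractions[0].session_dose.values)
        assert np.array_equal(a.fractions[1].rigid.matrix, b.fractions[1].rigid.matrix)

    def test_distinct_seeds_spread_session_means(self):
        """Repeated measurements must show nonzero spread for range reporting."""
        means = []
        for seed in range(4):
            b = make_scenario("insert_swap", 1, seed=seed)
            f = b.fractions[0]
            means.append(f.session_dose.values[f.session_structures.masks["GTV"]].mean())
        assert np.std(means) > 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("mystery")

    def test_generated_swap_fields_diffeomorphic(self, swap_bundle):
        for f in swap_bundle.fractions:
            assert jacobian_determinant(f.dvf).values.min() > 0.0

    def test_pelvis_gaussian_reference_ct_differs_from_sessions(self):
        b = make_scenario("pelvis_gaussian", 1, seed=2)
        assert b.fractions[0].dvf.max_magnitude() > 5.0
        assert not np.array_equal(b.reference_ct.values, b.fractions[0].session_ct.values)
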