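"""Warping primitives: rigid application, DVF application, composition, inversion."""

import numpy as np
import pytest

from doseaccqa import (
    DVFInversionError,
    GridGeometry,
    ImageGrid,
    RigidTransform,
    VectorField,
    apply_dvf,
    apply_rigid,
    compose_rigid_then_dvf,
    convert_convention,
    invert_dvf,
    jacobian_determinant,
)
from doseaccqa.phantoms import GaussianDVFSpec, make_gaussian_dvf

GEOM = GridGeometry((31, 31, 31), (-30.0, -30.0, -30.0), (2.0, 2.0, 2.0))


def hotspot_grid(center=(0.0, 0.0, 0.0), sigma=4.0):
    pts = GEOM.voxel_centers()
    r2 = ((pts - np.asarray(center)) ** 2).sum(axis=1)
    return ImageGrid((100.0 * np.exp(-r2 / (2 * sigma ** 2))).reshape(GEOM.shape),
                     GEOM.origin, GEOM.spacing)


def dose_centroid(grid):
    pts = grid.geometry.voxel_centers()
    w = grid.values.ravel()
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def gaussian_field(sigma=15.0, peak=(8.0, 0.0, 0.0)):
    return make_gaussian_dvf(GaussianDVFSpec((0.0, 0.0, 0.0), sigma, peak), GEOM)


class TestApplyRigid:
    def test_identity_is_exact(self):
        grid = hotspot_grid()
        out = apply_rigid(grid, RigidTransform.identity())
        assert np.array_equal(out.values, grid.values)

    def test_translation_preserves_constant_interior(self):
        grid = ImageGrid(np.full(GEOM.shape, 80.0), GEOM.origin, GEOM.spacing)
        out = apply_rigid(grid, RigidTransform.from_translation((5.0, 0.0, 0.0)))
        assert np.allclose(out.values[2:-4, 2:-2, 2:-2], 80.0)

    def test_hotspot_shifts_against_translation(self):
        """Pull-back: sampling dose(T(x)) moves the hotspot by -t in the output."""
        grid = hotspot_grid(center=(0.0, 0.0, 0.0))
        t = np.array([6.0, -4.0, 2.0])
        out = apply_rigid(grid, RigidTransform.from_translation(t))
        assert np.abs(dose_centroid(out) - (dose_centroid(grid) - t)).max() < 0.1


class TestApplyDVF:
    def test_zero_field_is_exact(self):
        grid = hotspot_grid()
        out = apply_dvf(grid, VectorField.zeros(GEOM))
        assert np.array_equal(out.values, grid.values)

    def test_constant_field_equals_rigid_translation(self):
        grid = hotspot_grid()
        t = (4.0, 0.0, 0.0)
        dvf = VectorField(np.broadcast_to(np.array(t), GEOM.shape + (3,)).copy(),
                          GEOM.origin, GEOM.spacing)
        a = apply_dvf(grid, dvf)
        b = apply_rigid(grid, RigidTransform.from_translation(t))
        assert np.abs(a.values - b.values).max() < 1e-9

    def test_pullback_respects_input_range(self):
        grid = hotspot_grid()
        out = apply_dvf(grid, gaussian_field())
        assert out.values.min() >= 0.0
        assert out.values.max() <= grid.values.max() + 1e-9

    def test_gaussian_round_trip_within_two_percent(self):
        # smooth dose (10 mm scale) so interpolation error does not mask the
        # deformation round-trip error the contract is about
        grid = hotspot_grid(sigma=10.0)
        d = gaussian_field()
        warped = apply_dvf(grid, d)
        restored = apply_dvf(warped, invert_dvf(d))
        interior = (slice(3, -3),) * 3
        err = np.abs(restored.values[interior] - grid.values[interior]).max()
        assert err < 0.02 * grid.values.max()


class TestCompose:
    def test_identity_rigid_gives_same_field(self):
        d = gaussian_field()
        e = compose_rigid_then_dvf(RigidTransform.identity(), d)
        assert np.abs(e.displacements - d.displacements).max() < 1e-9

    def test_zero_field_gives_rigid_displacement(self):
        t = RigidTransform.from_translation((3.0, -1.0, 2.0))
        e = compose_rigid_then_dvf(t, VectorField.zeros(GEOM))
        assert np.allclose(e.displacements, [3.0, -1.0, 2.0])

    def test_one_step_matches_two_step_within_one_percent(self):
        grid = hotspot_grid(sigma=10.0)
        t = RigidTransform.compose(
            RigidTransform.from_rotation_z(1.5), RigidTransform.from_translation((2.0, 1.0, -1.0))
        )
        d = gaussian_field(peak=(5.0, 0.0, 3.0))
        two_step = apply_dvf(apply_rigid(grid, t), d)
        one_step = apply_dvf(grid, compose_rigid_then_dvf(t, d))
        interior = (slice(2, -2),) * 3
        err = np.abs(two_step.values[interior] - one_step.values[interior]).max()
        assert err < 0.01 * grid.values.max()


class TestInvert:
    def test_zero_field_inverts_to_zero(self):
        inv = invert_dvf(VectorField.zeros(GEOM))
        assert np.allclose(inv.displacements, 0.0)

    def test_constant_field_inverts_to_negative(self):
        c = np.array([2.5, -1.0, 0.5])
        dvf = VectorField(np.broadcast_to(c, GEOM.shape + (3,)).copy(), GEOM.origin, GEOM.spacing)
        inv = invert_dvf(dvf)
        interior = (slice(4, -4),) * 3
        assert np.abs(inv.displacements[interior] + c).max() < 0.1

    def test_gaussian_residual_below_tolerance(self):
        d = gaussian_field()
        inv = invert_dvf(d, max_iter=50, tol_mm=0.1)
        pts = GEOM.voxel_centers()
        resid = inv.displacements.reshape(-1, 3) + d.sample(pts + inv.displacements.reshape(-1, 3))
        interior = np.all(np.abs(pts) <= 10.0, axis=1)
        assert np.sqrt((resid[interior] ** 2).sum(axis=1)).max() < 0.1

    def test_nonconvergence_raises_with_residual(self):
        d = gaussian_field()
        with pytest.raises(DVFInversionError) as exc:
            invert_dvf(d, max_iter=1, tol_mm=1e-9)
        assert exc.value.residual_mm > 0

    def test_push_pull_converter_round_trips(self):
        d = gaussian_field(peak=(5.0, 2.0, 0.0))
        back = convert_convention(convert_convention(d))
        interior = (slice(4, -4),) * 3
        assert np.abs(back.displacements[interior] - d.displacements[interior]).max() < 0.25


class TestJacobian:
    def test_zero_field_has_unit_determinant(self):
        det = jacobian_determinant(VectorField.zeros(GEOM))
        assert np.allclose(det.values, 1.0)

    def test_uniform_scaling_closed_form(self):
        pts = GEOM.voxel_centers()
        disp = (0.1 * pts).reshape(GEOM.shape + (3,))
        det = jacobian_determinant(VectorField(disp, GEOM.origin, GEOM.spacing))
        assert np.allclose(det.values[1:-1, 1:-1, 1:-1], 1.1 ** 3, atol=1e-9)

    def test_default_gaussian_is_diffeomorphic(self):
        det = jacobian_determinant(gaussian_field())
        assert det.values.min() > 0.0
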