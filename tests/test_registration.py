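"""Deformable and rigid registration: identity, recovery, smoothness,
field sampling and resampling contracts."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from gridwarp_qa.registration import (
    RegistrationConfig,
    RigidTransform,
    apply_deformation,
    bspline_register,
    rigid_align,
    sample_field,
)
from gridwarp_qa.synthetic import marker_positions, true_marker_displacements
from gridwarp_qa.volume import DeformationField, ImageVolume

from conftest import SMALL_SPACING


class TestConfig:
    def test_control_spacing_must_exceed_voxel(self, small_ct):
        cfg = RegistrationConfig(control_point_spacing=2.0)
        with pytest.raises(ValueError, match="control_point_spacing"):
            cfg.resolved_cp_spacing(small_ct)

    def test_default_control_spacing(self, small_ct):
        assert RegistrationConfig().resolved_cp_spacing(small_ct) == 5 * SMALL_SPACING

    @pytest.mark.parametrize("bad", [dict(pyramid_levels=0), dict(similarity="mse"),
                                     dict(bending_energy_weight=-1.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            RegistrationConfig(**bad)


class TestBsplineRegistration:
    def test_identity_registration_is_null(self, small_ct_masked, reg_config, body_mask):
        """Registering an image to itself yields a vanishing field in the body."""
        field = bspline_register(small_ct_masked, small_ct_masked, reg_config, fixed_mask=body_mask)
        assert np.abs(field.data[body_mask]).max() < 0.1 * SMALL_SPACING

    def test_smooth_warp_recovered_at_markers(
        self, recovered_field, small_spec, radial_model
    ):
        """A smooth radial warp is recovered to sub-half-voxel RMS at markers."""
        pos = marker_positions(small_spec)
        gt = true_marker_displacements(small_spec, radial_model)
        rec = sample_field(recovered_field, pos)
        err = np.linalg.norm(rec - gt[["ux_mm", "uy_mm", "uz_mm"]].to_numpy(), axis=1)
        assert np.sqrt(np.mean(err**2)) < 0.5 * SMALL_SPACING

    def test_bending_weight_does_not_increase_roughness(
        self, small_mr, small_ct_masked, body_mask
    ):
        """Doubling the bending-energy weight cannot roughen the field:
        the optimised bending energy is non-increasing in the weight."""
        energies = []
        for w in (1e-3, 2e-3, 4e-3):
            cfg = RegistrationConfig(
                control_point_spacing=24.0, pyramid_levels=2, max_iterations=80,
                bending_energy_weight=w,
            )
            f = bspline_register(small_mr, small_ct_masked, cfg, fixed_mask=body_mask)
            assert np.isfinite(f.meta["bending_energy"])
            energies.append(f.meta["bending_energy"])
        assert energies[1] <= energies[0] + 1e-12
        assert energies[2] <= energies[1] + 1e-12

    def test_housing_mask_reduces_false_rim_deformation(
        self, small_ct, small_ct_masked, small_mr_undistorted, small_spec, reg_config
    ):
        """On a zero-distortion pair, masking the CT housing shrinks the
        spurious deformation at the phantom rim (the failure mode the
        masking step exists to prevent)."""
        f_unmasked = bspline_register(
            small_mr_undistorted, small_ct, reg_config, fixed_mask=small_ct.data > 10
        )
        f_masked = bspline_register(
            small_mr_undistorted, small_ct_masked, reg_config,
            fixed_mask=small_ct_masked.data > 10,
        )
        shape = small_ct.grid_shape
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        w = small_ct.index_to_world(np.stack([ii, jj, kk], -1).reshape(-1, 3))
        rho = np.hypot(w[:, 0], w[:, 1]).reshape(shape)
        rim = (rho > small_spec.body_diameter / 2 - 12) & (rho < small_spec.body_diameter / 2)
        assert np.mean(np.linalg.norm(f_masked.data[rim], axis=-1)) < np.mean(
            np.linalg.norm(f_unmasked.data[rim], axis=-1)
        )

    def test_nonfinite_input_rejected(self, small_ct_masked):
        bad = small_ct_masked.with_data(
            np.where(small_ct_masked.data > 1e9, np.nan, small_ct_masked.data)
        )
        bad.data[0, 0, 0] = np.nan
        from gridwarp_qa.registration import RegistrationError

        with pytest.raises(RegistrationError):
            bspline_register(bad, small_ct_masked)

    def test_sitk_driver_agrees_with_builtin(
        self, small_mr, small_ct_masked, body_mask, small_spec, radial_model, recovered_field
    ):
        """Independent cross-check: the SimpleITK B-spline driver recovers
        marker displacements consistent with the built-in optimiser."""
        pytest.importorskip("SimpleITK")
        cfg = RegistrationConfig(
            control_point_spacing=24.0, pyramid_levels=2, max_iterations=60, backend="sitk"
        )
        f_sitk = bspline_register(small_mr, small_ct_masked, cfg, fixed_mask=body_mask)
        pos = marker_positions(small_spec)
        truth = true_marker_displacements(small_spec, radial_model)[
            ["ux_mm", "uy_mm", "uz_mm"]
        ].to_numpy()
        err_sitk = np.linalg.norm(sample_field(f_sitk, pos) - truth, axis=1)
        # both routes must land within a voxel of the ground truth
        assert np.sqrt(np.mean(err_sitk**2)) < 1.0 * SMALL_SPACING
        agree = np.linalg.norm(
            sample_field(f_sitk, pos) - sample_field(recovered_field, pos), axis=1
        )
        assert np.sqrt(np.mean(agree**2)) < 1.0 * SMALL_SPACING


class TestApplyDeformation:
    def test_zero_field_is_identity(self, small_mr):
        zero = DeformationField(
            data=np.zeros(small_mr.grid_shape + (3,)), **small_mr.geometry_like()
        )
        out = apply_deformation(small_mr, zero)
        assert np.allclose(out.data, small_mr.data)

    def test_constant_field_on_uniform_image(self, small_mr):
        uni = small_mr.with_data(np.full(small_mr.grid_shape, 7.0))
        const = DeformationField(
            data=np.full(small_mr.grid_shape + (3,), 5.0), **small_mr.geometry_like()
        )
        out = apply_deformation(uni, const, background=7.0)
        assert np.allclose(out.data, 7.0)

    def test_deformed_mr_markers_land_on_ct_markers(
        self, small_mr, recovered_field, small_spec
    ):
        """Applying the recovered field to the MR returns the markers to
        their CT positions within half a voxel."""
        deformed = apply_deformation(small_mr, recovered_field)
        lab, n = ndimage.label(deformed.data > 600)
        assert n == 27
        com = ndimage.center_of_mass(deformed.data, lab, range(1, n + 1))
        cents = np.atleast_2d(deformed.index_to_world(np.asarray(com, float)))
        pos = marker_positions(small_spec)
        errs = [np.min(np.linalg.norm(cents - p, axis=1)) for p in pos]
        assert max(errs) < 0.5 * SMALL_SPACING


class TestSampleField:
    @pytest.fixture()
    def random_field(self):
        rng = np.random.default_rng(4)
        return DeformationField(
            data=rng.normal(size=(9, 9, 9, 3)), spacing=(4.0, 4.0, 4.0),
            origin=(-16.0, -16.0, -16.0),
        )

    def test_grid_node_returns_stored_vector(self, random_field):
        pt = random_field.index_to_world([3, 5, 2])
        assert np.allclose(sample_field(random_field, [pt])[0], random_field.data[3, 5, 2])

    def test_midpoint_of_linear_field_is_average(self):
        ii, jj, kk = np.meshgrid(*(np.arange(6),) * 3, indexing="ij")
        data = np.stack([2.0 * ii, -1.0 * jj, 0.5 * kk], axis=-1)
        f = DeformationField(data=data, spacing=(2.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0))
        mid = (f.index_to_world([1, 1, 1]) + f.index_to_world([2, 1, 1])) / 2
        expected = (f.data[1, 1, 1] + f.data[2, 1, 1]) / 2
        assert np.allclose(sample_field(f, [mid])[0], expected)

    def test_outside_points_rejected(self, random_field):
        with pytest.raises(ValueError, match="outside"):
            sample_field(random_field, [[1000.0, 0.0, 0.0]])

    def test_polynomial_field_within_interpolation_bound(self, radial_model):
        """Sampling a rasterised smooth field at random points agrees with
        the analytic model within the trilinear interpolation error bound
        (sum over axes of max|second difference| / 8)."""
        sp = 4.0
        n = 24
        origin = -(n - 1) / 2 * sp
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        pts = np.stack([ii, jj, kk], -1).reshape(-1, 3) * sp + origin
        data = radial_model.displacement(pts).reshape(n, n, n, 3)
        f = DeformationField(data=data, spacing=(sp,) * 3, origin=(origin,) * 3)
        bound = sum(
            np.abs(np.diff(data, n=2, axis=ax)).max() for ax in range(3)
        ) / 8.0 + 1e-12
        rng = np.random.default_rng(11)
        q = rng.uniform(origin + sp, -origin - sp, size=(200, 3))
        err = np.abs(sample_field(f, q) - radial_model.displacement(q)).max()
        assert err <= bound


class TestRigidAlign:
    def test_identity_recovered_for_equal_images(self, small_ct_masked):
        tr, res = rigid_align(small_ct_masked, small_ct_masked)
        assert np.linalg.norm(tr.translation) < 0.2
        assert tr.rotation_angle_deg() < 0.1
        assert np.allclose(res.data, small_ct_masked.data, atol=1e-6)

    def test_small_translation_recovered(self, small_ct_masked):
        """A 3 mm offset is recovered to 0.2 mm / 0.1 degrees."""
        d = np.array([3.0, 0.0, 0.0])
        moving = ImageVolume(
            data=small_ct_masked.data,
            spacing=small_ct_masked.spacing,
            origin=tuple(np.asarray(small_ct_masked.origin) + d),
        )
        tr, res = rigid_align(moving, small_ct_masked)
        assert np.linalg.norm(tr.translation - d) < 0.2
        assert tr.rotation_angle_deg() < 0.1
        # resampled moving matches the fixed image away from the boundary
        core = (slice(4, -4),) * 3
        assert np.abs(res.data[core] - small_ct_masked.data[core]).max() < 60.0

    def test_full_grid_period_offset_degenerate(self, small_ct_masked, small_spec):
        """Offsetting by one full marker-grid period is the documented
        failure mode: either the warning path triggers or the correct lock
        is still found."""
        d = np.array([small_spec.grid_spacing[0], 0.0, 0.0])
        moving = ImageVolume(
            data=small_ct_masked.data,
            spacing=small_ct_masked.spacing,
            origin=tuple(np.asarray(small_ct_masked.origin) + d),
        )
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            tr, _ = rigid_align(moving, small_ct_masked)
        warned = any("identity" in str(w.message) for w in rec)
        correct = np.linalg.norm(tr.translation - d) < 0.5 * SMALL_SPACING
        assert warned or correct

    def test_rigid_transform_validation(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.eye(3) * 2.0)
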