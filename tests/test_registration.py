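"""Registration engine: demons forces, velocity composition, exponentials,
warping, symmetric registration and affine pre-alignment."""
import numpy as np
import pytest
from scipy import ndimage

from morphodist.registration import (
    RegistrationParams,
    _compose_disp,
    affine_align,
    compose_velocity,
    demons_update,
    exp_field,
    register_symmetric,
    warp,
)
from morphodist.volumes import (
    DeformationField,
    Grid,
    GridMismatchError,
    ImageVolume,
    LabelVolume,
    VelocityField,
)
from conftest import gaussian_blob, smooth_vector_field


# ---------------------------------------------------------------------------
# demons forces


class TestDemonsUpdate:
    def test_identical_images_give_zero_update(self, grid16):
        img = ImageVolume(gaussian_blob((16, 16, 16), (8, 8, 8)), grid16)
        u = demons_update(img, img, RegistrationParams())
        assert np.abs(u.data).max() == 0

    def test_unit_ramp_gives_half_voxel_force(self, grid16):
        # I_fixed = x, I_warped = x - 1, sigma_x = 1:
        # u_x = diff * g / (g^2 + diff^2) = 1 * 1 / (1 + 1) = 0.5
        ramp = np.broadcast_to(
            np.arange(16, dtype=float).reshape(16, 1, 1), (16, 16, 16)
        ).copy()
        fixed = ImageVolume(ramp, grid16)
        moved = ImageVolume(ramp - 1.0, grid16)
        u = demons_update(fixed, moved, RegistrationParams())
        interior = u.data[1:-1]
        np.testing.assert_allclose(interior[..., 0], 0.5, atol=1e-12)
        np.testing.assert_allclose(interior[..., 1:], 0.0, atol=1e-12)

    def test_flat_fixed_image_gives_zero_thirion_force(self, grid16):
        fixed = ImageVolume(np.full((16, 16, 16), 0.3), grid16)
        moved = ImageVolume(np.random.default_rng(0).random((16, 16, 16)), grid16)
        u = demons_update(fixed, moved, RegistrationParams(force_type="thirion"))
        assert np.abs(u.data).max() == 0

    def test_grid_mismatch_raises(self, grid16, grid32):
        a = ImageVolume(np.zeros((16, 16, 16)), grid16)
        b = ImageVolume(np.zeros((32, 32, 32)), grid32)
        with pytest.raises(GridMismatchError):
            demons_update(a, b, RegistrationParams())


# ---------------------------------------------------------------------------
# velocity composition (BCH)


class TestComposeVelocity:
    @pytest.mark.parametrize("order", ["zeroth", "first"])
    def test_zero_update_returns_v(self, order, grid16):
        rng = np.random.default_rng(3)
        v = VelocityField(smooth_vector_field(rng, (16, 16, 16), 0.5), grid16)
        u = VelocityField(np.zeros((16, 16, 16, 3)), grid16)
        z = compose_velocity(v, u, order)
        np.testing.assert_allclose(z.data, v.data, atol=1e-12)

    @pytest.mark.parametrize("order", ["zeroth", "first"])
    def test_constant_fields_add(self, order, grid16):
        v = VelocityField(np.full((16, 16, 16, 3), 0.4), grid16)
        u = VelocityField(np.full((16, 16, 16, 3), -0.1), grid16)
        z = compose_velocity(v, u, order)
        np.testing.assert_allclose(z.data, 0.3, atol=1e-12)

    def test_first_order_beats_zeroth_on_smooth_fields(self):
        # exp(Z(v,u)) should approximate exp(v) o exp(u) better with the
        # Lie-bracket correction than with plain addition.
        g = Grid((8, 8, 8))
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(5):
            v = VelocityField(smooth_vector_field(rng, (8, 8, 8), 0.5), g)
            u = VelocityField(smooth_vector_field(rng, (8, 8, 8), 0.5), g)
            true = _compose_disp(exp_field(v).data, exp_field(u).data, g)
            errs = {}
            for order in ("zeroth", "first"):
                z = compose_velocity(v, u, order)
                d = exp_field(z).data
                errs[order] = np.sqrt(((d - true) ** 2).sum(-1)).max()
            if errs["first"] < errs["zeroth"]:
                wins += 1
        assert wins >= 4

    def test_unknown_order_rejected(self, grid16):
        v = VelocityField(np.zeros((16, 16, 16, 3)), grid16)
        with pytest.raises(ValueError, match="bch_order"):
            compose_velocity(v, v, "second")


# ---------------------------------------------------------------------------
# exponential (scaling and squaring)


class TestExpField:
    def test_zero_velocity_is_identity(self, grid16):
        v = VelocityField(np.zeros((16, 16, 16, 3)), grid16)
        d = exp_field(v)
        assert np.abs(d.data).max() == 0

    def test_constant_velocity_is_exact_translation(self, grid16):
        t = np.array([0.7, -0.3, 1.1])
        v = VelocityField(np.broadcast_to(t, (16, 16, 16, 3)).copy(), grid16)
        d = exp_field(v)
        interior = d.data[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(interior, np.broadcast_to(t, interior.shape), atol=1e-12)

    def test_rotation_generator_matches_closed_form(self, grid32):
        # v(x) = omega x (x - c) integrates to a rotation by |omega| radians.
        theta = 0.1
        c = np.array([15.5, 15.5, 15.5])
        coords = np.moveaxis(np.mgrid[0:32, 0:32, 0:32].astype(float), 0, -1) - c
        vel = np.cross(np.array([0.0, 0.0, theta]), coords)
        d = exp_field(VelocityField(vel, grid32))
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        exact = np.einsum("ij,xyzj->xyzi", R, coords) - coords
        err = np.abs(d.data - exact)[8:-8, 8:-8, 8:-8].max()
        assert err < 0.1

    def test_matches_euler_ode_integration(self, grid16):
        # Flow of the stationary field with 2^8 Euler steps as oracle.
        rng = np.random.default_rng(7)
        vel = smooth_vector_field(rng, (16, 16, 16), 1.0)
        d = exp_field(VelocityField(vel, grid16))
        n_steps = 256
        pos = np.moveaxis(np.mgrid[0:16, 0:16, 0:16].astype(float), 0, -1)
        start = pos.copy()
        for _ in range(n_steps):
            sampled = np.stack(
                [
                    ndimage.map_coordinates(
                        vel[..., i], np.moveaxis(pos, -1, 0), order=1, mode="nearest"
                    )
                    for i in range(3)
                ],
                axis=-1,
            )
            pos = pos + sampled / n_steps
        oracle = pos - start
        err = np.sqrt(((d.data - oracle) ** 2).sum(-1))[2:-2, 2:-2, 2:-2].max()
        assert err < 0.05

    def test_nonfinite_rejected(self, grid16):
        bad = np.zeros((16, 16, 16, 3))
        bad[0, 0, 0, 0] = np.inf
        v = VelocityField.__new__(VelocityField)  # bypass container validation
        v.data, v.grid = bad, grid16
        with pytest.raises(ValueError, match="finite"):
            exp_field(v)


# ---------------------------------------------------------------------------
# warping


class TestWarp:
    def test_identity_deformation_is_noop(self, grid16):
        img = ImageVolume(np.random.default_rng(0).random((16, 16, 16)), grid16)
        phi = DeformationField(np.zeros((16, 16, 16, 3)), grid16)
        out = warp(img, phi)
        np.testing.assert_array_equal(out.data, img.data)

    def test_one_voxel_shift_is_exact_in_interior(self, grid16):
        img = ImageVolume(np.random.default_rng(1).random((16, 16, 16)), grid16)
        disp = np.zeros((16, 16, 16, 3))
        disp[..., 0] = 1.0
        out = warp(img, DeformationField(disp, grid16))
        np.testing.assert_allclose(out.data[:-1], img.data[1:], atol=1e-12)

    def test_nearest_warp_introduces_no_new_labels(self, grid16):
        rng = np.random.default_rng(2)
        lab = LabelVolume(rng.integers(0, 4, (16, 16, 16)), grid16)
        disp = smooth_vector_field(rng, (16, 16, 16), 2.0)
        out = warp(lab, DeformationField(disp, grid16), "nearest")
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_linear_warp_preserves_intensity_range(self, grid16):
        rng = np.random.default_rng(3)
        img = ImageVolume(rng.random((16, 16, 16)), grid16)
        disp = smooth_vector_field(rng, (16, 16, 16), 3.0)
        out = warp(img, DeformationField(disp, grid16))
        assert out.data.min() >= img.data.min() - 1e-12
        assert out.data.max() <= img.data.max() + 1e-12


# ---------------------------------------------------------------------------
# symmetric registration


class TestRegisterSymmetric:
    def test_self_registration_gives_null_velocity(self, blob_pair):
        fixed, _ = blob_pair
        reg = register_symmetric(fixed, fixed)
        assert np.abs(reg.velocity.data).max() < 1e-6
        assert reg.energy_trace[-1] <= reg.energy_trace[0] + 1e-12

    def test_blob_shift_recovered(self, blob_pair):
        fixed, moving = blob_pair
        reg = register_symmetric(fixed, moving)
        # displacement at the blob centre must point 3 voxels towards the
        # moving blob (pull-back convention: fixed frame samples moving frame)
        assert abs(reg.forward.data[16, 16, 16, 0] - (-3.0)) < 0.5
        warped = warp(moving, reg.forward)
        mse0 = np.mean((fixed.data - moving.data) ** 2)
        mse1 = np.mean((fixed.data - warped.data) ** 2)
        assert mse1 < 0.1 * mse0

    def test_inverse_consistency_of_exponentials(self, blob_pair):
        fixed, moving = blob_pair
        reg = register_symmetric(fixed, moving)
        resid = _compose_disp(reg.inverse.data, reg.forward.data, fixed.grid)
        assert np.sqrt((resid**2).sum(-1)).mean() < 0.1

    def test_argument_swap_negates_velocity(self, blob_pair):
        fixed, moving = blob_pair
        v_fm = register_symmetric(fixed, moving).velocity.data
        v_mf = register_symmetric(moving, fixed).velocity.data
        err = np.sqrt(((v_fm + v_mf) ** 2).sum(-1)).mean()
        assert err < 0.2

    def test_per_level_energy_never_increases(self, blob_pair):
        fixed, moving = blob_pair
        reg = register_symmetric(fixed, moving)
        trace = reg.energy_trace
        assert np.isfinite(trace).all()
        assert trace[-1] <= trace[0]

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RegistrationParams(pyramid_levels=2, iters_per_level=(10,))
        with pytest.raises(ValueError):
            RegistrationParams(force_type="magnetic")


# ---------------------------------------------------------------------------
# affine pre-alignment


@pytest.fixture(scope="module")
def affine_target(grid32):
    # a 12-dof affine is only well conditioned on a structured image, so the
    # target is an ellipsoid shell with asymmetric satellite blobs
    coords = np.mgrid[0:32, 0:32, 0:32].astype(float)
    rng = np.random.default_rng(0)
    r2 = (
        ((coords[0] - 16) / 10) ** 2
        + ((coords[1] - 15) / 8) ** 2
        + ((coords[2] - 16) / 9) ** 2
    )
    img = np.exp(-((np.sqrt(r2) - 0.8) ** 2) / 0.03)
    for cen, s in [
        ((12, 11, 14), 2.0),
        ((20, 19, 13), 1.5),
        ((14, 20, 20), 2.5),
        ((19, 12, 19), 1.8),
        ((16, 16, 16), 2.2),
    ]:
        rr = sum((coords[i] - cen[i]) ** 2 for i in range(3))
        img += (0.5 + 0.5 * rng.random()) * np.exp(-rr / (2 * s * s))
    return ImageVolume(img, grid32)


class TestAffineAlign:
    def test_identity_for_equal_images(self, affine_target):
        T, _ = affine_align(affine_target, affine_target)
        assert np.abs(T - np.eye(4)).max() < 1e-3

    def test_translation_recovered(self, affine_target, grid32):
        moving = ImageVolume(
            ndimage.shift(affine_target.data, (-4, 0, 0), order=1, mode="nearest"),
            grid32,
        )
        T, resampled = affine_align(moving, affine_target)
        # moving(x) = fixed(x + 4), so the aligning translation is -4 mm in x
        assert abs(T[0, 3] - (-4.0)) < 0.5
        assert abs(T[1, 3]) < 0.5 and abs(T[2, 3]) < 0.5
        mse = np.mean((resampled.data - affine_target.data) ** 2)
        assert mse < 0.01 * np.mean(affine_target.data**2)

    def test_scale_recovered(self, affine_target, grid32):
        coords = np.mgrid[0:32, 0:32, 0:32].astype(float)
        c = 15.5
        shrunk = ndimage.map_coordinates(
            affine_target.data,
            [(coords[i] - c) / 0.9 + c for i in range(3)],
            order=1,
            mode="nearest",
        )
        T, _ = affine_align(ImageVolume(shrunk, grid32), affine_target)
        scales = np.linalg.svd(T[:3, :3], compute_uv=False)
        np.testing.assert_allclose(np.sort(scales), 0.9, rtol=0.02)

    def test_skip_passthrough(self, affine_target):
        T, out = affine_align(affine_target, affine_target, skip=True)
        assert np.array_equal(T, np.eye(4))
        assert out is affine_target
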