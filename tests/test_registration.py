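"""Warping, Jacobians, energies and the greedy diffeomorphic registration."""

import numpy as np
import pytest

from cdtmorph import registration as reg
from cdtmorph.gmf import GMField
from cdtmorph.io_formats import ValidationError
from cdtmorph.synthetic import PhantomSpec, make_phantom, make_random_diffeo


class TestJacobian:
    def test_identity(self):
        T = reg.identity_deformation((6, 6, 6))
        J = reg.jacobian_field(T).J
        np.testing.assert_allclose(J, np.broadcast_to(np.eye(3), J.shape))

    def test_linear_displacement(self):
        shape = (8, 8, 8)
        d = np.zeros(shape + (3,))
        d[..., 0] = 0.1 * np.arange(8)[:, None, None]
        J = reg.jacobian_field(reg.DeformationField(disp=d, affine=np.eye(4))).J
        np.testing.assert_allclose(J[4, 4, 4], np.diag([1.1, 1.0, 1.0]), atol=1e-12)

    def test_affine_warp_interior_exact(self, rng):
        shape = (10, 10, 10)
        A = 0.05 * rng.normal(size=(3, 3))
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                    indexing="ij"), axis=-1)
        d = np.einsum("pq,...q->...p", A, grid)
        J = reg.jacobian_field(reg.DeformationField(disp=d, affine=np.eye(4))).J
        interior = J[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(
            interior, np.broadcast_to(np.eye(3) + A, interior.shape), atol=1e-10
        )


class TestSmoothnessPenalty:
    def test_identity_zero(self):
        T = reg.identity_deformation((8, 8, 8))
        assert reg.smoothness_penalty(T, reg.RegistrationConfig(lam=1.0)) == 0.0

    def test_uniform_expansion_value(self):
        # d(x) = (2^{1/3} - 1) x gives det J = 2 at interior voxels
        shape = (12, 12, 12)
        c = 2 ** (1 / 3) - 1
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                    indexing="ij"), axis=-1)
        T = reg.DeformationField(disp=c * grid, affine=np.eye(4))
        detJ = reg.jacobian_field(T).det
        np.testing.assert_allclose(detJ, 2.0, rtol=1e-10)
        pen = reg.smoothness_penalty(T, reg.RegistrationConfig(lam=1.0))
        V = np.prod(shape)
        assert pen == pytest.approx(np.log(2.0) * 1.0 * V, rel=1e-10)

    def test_det_term_asymmetric_under_inversion(self):
        # log(d)(d-1) at d=2 vs d=0.5: both positive but unequal
        f = lambda d: np.log(d) * (d - 1)
        assert f(2.0) > 0 and f(0.5) > 0
        assert f(2.0) != pytest.approx(f(0.5))

    def test_negative_det_infinite(self):
        shape = (8, 8, 8)
        d = np.zeros(shape + (3,))
        d[..., 0] = -2.0 * np.arange(8)[:, None, None]  # folds the grid
        T = reg.DeformationField(disp=d, affine=np.eye(4))
        assert reg.smoothness_penalty(T, reg.RegistrationConfig()) == np.inf


class TestWarp:
    def test_identity_warp_is_noop(self, small_phantom):
        _, _, truth = small_phantom
        out = reg.apply_warp(truth, reg.identity_deformation(truth.shape))
        np.testing.assert_allclose(out.weights_grid, truth.weights_grid, atol=1e-12)
        # identity Jacobian leaves every atom axis unchanged
        np.testing.assert_allclose(
            out.axes_grid,
            np.broadcast_to(truth.dictionary.axes, out.axes_grid.shape),
            atol=1e-12,
        )

    def test_warp_then_inverse_recovers_weights(self, small_phantom):
        _, _, truth = small_phantom
        T = make_random_diffeo(truth.shape, amplitude=1.5, smoothness=4.0, seed=3)
        T_inv = reg.invert_deformation(T)
        once = reg.snap_to_dictionary(reg.apply_warp(truth, T))
        back = reg.snap_to_dictionary(reg.apply_warp(once, T_inv))
        diff = np.abs(back.weights_grid - truth.weights_grid)
        assert diff.mean() < 5e-2

    def test_out_of_domain_is_background(self, small_phantom):
        _, _, truth = small_phantom
        d = np.full(truth.shape + (3,), 100.0)
        out = reg.apply_warp(truth, reg.DeformationField(disp=d, affine=np.eye(4)))
        assert np.all(out.weights_grid == 0)


class TestInversion:
    def test_identity(self):
        T = reg.identity_deformation((8, 8, 8))
        assert np.abs(reg.invert_deformation(T).disp).max() == 0.0

    def test_translation(self):
        shape = (16, 16, 16)
        d = np.zeros(shape + (3,))
        d[..., 1] = 2.0
        T = reg.DeformationField(disp=d, affine=np.eye(4))
        inv = reg.invert_deformation(T)
        core = inv.disp[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(core[..., 1], -2.0, atol=1e-6)

    def test_random_smooth_warp_composition_residual(self):
        T = make_random_diffeo((20, 20, 20), amplitude=1.5, smoothness=4.0, seed=8)
        inv = reg.invert_deformation(T)
        comp = reg.compose_deformations(T, inv)
        assert np.abs(comp.disp[2:-2, 2:-2, 2:-2]).max() < 0.1


class TestDataEnergy:
    def test_self_energy_zero(self, small_phantom):
        _, _, truth = small_phantom
        assert reg.data_energy(truth, truth) == pytest.approx(0.0, abs=1e-10)

    def test_nonnegative(self, small_phantom, rng):
        _, _, truth = small_phantom
        other = GMField(
            weights_grid=np.clip(
                truth.weights_grid + 0.05 * rng.normal(size=truth.weights_grid.shape),
                0, None),
            dictionary=truth.dictionary, affine=truth.affine)
        assert reg.data_energy(other, truth) >= 0

    def test_grid_mismatch_rejected(self, small_phantom):
        _, _, truth = small_phantom
        small = GMField(weights_grid=truth.weights_grid[:10],
                        dictionary=truth.dictionary, affine=truth.affine)
        with pytest.raises(ValidationError):
            reg.data_energy(small, truth)

    def test_global_rotation_warp_conjugates_axes(self, small_phantom):
        """A rotational warp's PPD equals conjugation of every atom axis."""
        from scipy.spatial.transform import Rotation

        _, _, truth = small_phantom
        R = Rotation.from_rotvec([0, 0, 0.2]).as_matrix()
        shape = truth.shape
        c = (np.array(shape) - 1) / 2
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                    indexing="ij"), axis=-1)
        disp = np.einsum("pq,...q->...p", R, grid - c) + c - grid
        T = reg.DeformationField(disp=disp, affine=np.eye(4))
        out = reg.apply_warp(truth, T)
        expected = (R @ truth.dictionary.axes.T).T
        core = out.axes_grid[8:-8, 8:-8, 4:-4]
        dots = np.abs(np.einsum("...kp,kp->...k", core, expected))
        assert dots.min() > 1 - 1e-6


class TestNonrigidRegistration:
    def test_identical_images_no_force(self, small_phantom):
        _, _, truth = small_phantom
        T, info = reg.nonrigid_register(
            truth, truth, reg.RegistrationConfig(n_iter=10, n_levels=2))
        assert np.abs(T.disp).max() < 0.1
        assert info["min_detj"] > 0

    def test_energy_trace_monotone(self, small_phantom):
        _, _, truth = small_phantom
        T_true = make_random_diffeo(truth.shape, amplitude=1.5, smoothness=4.0, seed=4)
        fixed = reg.snap_to_dictionary(reg.apply_warp(truth, T_true))
        _, info = reg.nonrigid_register(
            truth, fixed, reg.RegistrationConfig(n_iter=15, n_levels=2))
        for trace in info["level_traces"]:
            diffs = np.diff(trace)
            assert np.all(diffs <= 1e-9)

    def test_warp_recovery_and_diffeomorphism(self, small_phantom):
        _, _, truth = small_phantom
        T_true = make_random_diffeo(truth.shape, amplitude=2.0, smoothness=4.0, seed=4)
        fixed = reg.snap_to_dictionary(reg.apply_warp(truth, T_true))
        T_est, info = reg.nonrigid_register(
            truth, fixed, reg.RegistrationConfig(n_iter=40, n_levels=2))
        assert info["min_detj"] > 0
        err = np.linalg.norm(T_est.disp - T_true.disp, axis=-1)
        assert err[truth.mask].mean() < 0.5

    def test_noise_does_not_hallucinate_deformation(self):
        """Registering two noisy copies of the same anatomy stays near identity."""
        from cdtmorph.gmf import estimate_gmf
        from cdtmorph.synthetic import synthesize_dwi

        spec = PhantomSpec(shape=(24, 24, 16), snr=20.0, seed=6, n_orient=12)
        _, truth = make_phantom(spec)
        gt = spec.gradient_table()
        dwi1 = synthesize_dwi(truth, gt, snr=20.0, rng=np.random.default_rng(1))
        dwi2 = synthesize_dwi(truth, gt, snr=20.0, rng=np.random.default_rng(2))
        f1 = estimate_gmf(dwi1, truth.dictionary)
        f2 = estimate_gmf(dwi2, truth.dictionary)
        T, info = reg.nonrigid_register(
            f1, f2, reg.RegistrationConfig(n_iter=20, n_levels=2))
        assert np.linalg.norm(T.disp, axis=-1)[truth.mask].mean() < 2.0


class TestSimilarity:
    def test_identity_on_equal_images(self, small_phantom):
        _, dwi, truth = small_phantom
        s0 = dwi.data[..., 0]
        tf = reg.similarity_register(s0, s0)
        assert np.abs(tf.translation).max() < 0.3
        assert tf.scale == pytest.approx(1.0, abs=0.03)

    def test_translation_recovery(self, small_phantom):
        _, dwi, _ = small_phantom
        s0 = dwi.data[..., 0]
        moved = np.roll(s0, 3, axis=0)  # fixed = moving shifted +3 in x
        tf = reg.similarity_register(s0, moved)
        assert tf.translation[0] == pytest.approx(-3.0, abs=0.5)

    def test_scale_recovery(self, small_phantom):
        from scipy import ndimage

        _, dwi, _ = small_phantom
        s0 = dwi.data[..., 0]
        c = (np.array(s0.shape) - 1) / 2
        grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in s0.shape],
                                    indexing="ij"), axis=-1)
        coords = c + (grid - c) / 1.1  # fixed = moving scaled 1.1x about center
        scaled = ndimage.map_coordinates(s0, coords.reshape(-1, 3).T, order=1) \
            .reshape(s0.shape)
        tf = reg.similarity_register(s0, scaled)
        assert 1.05 <= tf.magnification <= 1.15
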