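"""Gaussian-mixture EAP machinery: forward model, fitting, distance, PPD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdtmorph import gmf
from cdtmorph.io_formats import GradientTable, DWIVolume, ValidationError
from cdtmorph.synthetic import default_gradient_table


def _single_atom_dict(**kw):
    return gmf.build_dictionary(orientations=[(1.0, 0.0, 0.0)],
                                include_isotropic=False, **kw)


class TestDictionary:
    def test_single_orientation_tensor(self):
        d = _single_atom_dict()
        D = d.tensors[0]
        np.testing.assert_allclose(D, np.diag([1.7e-3, 3e-4, 3e-4]), atol=1e-12)

    def test_equal_eigenvalues_isotropic(self):
        d = gmf.build_dictionary(n_orient=5, lambda_par=1e-3, lambda_perp=1e-3,
                                 include_isotropic=False)
        for D in d.tensors:
            np.testing.assert_allclose(D, 1e-3 * np.eye(3), atol=1e-15)

    def test_atom_count_with_isotropic(self):
        d = gmf.build_dictionary(n_orient=321)
        assert d.n_atoms == 322

    def test_degenerate_eigenvalues_rejected(self):
        with pytest.raises(ValidationError):
            gmf.build_dictionary(n_orient=3, lambda_par=1e-3, lambda_perp=0.0)

    def test_orientations_antipodally_distinct(self):
        u = gmf.hemisphere_orientations(46)
        dots = u @ u.T
        off = dots[~np.eye(46, dtype=bool)]
        assert off.max() < 1 - 1e-6  # no duplicates
        assert off.min() > -1 + 1e-6  # no antipodal pairs

    def test_json_roundtrip(self):
        d = gmf.build_dictionary(n_orient=7)
        back = gmf.DiffusionDictionary.from_json(d.to_json())
        np.testing.assert_allclose(back.axes, d.axes)
        np.testing.assert_allclose(back.a1, d.a1)
        assert back.tau == d.tau


class TestForwardModel:
    def test_attenuation_along_and_across_fiber(self):
        d = _single_atom_dict()
        gt = GradientTable([0, 1000, 1000],
                           [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        E = gmf.predict_attenuation(d, [1.0], gt)
        assert E[0] == pytest.approx(1.0)
        assert E[1] == pytest.approx(np.exp(-1.7), rel=1e-12)
        assert E[2] == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_b0_is_one_for_any_weights(self, default_dictionary, rng):
        gt = GradientTable([0.0], [[0, 0, 0]])
        w = rng.random(default_dictionary.n_atoms)
        assert gmf.predict_attenuation(default_dictionary, w, gt)[0] == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self, default_dictionary):
        gt = GradientTable([0.0], [[0, 0, 0]])
        with pytest.raises(ValidationError):
            gmf.predict_attenuation(default_dictionary, np.zeros(default_dictionary.n_atoms), gt)


class TestEstimation:
    def _dwi_from_weights(self, dictionary, weights, gt, scale=1.0):
        E = gmf.design_matrix(dictionary, gt) @ (weights / weights.sum())
        data = (scale * E).reshape(1, 1, 1, -1)
        return DWIVolume(data=data, affine=np.eye(4), gradients=gt)

    def test_single_atom_recovery(self, default_dictionary):
        gt = default_gradient_table()
        w = np.zeros(default_dictionary.n_atoms)
        w[5] = 1.0
        dwi = self._dwi_from_weights(default_dictionary, w, gt, scale=100.0)
        est = gmf.estimate_gmf(dwi, default_dictionary,
                               mask=np.ones((1, 1, 1), bool), ridge=0.0)
        assert est.weights_grid[0, 0, 0, 5] >= 0.99

    def test_crossing_recovery(self, default_dictionary):
        gt = default_gradient_table()
        ax = default_dictionary.axes
        kx = np.argmax(np.abs(ax @ [1, 0, 0]))
        ky = np.argmax(np.abs(ax @ [0, 1, 0]))
        w = np.zeros(default_dictionary.n_atoms)
        w[kx] = w[ky] = 0.5
        dwi = self._dwi_from_weights(default_dictionary, w, gt)
        est = gmf.estimate_gmf(dwi, default_dictionary,
                               mask=np.ones((1, 1, 1), bool), ridge=0.0)
        got = est.weights_grid[0, 0, 0]
        assert 0.4 <= got[kx] <= 0.6
        assert 0.4 <= got[ky] <= 0.6

    def test_isotropic_recovery(self, default_dictionary):
        gt = default_gradient_table()
        iso = int(np.flatnonzero(default_dictionary.a1 == 0)[0])
        w = np.zeros(default_dictionary.n_atoms)
        w[iso] = 1.0
        dwi = self._dwi_from_weights(default_dictionary, w, gt)
        est = gmf.estimate_gmf(dwi, default_dictionary,
                               mask=np.ones((1, 1, 1), bool), ridge=0.0)
        assert np.argmax(est.weights_grid[0, 0, 0]) == iso

    def test_scale_equivariance(self, default_dictionary, rng):
        gt = default_gradient_table()
        w = rng.random(default_dictionary.n_atoms)
        d1 = self._dwi_from_weights(default_dictionary, w, gt, scale=50.0)
        d2 = self._dwi_from_weights(default_dictionary, w, gt, scale=500.0)
        mask = np.ones((1, 1, 1), bool)
        e1 = gmf.estimate_gmf(d1, default_dictionary, mask=mask)
        e2 = gmf.estimate_gmf(d2, default_dictionary, mask=mask)
        np.testing.assert_allclose(e1.weights_grid, e2.weights_grid, atol=1e-10)


class TestEAPDensity:
    def test_value_at_origin_single_gaussian(self):
        d = _single_atom_dict()
        C = d.covariances[0]
        gm = gmf.GaussianMixture(weights=np.array([1.0]))
        expected = (2 * np.pi) ** (-1.5) * np.linalg.det(C) ** (-0.5)
        assert gmf.eap_value(gm, d, [0, 0, 0]) == pytest.approx(expected, rel=1e-12)

    def test_mixture_linearity(self, rng):
        d = gmf.build_dictionary(n_orient=4)
        w = rng.random(d.n_atoms)
        r = rng.normal(size=3) * 1e-3
        total = gmf.eap_value(gmf.GaussianMixture(weights=w), d, r)
        parts = []
        for k in range(d.n_atoms):
            ek = np.zeros(d.n_atoms)
            ek[k] = 1.0
            parts.append(gmf.eap_value(gmf.GaussianMixture(weights=ek), d, r))
        assert total == pytest.approx(np.dot(w / w.sum(), parts), rel=1e-10)

    def test_density_integrates_to_one(self, rng):
        # order-1 covariances so a [-8, 8]^3 box captures the mass
        covs = np.stack([np.eye(3), 2 * np.eye(3), 0.5 * np.eye(3)])
        gm = gmf.GaussianMixture(weights=np.array([0.5, 0.3, 0.2]),
                                 covariances=covs)
        d = _single_atom_dict()
        x = np.linspace(-8, 8, 61)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        h = x[1] - x[0]
        integral = gmf.eap_value(gm, d, pts).sum() * h**3
        assert integral == pytest.approx(1.0, abs=1e-3)


def _random_order1_mixture(rng, n_comp=3):
    covs = []
    for _ in range(n_comp):
        A = rng.normal(size=(3, 3))
        covs.append(A @ A.T + 0.5 * np.eye(3))
    w = rng.random(n_comp) + 0.1
    return gmf.GaussianMixture(weights=w, covariances=np.stack(covs))


class TestL2Distance:
    def test_identical_mixtures_zero(self, rng):
        d = _single_atom_dict()
        gm = _random_order1_mixture(rng)
        assert gmf.gm_l2_distance(gm, gm, d) == pytest.approx(0.0, abs=1e-12)

    def test_two_isotropic_gaussians_closed_form(self):
        d = _single_atom_dict()
        g1 = gmf.GaussianMixture(np.array([1.0]), covariances=np.eye(3)[None])
        g2 = gmf.GaussianMixture(np.array([1.0]), covariances=4 * np.eye(3)[None])
        expected = (2 * np.pi) ** (-1.5) * (8**-0.5 + 512**-0.5 - 2 * 125**-0.5)
        assert gmf.gm_l2_distance_sq(g1, g2, d) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self, rng):
        d = _single_atom_dict()
        g1, g2 = _random_order1_mixture(rng), _random_order1_mixture(rng)
        assert gmf.gm_l2_distance(g1, g2, d) == pytest.approx(
            gmf.gm_l2_distance(g2, g1, d), rel=1e-12
        )

    @pytest.mark.parametrize("pair_seed", range(5))
    def test_closed_form_matches_quadrature(self, pair_seed):
        """Closed form vs brute-force 3D quadrature on a 61^3 grid."""
        rng = np.random.default_rng(1000 + pair_seed)
        d = _single_atom_dict()
        g1, g2 = _random_order1_mixture(rng), _random_order1_mixture(rng)
        closed = gmf.gm_l2_distance_sq(g1, g2, d)
        x = np.linspace(-9, 9, 61)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        h = x[1] - x[0]
        p = gmf.eap_value(g1, d, pts)
        q = gmf.eap_value(g2, d, pts)
        quad = ((p - q) ** 2).sum() * h**3
        assert closed == pytest.approx(quad, rel=1e-2)


class TestPPD:
    def test_identity_leaves_mixture_unchanged(self, small_dictionary, rng):
        w = rng.random(small_dictionary.n_atoms)
        out = gmf.reorient_ppd(gmf.GaussianMixture(weights=w),
                               small_dictionary, np.eye(3))
        np.testing.assert_allclose(out.covariances,
                                   small_dictionary.covariances, atol=1e-12)

    def test_rotation_conjugates_covariances(self, small_dictionary, rng):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        w = rng.random(small_dictionary.n_atoms)
        out = gmf.reorient_ppd(gmf.GaussianMixture(weights=w),
                               small_dictionary, R)
        C = small_dictionary.covariances
        np.testing.assert_allclose(out.covariances, R @ C @ R.T, atol=1e-12)

    def test_eigenvalues_preserved_for_general_jacobian(self, small_dictionary, rng):
        J = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        assert np.linalg.det(J) > 0
        out = gmf.reorient_ppd(gmf.GaussianMixture(
            weights=np.ones(small_dictionary.n_atoms)), small_dictionary, J)
        ev0 = np.sort(np.linalg.eigvalsh(small_dictionary.covariances), axis=1)
        ev1 = np.sort(np.linalg.eigvalsh(out.covariances), axis=1)
        np.testing.assert_allclose(ev0, ev1, atol=1e-12)

    def test_rotations_form_group(self, small_dictionary, rng):
        """PPD by R then by R^{-1} restores the original covariances."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        gm = gmf.GaussianMixture(weights=np.ones(small_dictionary.n_atoms))
        fwd = gmf.reorient_ppd(gm, small_dictionary, R)
        back = gmf.reorient_ppd(fwd, small_dictionary, R.T)
        np.testing.assert_allclose(back.covariances,
                                   small_dictionary.covariances, atol=1e-10)

    def test_singular_jacobian_rejected(self, small_dictionary):
        with pytest.raises(ValidationError):
            gmf.reorient_ppd(gmf.GaussianMixture(
                weights=np.ones(small_dictionary.n_atoms)),
                small_dictionary, np.diag([1.0, 1.0, 0.0]))

    def test_axisymmetric_fast_path_matches_generic(self, small_dictionary, rng):
        J = np.eye(3) + 0.25 * rng.normal(size=(3, 3))
        assert np.linalg.det(J) > 0
        generic = gmf.reorient_ppd(gmf.GaussianMixture(
            weights=np.ones(small_dictionary.n_atoms)), small_dictionary, J)
        ax = gmf.ppd_rotate_axes(small_dictionary.axes, J)
        d = small_dictionary
        fast = d.a1[:, None, None] * (ax[:, :, None] * ax[:, None, :]) \
            + d.a2[:, None, None] * np.eye(3)
        np.testing.assert_allclose(fast, generic.covariances, atol=1e-14)


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_distance_nonnegative_and_symmetric_property(seed):
    rng = np.random.default_rng(seed)
    d = _single_atom_dict()
    g1, g2 = _random_order1_mixture(rng), _random_order1_mixture(rng)
    d12 = gmf.gm_l2_distance(g1, g2, d)
    d21 = gmf.gm_l2_distance(g2, g1, d)
    assert d12 >= 0
    assert d12 == pytest.approx(d21, rel=1e-10)
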