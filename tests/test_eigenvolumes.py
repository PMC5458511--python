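import numpy as np
import pytest
from scipy.stats import spearmanr

from volscape.align import AlignedEnsemble, RigidTransform
from volscape.eigenvolumes import VolumePCA, explained_variance, fit_pca, project
from volscape.synthetic import render_phantom
from volscape.volume_io import BinaryMask, DegenerateInputError, VoxelGrid


def _ensemble_from_stack(stack, voxel=4.0, counts=None):
    vols = [VoxelGrid(v, voxel) for v in stack]
    n = len(vols)
    counts = np.full(n, 10) if counts is None else counts
    return AlignedEnsemble(vols, [RigidTransform() for _ in vols], counts, np.ones(n))


def _full_mask(shape, voxel=4.0):
    return BinaryMask(np.ones(shape, dtype=bool), voxel)


def _apply_sign_convention(components):
    out = components.copy()
    for k in range(out.shape[0]):
        j = np.argmax(np.abs(out[k]))
        if out[k, j] < 0:
            out[k] *= -1
    return out


class TestGramTrickEquivalence:
    def test_matches_direct_svd(self, rng):
        """Gram-matrix PCA must agree with an SVD of the centered data matrix."""
        n, box = 8, 16
        X = rng.normal(size=(n, box**3))
        est = VolumePCA(n_components=n - 1).fit(X)
        xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        comps_svd = _apply_sign_convention(vt[: n - 1])
        coeff_svd = xc @ comps_svd.T
        np.testing.assert_allclose(est.components_, comps_svd, atol=1e-8)
        np.testing.assert_allclose(est.coefficients_, coeff_svd, atol=1e-8)
        np.testing.assert_allclose(est.eigenvalues_, (s**2)[: n - 1], rtol=1e-10)

    def test_orthonormal_components(self, rng):
        X = rng.normal(size=(6, 1000))
        est = VolumePCA(n_components=5).fit(X)
        gram = est.components_ @ est.components_.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-6)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(6, 500))
        est = VolumePCA(n_components=5).fit(X)
        rec = est.inverse_transform(est.coefficients_)
        rms = np.sqrt(np.mean((rec - X) ** 2))
        assert rms < 1e-5


class TestProjection:
    @pytest.fixture()
    def fitted(self, rng):
        stack = rng.normal(size=(6, 12, 12, 12))
        ens = _ensemble_from_stack(stack)
        return ens, fit_pca(ens, _full_mask((12, 12, 12)), 3)

    def test_mean_projects_to_zero(self, fitted):
        # mean volume round-trips through float32 map storage
        _, decomp = fitted
        np.testing.assert_allclose(project(decomp.mean_volume, decomp), 0.0, atol=1e-5)

    def test_training_volume_projection_consistent(self, fitted):
        ens, decomp = fitted
        got = project(ens.volumes[2], decomp)
        np.testing.assert_allclose(got, decomp.coefficients[2], atol=1e-4)

    def test_constructed_coefficient_recovered(self, fitted):
        _, decomp = fitted
        synth = decomp.mean_volume.with_data(
            decomp.mean_volume.data + 2.0 * decomp.eigenvolumes[0].data
        )
        got = project(synth, decomp)
        np.testing.assert_allclose(got, [2.0, 0.0, 0.0], atol=1e-4)

    def test_grid_mismatch_rejected(self, fitted):
        _, decomp = fitted
        with pytest.raises(ValueError):
            project(VoxelGrid(np.zeros((10, 10, 10)), 4.0), decomp)


class TestEdgeCases:
    def test_two_volume_pca_antisymmetric_coefficients(self, rng):
        X = rng.normal(size=(2, 200))
        est = VolumePCA(n_components=1).fit(X)
        c = est.coefficients_[:, 0]
        assert c[0] == pytest.approx(-c[1], rel=1e-10)

    def test_identical_volumes_degenerate(self):
        X = np.tile(np.arange(100.0), (4, 1))
        with pytest.raises(DegenerateInputError):
            VolumePCA(n_components=2).fit(X)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            VolumePCA(n_components=5).fit(rng.normal(size=(4, 50)))

    def test_coefficients_invariant_to_global_offset(self, rng):
        X = rng.normal(size=(5, 300))
        a = VolumePCA(n_components=2).fit(X)
        b = VolumePCA(n_components=2).fit(X + 17.0)
        np.testing.assert_allclose(a.coefficients_, b.coefficients_, atol=1e-8)


@pytest.fixture(scope="module")
def sweep(spec32):
    thetas = np.linspace(-25, 25, 9)
    stack = np.stack([render_phantom(spec32, t).data for t in thetas])
    ens = _ensemble_from_stack(stack, voxel=spec32.voxel_size)
    mask = _full_mask(stack.shape[1:], spec32.voxel_size)
    return thetas, ens, fit_pca(ens, mask, 3)


class TestPhantomEnsemble:
    def test_first_coefficient_monotone_in_angle(self, sweep):
        thetas, _, decomp = sweep
        rho = spearmanr(thetas, decomp.coefficients[:, 0]).statistic
        assert abs(rho) == pytest.approx(1.0, abs=1e-12)

    def test_single_mode_dominates(self, spec32):
        # moderate sweep: the rotation manifold's curvature stays small and a
        # single eigenvolume carries nearly all the variance
        thetas = np.linspace(-15, 15, 9)
        stack = np.stack([render_phantom(spec32, t).data for t in thetas])
        ens = _ensemble_from_stack(stack, voxel=spec32.voxel_size)
        decomp = fit_pca(ens, _full_mask(stack.shape[1:], spec32.voxel_size), 3)
        frac = explained_variance(decomp)
        assert frac[0] > 0.95
        assert np.all(np.diff(frac) <= 1e-12)

    def test_first_eigenvolume_localised_in_rp(self, sweep, masks32):
        _, _, decomp = sweep
        _, rp = masks32
        ev = decomp.eigenvolumes[0].data
        inside = np.sum(ev[rp.data] ** 2)
        assert inside / np.sum(ev**2) > 0.8

    def test_white_noise_spectrum_roughly_flat(self, rng):
        stack = rng.normal(size=(10, 12, 12, 12))
        ens = _ensemble_from_stack(stack)
        decomp = fit_pca(ens, _full_mask((12, 12, 12)), 9)
        frac = explained_variance(decomp)
        assert frac.max() / frac.min() < 3.0

    def test_full_rank_fractions_sum_to_one(self, rng):
        stack = rng.normal(size=(6, 12, 12, 12))
        ens = _ensemble_from_stack(stack)
        decomp = fit_pca(ens, _full_mask((12, 12, 12)), 5)
        assert explained_variance(decomp).sum() == pytest.approx(1.0, abs=1e-9)
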