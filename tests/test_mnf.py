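"""MNF core: eigenproblem, SNR ordering, retention, denoising matrix, batch."""

import numpy as np
import pytest
import scipy.linalg

from mnfstream.config import DenoiseConfig, RetentionPolicy
from mnfstream.mnf import (
    EigensolveError,
    apply_denoise,
    band_snr,
    choose_r,
    component_table,
    denoise_batch,
    denoising_matrix,
    forward_transform,
    signal_fraction,
    solve_mnf,
)
from mnfstream.synthetic import sam_profile


@pytest.fixture(scope="module")
def medium_scene():
    """A 60 x 48 x 80 block scene at sigma^2 = 1e-4 (full band count, small
    spatial extent) for efficacy checks that depend on the band budget."""
    from mnfstream.synthetic import SyntheticSpec, add_noise, make_block_image

    spec = SyntheticSpec(lines=60, samples=48, bands=80, noise_variance=1e-4, seed=11)
    clean = make_block_image(spec)
    return clean, add_noise(clean, spec.noise_variance, seed=12)


def random_spd(rng, b, scale=1.0):
    Q = rng.normal(size=(b, b))
    return scale * (Q @ Q.T / b + np.eye(b) * 0.1)


def generalized_residual(model):
    """max_j ||Sigma_N a_j - lambda_j Sigma a_j|| / ||Sigma_N||"""
    A, lam = model.transform, model.eigenvalues
    res = model.sigma_noise @ A - model.sigma @ A * lam[None, :]
    return np.linalg.norm(res, axis=0).max() / np.linalg.norm(model.sigma_noise)


class TestSolve:
    def test_diagonal_2x2_oracle(self):
        """Sigma=diag(4,1), Sigma_N=I: lambda=(1/4, 1), SNR=(3, 0), high-variance
        band ordered first."""
        m = solve_mnf(np.diag([4.0, 1.0]), np.eye(2), np.zeros(2))
        np.testing.assert_allclose(m.eigenvalues, [0.25, 1.0], atol=1e-12)
        np.testing.assert_allclose(band_snr(m), [3.0, 0.0], atol=1e-12)
        # first eigenvector points along the variance-4 band
        v = m.transform[:, 0] / np.linalg.norm(m.transform[:, 0])
        np.testing.assert_allclose(np.abs(v), [1.0, 0.0], atol=1e-12)

    def test_identity_pencil_degenerate_case(self):
        m = solve_mnf(np.eye(3), np.eye(3), np.zeros(3))
        np.testing.assert_allclose(m.eigenvalues, 1.0, atol=1e-12)
        np.testing.assert_allclose(band_snr(m), 0.0, atol=1e-10)
        assert generalized_residual(m) < 1e-8

    def test_residual_and_snr_identity_on_random_pencils(self, rng):
        """Residual bound and SNR_j = Rayleigh-quotient ratio - 1 = 1/lambda - 1."""
        for _ in range(25):
            b = int(rng.integers(2, 41))
            sigma = random_spd(rng, b)
            sigma_n = random_spd(rng, b, scale=0.1)
            m = solve_mnf(sigma, sigma_n, np.zeros(b))
            assert generalized_residual(m) <= 1e-8
            A = m.transform
            rayleigh = np.einsum("ij,ij->j", A, sigma @ A) / np.einsum(
                "ij,ij->j", A, sigma_n @ A
            )
            np.testing.assert_allclose(band_snr(m), rayleigh - 1.0, atol=1e-8)
            snr = band_snr(m)
            assert np.all(np.diff(snr) <= 1e-8 * np.maximum(np.abs(snr[:-1]), 1.0))

    def test_agrees_with_qz_oracle(self, rng):
        """Cross-check eigenvalues against the independent QZ (nonsymmetric) solver."""
        sigma = random_spd(rng, 12)
        sigma_n = random_spd(rng, 12, scale=0.3)
        m = solve_mnf(sigma, sigma_n, np.zeros(12))
        w = scipy.linalg.eig(sigma_n, sigma, right=False)
        np.testing.assert_allclose(np.sort(w.real), m.eigenvalues, rtol=1e-8)

    def test_noise_scaling_doubles_eigenvalues_keeps_D(self, rng):
        sigma = random_spd(rng, 8)
        sigma_n = random_spd(rng, 8, scale=0.2)
        m1 = solve_mnf(sigma, sigma_n, np.zeros(8))
        m2 = solve_mnf(sigma, 2.0 * sigma_n, np.zeros(8))
        np.testing.assert_allclose(m2.eigenvalues, 2.0 * m1.eigenvalues, rtol=1e-9)
        for r in range(1, 9):
            d1 = denoising_matrix(m1, r).matrix
            d2 = denoising_matrix(m2, r).matrix
            np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_nonsymmetric_input_rejected(self, rng):
        M = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            solve_mnf(M, np.eye(4), np.zeros(4))

    def test_singular_sigma_triggers_regularization(self):
        sigma = np.zeros((3, 3))
        sigma[0, 0] = 1.0  # rank 1
        m = solve_mnf(sigma, np.eye(3) * 1e-4, np.zeros(3), reg_eps=1e-8)
        assert m.regularized


class TestSignalFraction:
    def test_all_signal_in_first_component(self):
        m = solve_mnf(np.diag([4.0, 1.0]), np.eye(2), np.zeros(2))  # snr (3, 0)
        assert signal_fraction(m, 1) == pytest.approx(1.0)

    def test_partial_fraction(self):
        # snr (3, 1): lambda (1/4, 1/2)
        m = solve_mnf(np.diag([4.0, 2.0]), np.eye(2), np.zeros(2))
        np.testing.assert_allclose(band_snr(m), [3.0, 1.0], atol=1e-12)
        assert signal_fraction(m, 1) == pytest.approx(0.75)

    def test_full_retention_is_one_and_monotone(self, rng):
        sigma = random_spd(rng, 6)
        m = solve_mnf(sigma, 0.05 * np.eye(6), np.zeros(6))
        fr = [signal_fraction(m, r) for r in range(1, 7)]
        assert fr[-1] == pytest.approx(1.0)
        assert np.all(np.diff(fr) >= -1e-12)

    def test_no_signal_raises(self):
        m = solve_mnf(np.eye(2), np.eye(2), np.zeros(2))  # snr all 0
        with pytest.raises(ValueError, match="undefined"):
            signal_fraction(m, 1)


class FakeModelFactory:
    """Models with prescribed SNRs via lambda = 1/(snr+1) on identity Sigma."""

    @staticmethod
    def from_snr(snrs):
        lam = 1.0 / (np.asarray(snrs, dtype=float) + 1.0)
        b = lam.size
        return solve_mnf(np.diag(1.0 / lam), np.eye(b), np.zeros(b))


class TestChooseR:
    def test_min_snr_threshold(self):
        m = FakeModelFactory.from_snr([3.0, 1.0, 0.0, 0.0])
        assert choose_r(m, RetentionPolicy.min_snr(0.5)) == 2

    def test_min_fraction_threshold(self):
        m = FakeModelFactory.from_snr([3.0, 1.0, 0.0, 0.0])
        # f(1) = 0.75 < 0.9, f(2) = 1.0
        assert choose_r(m, RetentionPolicy.min_fraction(0.9)) == 2

    def test_fixed_echoes(self):
        m = FakeModelFactory.from_snr([3.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.0, 0.0])
        assert choose_r(m, RetentionPolicy.fixed(6)) == 6

    def test_fixed_out_of_range(self):
        m = FakeModelFactory.from_snr([1.0, 0.0])
        with pytest.raises(ValueError):
            choose_r(m, RetentionPolicy.fixed(3))

    def test_gap_finds_signal_noise_split(self):
        # eigenvalues 0.01, 0.02, 0.9, 0.95: biggest jump after index 1
        lam = np.array([0.01, 0.02, 0.9, 0.95])
        m = solve_mnf(np.diag(1.0 / lam), np.eye(4), np.zeros(4))
        assert choose_r(m, RetentionPolicy.gap()) == 2

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            RetentionPolicy("fixed", 0)
        with pytest.raises(ValueError):
            RetentionPolicy("min_snr", -1.0)
        with pytest.raises(ValueError):
            RetentionPolicy("nope")


class TestDenoisingMatrix:
    def test_full_retention_is_identity(self, rng):
        m = solve_mnf(random_spd(rng, 10), random_spd(rng, 10, 0.1), np.zeros(10))
        D = denoising_matrix(m, 10).matrix
        np.testing.assert_allclose(D, np.eye(10), atol=1e-10)

    def test_axis_aligned_projection(self):
        m = solve_mnf(np.diag([4.0, 1.0]), np.eye(2), np.zeros(2))
        D = denoising_matrix(m, 1).matrix
        np.testing.assert_allclose(D, np.diag([1.0, 0.0]), atol=1e-12)

    def test_idempotent_on_random_pencils(self, rng):
        for _ in range(10):
            b = int(rng.integers(2, 21))
            m = solve_mnf(random_spd(rng, b), random_spd(rng, b, 0.2), np.zeros(b))
            r = int(rng.integers(1, b + 1))
            D = denoising_matrix(m, r).matrix
            np.testing.assert_allclose(D @ D, D, atol=1e-8)

    def test_invariant_to_eigenvector_rescaling(self, rng):
        m = solve_mnf(random_spd(rng, 6), random_spd(rng, 6, 0.2), np.zeros(6))
        D = denoising_matrix(m, 3).matrix
        scales = rng.uniform(0.2, 5.0, size=6) * rng.choice([-1.0, 1.0], size=6)
        m.transform = m.transform * scales[None, :]
        D2 = denoising_matrix(m, 3).matrix
        np.testing.assert_allclose(D, D2, atol=1e-8)


class TestDenoiseBatch:
    def test_full_retention_returns_input(self, small_noisy):
        res = denoise_batch(
            small_noisy, DenoiseConfig(policy=RetentionPolicy.fixed(small_noisy.shape[2]))
        )
        np.testing.assert_allclose(res.cube, small_noisy, atol=1e-10)

    def test_rank_one_cube_recovered_exactly(self, rng):
        """All pixels proportional to one spectrum: r=1 keeps everything."""
        spectrum = 0.5 + 0.3 * np.sin(np.linspace(0, 3, 12))
        scales = 1.0 + 0.2 * rng.normal(size=(20, 15))
        cube = scales[:, :, None] * spectrum[None, None, :]
        res = denoise_batch(cube, DenoiseConfig(policy=RetentionPolicy.fixed(1)))
        np.testing.assert_allclose(res.cube, cube, atol=1e-8)

    def test_denoising_improves_sam(self, medium_scene):
        """Batch MNF at the gap-chosen r beats the noise floor by > 5x."""
        clean, noisy = medium_scene
        res = denoise_batch(noisy, DenoiseConfig())
        sam_noisy = sam_profile(noisy, clean).mean
        sam_den = sam_profile(res.cube, clean).mean
        assert sam_den < sam_noisy / 5

    def test_forward_transform_concentrates_noise_in_late_components(
        self, medium_scene
    ):
        """Projecting the pure noise field onto the MNF basis gives component
        noise variances ~ lambda_j: ascending, so the leading (high-SNR)
        components carry the least noise."""
        clean, noisy = medium_scene
        res = denoise_batch(noisy, DenoiseConfig())
        B = noisy.shape[2]
        noise_field = (noisy - clean).reshape(-1, B).T
        T = res.model.transform.T @ noise_field
        var = T.var(axis=1)
        lam = res.model.eigenvalues
        signal = lam < 0.5
        assert var[signal].max() < var[~signal].min()

    def test_zero_meaned_output_flag(self, small_noisy):
        cfg = DenoiseConfig(policy=RetentionPolicy.fixed(3), emit_zero_meaned=True)
        res = denoise_batch(small_noisy, cfg)
        assert np.abs(res.cube.mean(axis=(0, 1))).max() < 1e-8

    def test_constant_image_raises(self):
        cube = np.full((5, 6, 3), 0.7)
        with pytest.raises((EigensolveError, ValueError)):
            denoise_batch(cube, DenoiseConfig(policy=RetentionPolicy.fixed(1)))


def test_component_table_structure(small_noisy):
    res = denoise_batch(small_noisy, DenoiseConfig())
    df = component_table(res.model, res.r)
    assert list(df.columns) == [
        "component", "eigenvalue", "snr", "cumulative_fraction", "retained",
    ]
    assert df["retained"].sum() == res.r
    assert df["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)
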