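"""Subspace estimator algebra: autocorrelation, eigendecomposition, model
order, least-norm vector, pseudo-spectrum, and the sliding track."""

import numpy as np
import pytest

from period3.sequences import ComplexSignal, NucleotideSequence, map_sequence
from period3.subspace import (
    PSEUDO_SPECTRUM_CAP,
    EigenSystem,
    ExponentialsInNoiseModel,
    autocorrelation_matrix,
    eigendecompose,
    exact_autocorrelation,
    least_norm_vector,
    period3_track_least_norm,
    pseudo_spectrum,
    pseudo_spectrum_value,
    select_model_order,
)


def sig(x):
    return ComplexSignal(np.asarray(x, complex), "simulated")


def random_exact_eigensystem(rng, M, p, noise_var=0.5):
    """EigenSystem of an exact p-line autocorrelation matrix with well
    separated frequencies."""
    while True:
        w = np.sort(rng.uniform(0, 2 * np.pi, p))
        if p == 1 or np.min(np.diff(np.concatenate([w, [w[0] + 2 * np.pi]]))) > 0.5:
            break
    model = ExponentialsInNoiseModel(
        frequencies=tuple(w),
        amplitudes=tuple(rng.uniform(0.5, 2.0, p)),
        noise_variance=noise_var,
    )
    return eigendecompose(exact_autocorrelation(model, M)), model


def min_norm_oracle(Vn):
    """Independent solve of min ||a|| s.t. a = Vn c, a[0] = 1: the
    minimum-norm solution of the 1 x (M-p) system Vn[0,:] c = 1 via LAPACK
    least squares (||a|| = ||c|| because Vn has orthonormal columns)."""
    g = Vn[0, :].reshape(1, -1)
    c, *_ = np.linalg.lstsq(g, np.ones(1, dtype=complex), rcond=None)
    return Vn @ c


class TestAutocorrelation:
    def test_single_exponential_closed_form(self):
        w0 = 0.9
        n = np.arange(4096)
        R = autocorrelation_matrix(sig(np.exp(1j * w0 * n)), M=6).R
        expect = np.exp(1j * w0 * np.subtract.outer(np.arange(6), np.arange(6)))
        assert np.abs(R - expect).max() < 1e-2
        lam = np.linalg.eigvalsh(R)
        assert lam[-2] / lam[-1] < 1e-2  # effectively rank one

    def test_white_noise_is_nearly_diagonal(self):
        rng = np.random.default_rng(2024)
        x = (rng.standard_normal(16384) + 1j * rng.standard_normal(16384)) / np.sqrt(2)
        R = autocorrelation_matrix(sig(x), M=8).R
        off = R - np.diag(np.diag(R))
        assert np.abs(off).max() <= 0.05
        assert np.abs(np.diag(R) - 1).max() <= 0.05

    @pytest.mark.parametrize("estimator", ["biased_lag", "data_outer_product"])
    def test_hermitian_and_psd(self, estimator, rng):
        x = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        R = autocorrelation_matrix(sig(x), M=10, estimator=estimator).R
        assert np.abs(R - R.conj().T).max() < 1e-12
        lam = np.linalg.eigvalsh(R)
        assert lam.min() >= -1e-10 * np.trace(R).real

    def test_biased_lag_is_toeplitz(self, rng):
        x = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        R = autocorrelation_matrix(sig(x), M=6).R
        for d in range(-5, 6):
            diag = np.diagonal(R, d)
            assert np.abs(diag - diag[0]).max() < 1e-14

    def test_lag_size_validation(self):
        with pytest.raises(ValueError, match="lag size"):
            autocorrelation_matrix(sig(np.ones(4)), M=5)


class TestEigendecompose:
    def test_scaled_identity(self):
        eig = eigendecompose(2.0 * np.eye(5))
        np.testing.assert_allclose(eig.eigenvalues, 2.0)

    def test_rank_one_plus_noise_closed_form(self):
        M, P, s2, w0 = 8, 3.0, 1.0, 1.1
        e = np.exp(1j * w0 * np.arange(M))
        eig = eigendecompose(P * np.outer(e, e.conj()) + s2 * np.eye(M))
        assert eig.eigenvalues[0] == pytest.approx(M * P + s2, rel=1e-12)
        np.testing.assert_allclose(eig.eigenvalues[1:], s2, rtol=1e-12)

    def test_sorted_orthonormal_and_reconstructs(self, rng):
        A = rng.standard_normal((7, 7)) + 1j * rng.standard_normal((7, 7))
        R = A @ A.conj().T
        eig = eigendecompose(R)
        assert np.all(np.diff(eig.eigenvalues) <= 0)
        V = eig.eigenvectors
        np.testing.assert_allclose(V.conj().T @ V, np.eye(7), atol=1e-10)
        recon = (V * eig.eigenvalues) @ V.conj().T
        assert np.abs(recon - R).max() <= 1e-8 * np.linalg.norm(R)

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError, match="Hermitian"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestModelOrder:
    def test_argmax_of_eigenvalue_ratio(self):
        eig = EigenSystem(
            eigenvalues=np.array([10.0, 9.0, 1.01, 1.00, 0.99]),
            eigenvectors=np.eye(5, dtype=complex),
        )
        sel = select_model_order(eig, 1, 4)
        assert sel.p == 2
        assert sel.ratios[1] == pytest.approx(9.0 / 1.01)

    def test_flat_spectrum_is_an_error(self):
        eig = EigenSystem(
            eigenvalues=np.full(5, 2.0), eigenvectors=np.eye(5, dtype=complex)
        )
        with pytest.raises(ValueError, match="no eigenvalue gap"):
            select_model_order(eig)

    def test_exact_model_recovers_true_order(self, rng):
        for p in (1, 2, 3):
            eig, _ = random_exact_eigensystem(rng, M=10, p=p)
            assert select_model_order(eig, 1, 8).p == p


class TestLeastNormVector:
    def test_two_by_two_oracle(self):
        """Single exponential, M=2: the noise eigenvector gives
        a = (1, -e^{jw0}) and A(z) has its zero exactly at e^{jw0}."""
        w0 = 0.8
        e = np.array([1.0, np.exp(1j * w0)]) / np.sqrt(2)
        eig = eigendecompose(np.outer(e, e.conj()))
        a = least_norm_vector(eig, 1).a
        np.testing.assert_allclose(a, [1.0, -np.exp(1j * w0)], atol=1e-12)
        assert abs(a[0] + a[1] * np.exp(-1j * w0)) < 1e-12  # A(e^{jw0}) = 0

    def test_unit_first_element_and_noise_subspace_membership(self, rng):
        for trial in range(10):
            M = int(rng.integers(4, 9))
            p = int(rng.integers(1, M - 1))
            eig, _ = random_exact_eigensystem(rng, M, p)
            a = least_norm_vector(eig, p).a
            assert a[0] == 1.0
            Vs = eig.signal_subspace(p)
            assert np.linalg.norm(Vs.conj().T @ a) <= 1e-8 * np.linalg.norm(a)

    def test_projection_matrix_hermitian_idempotent(self, rng):
        eig, _ = random_exact_eigensystem(rng, M=6, p=2)
        Vn = eig.noise_subspace(2)
        Pn = Vn @ Vn.conj().T
        assert np.abs(Pn - Pn.conj().T).max() <= 1e-10
        assert np.abs(Pn @ Pn - Pn).max() <= 1e-10

    def test_minimal_norm_against_independent_solver(self, rng):
        """||a|| matches the LAPACK minimum-norm constrained solution and
        no feasible perturbation decreases it."""
        for trial in range(10):
            M = int(rng.integers(3, 7))
            p = int(rng.integers(1, M - 1))
            eig, _ = random_exact_eigensystem(rng, M, p)
            a = least_norm_vector(eig, p).a
            Vn = eig.noise_subspace(p)
            oracle = min_norm_oracle(Vn)
            assert np.linalg.norm(a) == pytest.approx(
                np.linalg.norm(oracle), abs=1e-8
            )
            # feasible directions keep a[0] = 1 and stay in the subspace
            for _ in range(5):
                c = rng.standard_normal(M - p) + 1j * rng.standard_normal(M - p)
                d = Vn @ c
                if abs(d[0]) > 1e-8:
                    d = d - a * d[0]  # enforce d[0] = 0 within the subspace
                assert np.linalg.norm(a + 0.1 * d) >= np.linalg.norm(a) - 1e-10

    def test_nulls_at_true_frequencies_and_spurious_roots_inside(self, rng):
        """Exact noiseless autocorrelation: A(e^{jw_i}) vanishes at every
        line and every other root of A(z) stays inside the unit circle."""
        for p, M in [(1, 5), (2, 6), (3, 8)]:
            eig, model = random_exact_eigensystem(rng, M, p, noise_var=0.0)
            a = least_norm_vector(eig, p).a
            for w in model.frequencies:
                e = np.exp(-1j * w * np.arange(M))
                assert abs(e @ a) <= 1e-6
            roots = np.roots(a)  # coefficients of z^{M-1} A(z)
            signal_roots = np.exp(1j * np.array(model.frequencies))
            spurious = [
                r for r in roots
                if np.min(np.abs(r - signal_roots)) > 1e-4
            ]
            assert len(spurious) == M - 1 - p
            assert all(abs(r) < 1 + 1e-6 for r in spurious)

    def test_one_dimensional_noise_subspace(self, rng):
        eig, _ = random_exact_eigensystem(rng, M=5, p=4)
        vM = eig.eigenvectors[:, -1]
        a = least_norm_vector(eig, 4).a
        np.testing.assert_allclose(a, vM / vM[0], atol=1e-10)

    def test_order_out_of_range_rejected(self, rng):
        eig, _ = random_exact_eigensystem(rng, M=5, p=2)
        with pytest.raises(ValueError):
            least_norm_vector(eig, 5)


class TestPseudoSpectrum:
    def test_delta_vector_gives_flat_spectrum(self):
        from period3.subspace import LeastNormVector

        a = LeastNormVector(a=np.array([1.0, 0, 0, 0], complex), p=1)
        ps = pseudo_spectrum(a, nfft=16)
        np.testing.assert_allclose(ps.values, 1.0)

    def test_peak_at_line_frequency_and_capped(self):
        w0 = np.pi / 2
        e = np.array([1.0, np.exp(1j * w0)]) / np.sqrt(2)
        eig = eigendecompose(np.outer(e, e.conj()))
        vec = least_norm_vector(eig, 1)
        ps = pseudo_spectrum(vec, nfft=4)
        assert np.argmax(ps.values) == 1  # 0.25 cycles/sample
        assert ps.values.max() == PSEUDO_SPECTRUM_CAP
        assert np.all(ps.values > 0)

    def test_grid_refinement_consistency(self, rng):
        eig, _ = random_exact_eigensystem(rng, M=6, p=1, noise_var=0.3)
        vec = least_norm_vector(eig, 1)
        coarse = pseudo_spectrum(vec, nfft=64)
        fine = pseudo_spectrum(vec, nfft=128)
        f_c = coarse.frequencies[np.argmax(coarse.values)]
        f_f = fine.frequencies[np.argmax(fine.values)]
        d = abs(f_f - f_c)
        assert min(d, 1 - d) <= 1.0 / 64

    def test_single_frequency_evaluation_matches_grid(self, rng):
        eig, _ = random_exact_eigensystem(rng, M=6, p=2, noise_var=0.3)
        vec = least_norm_vector(eig, 2)
        nfft = 12
        ps = pseudo_spectrum(vec, nfft)
        assert pseudo_spectrum_value(vec, f=4 / 12) == pytest.approx(
            ps.values[4], rel=1e-10
        )


class TestLeastNormTrack:
    def test_pure_codon_repeat_is_translation_invariant(self):
        seq = NucleotideSequence("x", "atg" * 120)
        track = period3_track_least_norm(map_sequence(seq), window=90, hop=9, order=3)
        np.testing.assert_allclose(track.values, track.values[0], atol=1e-6)

    def test_failed_windows_are_masked_not_fatal(self):
        bases = "acgt" * 40 + "n" * 160 + "acgt" * 40
        with pytest.warns(UserWarning):
            seq = map_sequence(NucleotideSequence("x", bases))
            track = period3_track_least_norm(seq, window=120, hop=30, order="auto")
        assert np.isnan(track.values).any()
        assert np.isfinite(track.values).any()

    def test_window_validation(self):
        x = map_sequence(NucleotideSequence("x", "acgt" * 30))
        with pytest.raises(ValueError, match="divisible by 3"):
            period3_track_least_norm(x, window=100)
        with pytest.raises(ValueError, match="fixed order"):
            period3_track_least_norm(x, window=60, lag=12, order=12)
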