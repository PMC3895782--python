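"""Minimum-norm (least-norm) noise-subspace frequency estimation.

The mapped DNA signal inside a coding region is modeled as a sum of ``p``
complex exponentials in white noise,

    x[n] = sum_i A_i exp(j n w_i) + w[n],

whose M-lag autocorrelation matrix decomposes into a rank-``p`` signal part
plus a scaled identity:  R = E P E^H + sigma^2 I.  Eigendecomposition splits
C^M into the *signal subspace* (eigenvectors of the p largest eigenvalues)
and the orthogonal *noise subspace*.  Any vector ``a`` in the noise subspace
satisfies e(w_i)^H a = 0 at the true frequencies, so the pseudo-spectrum

    P_LN(w) = 1 / |e(w)^H a|^2,      e(w) = [1, e^{jw}, ..., e^{j(M-1)w}]^T

peaks at them.  Among all noise-subspace vectors with unit first element the
*minimum-norm* choice

    a = P_n u_1 / (u_1^H P_n u_1),      P_n = V_n V_n^H

additionally pushes the spurious zeros of A(z) = sum_k a_k z^-k inside the
unit circle, suppressing false peaks.  The model order ``p`` is selected by
the largest eigenvalue-ratio gap lambda_p / lambda_{p+1} on the sorted
spectrum (the "elbow" of the scree plot).

Applied per sliding window at the fixed frequency 1/3 cycles/base, this
yields a positional period-3 track whose sharp peaks mark protein-coding
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .periodogram import SpectralTrack
from .sequences import ComplexSignal

__all__ = [
    "ExponentialsInNoiseModel",
    "AutocorrelationMatrix",
    "EigenSystem",
    "ModelOrderSelection",
    "LeastNormVector",
    "PseudoSpectrum",
    "autocorrelation_matrix",
    "exact_autocorrelation",
    "eigendecompose",
    "select_model_order",
    "least_norm_vector",
    "pseudo_spectrum",
    "pseudo_spectrum_value",
    "period3_track_least_norm",
    "PSEUDO_SPECTRUM_CAP",
]

#: Pseudo-spectrum values are capped here before any dB conversion: the
#: finite-precision estimate can land arbitrarily close to an exact null.
PSEUDO_SPECTRUM_CAP = 1e12

#: Period-3 frequency in cycles/sample.
F_PERIOD3 = 1.0 / 3.0


@dataclass(frozen=True)
class ExponentialsInNoiseModel:
    """p complex exponentials in circular white Gaussian noise.

    ``amplitudes`` are the magnitudes |A_i|; phases are drawn uniformly on
    [-pi, pi) at simulation time.  ``frequencies`` are in radians/sample and
    must be distinct modulo 2*pi.
    """

    frequencies: tuple[float, ...]
    amplitudes: tuple[float, ...]
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.amplitudes):
            raise ValueError("frequencies and amplitudes must have equal length")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be nonnegative")
        w = np.mod(np.asarray(self.frequencies), 2 * np.pi)
        if len(w) > 1 and np.min(np.abs(np.subtract.outer(w, w))[~np.eye(len(w), dtype=bool)]) == 0:
            raise ValueError("frequencies must be distinct modulo 2*pi")

    @property
    def p(self) -> int:
        return len(self.frequencies)

    @property
    def powers(self) -> np.ndarray:
        return np.asarray(self.amplitudes, dtype=float) ** 2


@dataclass(frozen=True)
class AutocorrelationMatrix:
    """Hermitian PSD M x M autocorrelation matrix estimate."""

    R: np.ndarray
    M: int
    estimator: str  # 'biased_lag' or 'data_outer_product'


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues (descending) and orthonormal eigenvectors of R."""

    eigenvalues: np.ndarray  # real, sorted descending
    eigenvectors: np.ndarray  # columns, unit norm, same order

    @property
    def M(self) -> int:
        return len(self.eigenvalues)

    def noise_subspace(self, p: int) -> np.ndarray:
        """Columns spanning the noise subspace for model order p."""
        return self.eigenvectors[:, p:]

    def signal_subspace(self, p: int) -> np.ndarray:
        return self.eigenvectors[:, :p]


@dataclass(frozen=True)
class ModelOrderSelection:
    p: int
    ratios: np.ndarray  # lambda_q / lambda_{q+1} for q in search range
    search_range: tuple[int, int]


@dataclass(frozen=True)
class LeastNormVector:
    """Minimum-norm noise-subspace vector with unit first element."""

    a: np.ndarray
    p: int


@dataclass(frozen=True)
class PseudoSpectrum:
    frequencies: np.ndarray  # cycles/sample on [0, 1)
    values: np.ndarray  # strictly positive, capped


def autocorrelation_matrix(
    signal, M: int, estimator: str = "biased_lag"
) -> AutocorrelationMatrix:
    """Estimate the M x M autocorrelation matrix of a complex signal.

    ``biased_lag`` (default) builds the Hermitian Toeplitz matrix from the
    biased lag estimates r(m) = (1/N) sum_n x[n+m] conj(x[n]); this
    estimator is positive semidefinite by construction.
    ``data_outer_product`` averages outer products of length-M snapshots
    (Hermitian PSD but not Toeplitz).
    """
    x = np.asarray(signal.values if isinstance(signal, ComplexSignal) else signal,
                   dtype=np.complex128)
    N = len(x)
    if not 1 <= M <= N:
        raise ValueError(f"lag size M={M} must satisfy 1 <= M <= N={N}")
    if estimator == "biased_lag":
        r = np.array([np.dot(x[m:], np.conj(x[: N - m])) for m in range(M)]) / N
        R = toeplitz(r, np.conj(r))
    elif estimator == "data_outer_product":
        S = np.lib.stride_tricks.sliding_window_view(x, M)
        R = (S.T @ np.conj(S)) / S.shape[0]
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return AutocorrelationMatrix(R=R, M=M, estimator=estimator)


def exact_autocorrelation(model: ExponentialsInNoiseModel, M: int) -> AutocorrelationMatrix:
    """Closed-form autocorrelation matrix of the exponentials-in-noise model.

    R[k, l] = sum_i P_i exp(j (k-l) w_i) + sigma^2 delta[k-l].  Useful as an
    exact (infinite-data) reference for subspace algebra.
    """
    k = np.arange(M)
    R = np.zeros((M, M), dtype=np.complex128)
    for w, P in zip(model.frequencies, model.powers):
        e = np.exp(1j * w * k)
        R += P * np.outer(e, np.conj(e))
    R += model.noise_variance * np.eye(M)
    return AutocorrelationMatrix(R=R, M=M, estimator="exact")


def eigendecompose(R: AutocorrelationMatrix | np.ndarray) -> EigenSystem:
    """Eigendecompose a Hermitian matrix, sorting eigenvalues descending.

    Inputs Hermitian to within 1e-10 (relative) are symmetrized; anything
    worse is rejected.
    """
    A = np.asarray(R.R if isinstance(R, AutocorrelationMatrix) else R)
    scale = max(np.abs(A).max(), 1e-300)
    if np.abs(A - A.conj().T).max() > 1e-10 * scale:
        raise ValueError("matrix is not Hermitian (beyond 1e-10 relative tolerance)")
    A = (A + A.conj().T) / 2
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    return EigenSystem(eigenvalues=vals[order], eigenvectors=vecs[:, order])


def select_model_order(
    eig: EigenSystem, p_min: int = 1, p_max: int | None = None
) -> ModelOrderSelection:
    """Pick the model order by the largest eigenvalue-ratio gap.

    Returns the argmax of lambda_q / lambda_{q+1} over q in
    ``[p_min, p_max]`` together with the full ratio series (the scree-ratio
    curve) for inspection.  A spectrum with no gap at all (all eigenvalues
    equal, i.e. pure white noise) is an error.
    """
    lam = eig.eigenvalues
    M = len(lam)
    if p_max is None:
        p_max = M - 1
    if not 1 <= p_min <= p_max <= M - 1:
        raise ValueError(f"invalid search range [{p_min}, {p_max}] for M={M}")
    scale = max(abs(lam[0]), 1e-300)
    if lam[0] - lam[-1] <= 1e-10 * scale:
        raise ValueError("no eigenvalue gap: all eigenvalues equal (white-noise-only input)")
    q = np.arange(p_min, p_max + 1)
    ratios = lam[q - 1] / np.maximum(lam[q], 1e-300)
    p = int(q[np.argmax(ratios)])
    return ModelOrderSelection(p=p, ratios=ratios, search_range=(p_min, p_max))


def least_norm_vector(eig: EigenSystem, p: int) -> LeastNormVector:
    """Minimum-norm noise-subspace vector with unit first element.

    With V_n the noise-subspace eigenvector matrix and u_1 the first unit
    vector, the solution of

        min ||a||  subject to  a in span(V_n),  a[0] = 1

    is a = V_n V_n^H u_1 / (u_1^H V_n V_n^H u_1).  The denominator vanishes
    only when u_1 is orthogonal to the noise subspace, in which case no
    vector in the subspace has nonzero first element.
    """
    M = eig.M
    if not 1 <= p < M:
        raise ValueError(f"model order p={p} must satisfy 1 <= p < M={M}")
    Vn = eig.noise_subspace(p)
    g = Vn[0, :]  # first row: V_n^H u_1 conjugated
    denom = float(np.real(np.vdot(g, g)))  # u_1^H P_n u_1
    if denom < 1e-12:
        raise ValueError(
            "first coordinate is orthogonal to the noise subspace "
            f"(u_1^H P_n u_1 = {denom:.3e}); cannot normalize the least-norm vector"
        )
    a = Vn @ np.conj(g) / denom
    a[0] = 1.0  # exact by construction; remove rounding residue
    return LeastNormVector(a=a, p=p)


def pseudo_spectrum(vec: LeastNormVector, nfft: int) -> PseudoSpectrum:
    """Evaluate P_LN(w) = 1/|e(w)^H a|^2 on an nfft-point frequency grid.

    |e(w_k)^H a| is the magnitude of the nfft-point DFT of ``a``; values are
    capped at ``PSEUDO_SPECTRUM_CAP`` so grid points near an exact null stay
    finite.
    """
    a = vec.a
    if nfft < len(a):
        raise ValueError(f"nfft={nfft} must be at least len(a)={len(a)}")
    denom = np.abs(np.fft.fft(a, nfft)) ** 2
    values = np.where(denom < 1.0 / PSEUDO_SPECTRUM_CAP, PSEUDO_SPECTRUM_CAP, 1.0 / np.maximum(denom, 1e-300))
    return PseudoSpectrum(frequencies=np.arange(nfft) / nfft, values=values)


def pseudo_spectrum_value(vec: LeastNormVector, f: float = F_PERIOD3) -> float:
    """Pseudo-spectrum at a single frequency f (cycles/sample), exactly.

    Uses the direct steering-vector inner product e(w)^H a rather than the
    nearest FFT bin, so f = 1/3 is evaluated without grid error.
    """
    a = vec.a
    w = 2 * np.pi * f
    denom = abs(np.dot(np.exp(-1j * w * np.arange(len(a))), a)) ** 2
    if denom < 1.0 / PSEUDO_SPECTRUM_CAP:
        return PSEUDO_SPECTRUM_CAP
    return 1.0 / denom


def default_lag_size(window: int) -> int:
    """Default autocorrelation lag size for a given analysis window."""
    return int(min(max(window // 3, 12), 60, window))


def period3_track_least_norm(
    signal: ComplexSignal,
    window: int,
    hop: int = 3,
    lag: int | None = None,
    order: int | str = "auto",
    estimator: str = "biased_lag",
    db: bool = True,
) -> SpectralTrack:
    """Sliding-window minimum-norm period-3 track.

    Per window: autocorrelation matrix (lag ``lag``), eigendecomposition,
    model order (fixed integer or per-window eigenvalue-ratio selection),
    least-norm vector, pseudo-spectrum value at 1/3 cycles/base.  Windows
    where any step fails (e.g. a gap-free eigenvalue spectrum) are masked
    as NaN with a warning rather than aborting the track.

    Values are reported in dB (10 log10) by default.
    """
    x = np.asarray(signal.values)
    N = len(x)
    if window % 3 != 0:
        raise ValueError(f"window={window} must be divisible by 3")
    if not 3 <= window <= N:
        raise ValueError(f"window={window} must be in [3, {N}]")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    M = default_lag_size(window) if lag is None else lag
    if not 2 < M <= window:
        raise ValueError(f"lag size M={M} must satisfy 3 <= M <= window={window}")
    if isinstance(order, int) and not 1 <= order < M:
        raise ValueError(f"fixed order {order} must satisfy 1 <= p < M={M}")
    starts = np.arange(0, N - window + 1, hop)
    values = np.full(len(starts), np.nan)
    n_failed = 0
    for i, s in enumerate(starts):
        seg = x[s : s + window]
        try:
            eig = eigendecompose(autocorrelation_matrix(seg, M, estimator))
            p = order if isinstance(order, int) else select_model_order(eig, 1, M - 2).p
            vec = least_norm_vector(eig, p)
            values[i] = pseudo_spectrum_value(vec)
        except ValueError:
            n_failed += 1
    if n_failed:
        warnings.warn(
            f"{n_failed}/{len(starts)} windows failed and were masked as NaN",
            stacklevel=2,
        )
    if db:
        values = 10.0 * np.log10(np.maximum(values, 1e-300))
    positions = signal.origin_offset + starts + window // 2 + 1
    return SpectralTrack(
        positions=positions,
        values=values,
        window_length=window,
        hop=hop,
        method="least_norm",
        units="db" if db else "linear",
    )
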