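"""Modified (averaged, windowed) periodogram baseline.

The classical non-parametric route to the period-3 signature: the mapped
signal is divided into overlapping segments, each segment is tapered
(Bartlett window by default) and its periodogram

    P(k/M) = (1/M) | sum_n x[n] exp(-j 2 pi n k / M) |^2

is computed; the segment periodograms are averaged to trade frequency
resolution for variance.  Windowed estimates are normalized by the window
power (sum of squared window samples) so that the rectangular-window case
reduces exactly to the formula above.

For exon detection the relevant quantity is the power at frequency 1/3
cycles/base, extracted per sliding window to form a positional track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as _windows

from .sequences import ComplexSignal

__all__ = [
    "PsdEstimate",
    "SpectralTrack",
    "modified_periodogram",
    "period3_track_sdft",
    "choose_window_length",
]


@dataclass(frozen=True)
class PsdEstimate:
    """Averaged-periodogram PSD estimate on the M-point DFT grid."""

    frequencies: np.ndarray  # cycles/sample, k/M for k = 0..M-1
    power: np.ndarray  # nonnegative
    M: int  # segment length
    K: int  # number of averaged segments
    overlap_fraction: float


@dataclass(frozen=True)
class SpectralTrack:
    """Per-position period-3 content along a sequence.

    ``positions`` are 1-based window-center coordinates in the source
    sequence; spacing is the constant hop.  ``values`` may be linear power
    (``units='linear'``) or decibels (``units='db'``); windows where the
    estimator failed are NaN (masked), never fabricated.
    """

    positions: np.ndarray
    values: np.ndarray
    window_length: int
    hop: int
    method: str  # 'sdft' or 'least_norm'
    units: str = "linear"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if len(pos) > 1 and not np.all(np.diff(pos) == self.hop):
            raise ValueError("track positions must increase by the constant hop")


def _taper(M: int, window: str) -> np.ndarray:
    if window == "bartlett":
        # sym=True triangular taper, the standard choice for averaging
        return _windows.triang(M)
    if window == "rect":
        return np.ones(M)
    raise ValueError(f"unknown window {window!r}; choose 'bartlett' or 'rect'")


def _segment_periodogram(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # window-power normalization: rect reduces to (1/M)|X|^2
    X = np.fft.fft(w * x)
    return (X.real**2 + X.imag**2) / np.sum(w * w)


def modified_periodogram(
    signal: ComplexSignal,
    M: int,
    overlap: float = 0.5,
    window: str = "bartlett",
) -> PsdEstimate:
    """Average windowed periodograms over K overlapping segments.

    Parameters
    ----------
    signal : ComplexSignal
        Mapped sequence (or any complex series).
    M : int
        Segment length; must satisfy ``3 <= M <= len(signal)``.
    overlap : float
        Fractional overlap between consecutive segments, in ``[0, 1)``.
        The default 0.5 is the usual averaged-periodogram operating point.
    window : {'bartlett', 'rect'}
        Per-segment taper.
    """
    x = np.asarray(signal.values)
    N = len(x)
    if M < 3:
        raise ValueError(f"segment length M={M} must be at least 3")
    if M > N:
        raise ValueError(f"segment length M={M} exceeds signal length N={N}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap fraction must be in [0, 1); got {overlap}")
    w = _taper(M, window)
    hop = max(1, int(round(M * (1.0 - overlap))))
    starts = range(0, N - M + 1, hop)
    acc = np.zeros(M)
    K = 0
    for s in starts:
        acc += _segment_periodogram(x[s : s + M], w)
        K += 1
    return PsdEstimate(
        frequencies=np.arange(M) / M,
        power=acc / K,
        M=M,
        K=K,
        overlap_fraction=overlap,
    )


def period3_track_sdft(
    signal: ComplexSignal,
    M: int,
    hop: int = 3,
    window: str = "bartlett",
) -> SpectralTrack:
    """Sliding-window period-3 power track (the DFT baseline).

    For each window of length ``M`` (a multiple of 3, so that DFT bin
    ``k = M/3`` sits exactly on frequency 1/3 cycles/base) the windowed
    periodogram power at that bin is recorded at the window-center
    position.
    """
    x = np.asarray(signal.values)
    N = len(x)
    if M % 3 != 0:
        near = 3 * round(M / 3)
        raise ValueError(
            f"window length M={M} must be divisible by 3 (nearest multiple: {near})"
        )
    if M < 3 or M > N:
        raise ValueError(f"window length M={M} must be in [3, {N}]")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    w = _taper(M, window)
    k3 = M // 3
    starts = np.arange(0, N - M + 1, hop)
    wpow = np.sum(w * w)
    phase = np.exp(-2j * np.pi * k3 * np.arange(M) / M) * w
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        X = np.dot(phase, x[s : s + M])
        values[i] = (X.real**2 + X.imag**2) / wpow
    positions = signal.origin_offset + starts + M // 2 + 1  # 1-based centers
    return SpectralTrack(
        positions=positions,
        values=values,
        window_length=M,
        hop=hop,
        method="sdft",
        units="linear",
    )


def choose_window_length(N: int) -> int:
    """Default analysis window length for a sequence of N bases.

    A compromise between spectral resolution (large M) and statistical
    variance (small M): M is a multiple of 3 strictly inside the open
    interval (N/25, N/3), anchored at N/23 — for an 8060-base span that
    anchor gives 351 bases, a typical choice for genes with exons of a few
    hundred bases.
    """
    if N < 75:
        raise ValueError(f"sequence length N={N} too short to choose a window (need >= 75)")
    lo, hi = N / 25.0, N / 3.0
    m_min = 3 * int(np.floor(lo / 3.0)) + 3  # smallest multiple of 3 > lo
    if m_min <= lo:
        m_min += 3
    m_max = 3 * int(np.ceil(hi / 3.0)) - 3  # largest multiple of 3 < hi
    if m_max >= hi:
        m_max -= 3
    if m_min > m_max:
        raise ValueError(f"no multiple of 3 strictly inside ({lo:.1f}, {hi:.1f})")
    anchor = 3 * round(N / 23.0 / 3.0)
    return int(min(max(anchor, m_min), m_max))
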