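"""End-to-end prediction: sequence -> track -> called regions.

This module fixes the operating defaults that turn the estimators into a
coding-region predictor:

* mapping: the proposed quaternary code (a=-1, c=-j, g=+1, t=+j);
* window: explicit, or chosen from the sequence length (multiple of 3 in
  (N/25, N/3), anchored at N/23); the window should be comparable to the
  exon scale of interest;
* least-norm method: autocorrelation lag = window/3 (capped at 60), fixed
  model order p = 3 — the coding-window model has exactly three
  deterministic lines (DC and the two period-3 components of the mapped
  codon-position means) — and threshold-free calling with a 10 dB absolute
  null-depth floor plus persistent support over at least window/3 bases;
* SDFT baseline: Bartlett taper, mean-relative threshold 1.75 (the
  conventional stricter of the two published operating points).
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import (
    LEAST_NORM_DEPTH_FLOOR_DB,
    PredictedRegions,
    detect_peaks,
)
from .periodogram import SpectralTrack, choose_window_length, period3_track_sdft
from .sequences import NucleotideSequence, map_sequence
from .subspace import period3_track_least_norm

__all__ = ["PredictorSettings", "predict_regions"]

#: Default fixed model order for per-window least-norm estimation: DC plus
#: the two complex-exponential components at +-1/3 cycles/base.
DEFAULT_ORDER = 3

#: Default mean-relative peak threshold for the periodogram baseline.
DEFAULT_SDFT_THRESHOLD = 1.75


@dataclass(frozen=True)
class PredictorSettings:
    """Resolved analysis settings actually used for a prediction run."""

    method: str
    mapping: str
    window: int
    hop: int
    lag: int | None
    order: int | str
    taper: str
    threshold: float | str
    min_separation: int
    depth_floor: float | None
    min_width: int | None


def predict_regions(
    seq: NucleotideSequence,
    method: str = "least_norm",
    mapping: str = "proposed_quaternary",
    window: int | None = None,
    hop: int = 3,
    lag: int | None = None,
    order: int | str | None = None,
    taper: str = "bartlett",
    threshold: float | str | None = None,
    min_separation: int | None = None,
    depth_floor: float | None = None,
    min_width: int | None = None,
) -> tuple[SpectralTrack, PredictedRegions, PredictorSettings]:
    """Predict period-3 (coding) regions in one sequence.

    Parameters left at ``None`` resolve to the method's operating defaults
    (see module docstring).  Returns the spectral track, the called
    regions, and the fully resolved settings for provenance.
    """
    if method not in ("least_norm", "sdft"):
        raise ValueError(f"unknown method {method!r}; use 'least_norm' or 'sdft'")
    signal = map_sequence(seq, mapping)
    W = window if window is not None else choose_window_length(len(signal))
    if min_separation is None:
        min_separation = max(W // 4, hop)
    if method == "sdft":
        track = period3_track_sdft(signal, M=W, hop=hop, window=taper)
        thr: float | str = DEFAULT_SDFT_THRESHOLD if threshold is None else threshold
        regions = detect_peaks(
            track, threshold=thr, min_separation=min_separation, min_width=min_width
        )
        resolved_lag: int | None = None
        resolved_order: int | str = "n/a"
    else:
        resolved_order = DEFAULT_ORDER if order is None else order
        track = period3_track_least_norm(
            signal, window=W, hop=hop, lag=lag, order=resolved_order
        )
        thr = "none" if threshold is None else threshold
        if depth_floor is None and thr == "none":
            depth_floor = LEAST_NORM_DEPTH_FLOOR_DB
        if min_width is None and thr == "none":
            min_width = W // 3
        regions = detect_peaks(
            track,
            threshold=thr,
            min_separation=min_separation,
            depth_floor=depth_floor,
            min_width=min_width,
        )
        from .subspace import default_lag_size

        resolved_lag = lag if lag is not None else default_lag_size(W)
    settings = PredictorSettings(
        method=method,
        mapping=signal.scheme,
        window=W,
        hop=hop,
        lag=resolved_lag,
        order=resolved_order,
        taper=taper,
        threshold=thr,
        min_separation=min_separation,
        depth_floor=depth_floor,
        min_width=min_width,
    )
    return track, regions, settings
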