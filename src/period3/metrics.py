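"""Peak calling and exon-level prediction evaluation.

A spectral track is reduced to called regions (peaks), matched against
annotated exon intervals, and scored with the standard exon-level measures

    Sn = Tp / (Tp + Fn)        sensitivity
    Sp = Tp / (Tp + Fp)        specificity
    Mr = Me / Ae               miss rate   (missed exons over actual exons)
    Wr = We / Pe               wrong rate  (false peaks over predicted peaks)

A prediction matches an exon iff its peak position lies inside the
annotated interval (containment; an optional slack widens the intervals).
Track spikiness is summarized by the quality factor, the ratio of the
variance to the squared mean of the spectral values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .periodogram import SpectralTrack

__all__ = [
    "ExonAnnotation",
    "PredictedRegions",
    "ConfusionCounts",
    "PredictionMetrics",
    "detect_peaks",
    "confusion_counts",
    "prediction_measures",
    "quality_factor",
    "percent_rise",
    "read_intervals",
    "write_bed",
]

#: Peak-prominence multiplier for the threshold-free (least-norm) rule:
#: a position is above-noise when it exceeds the track median by more than
#: this many median absolute deviations.
MAD_PROMINENCE = 6.0

#: Absolute null-depth floor (dB) used for least-norm tracks: a called
#: period-3 null must be at least this far above the unit off-null response
#: level of a minimum-norm vector (a[0] = 1), i.e. at least 10x deeper than
#: the typical background response.
LEAST_NORM_DEPTH_FLOOR_DB = 10.0


@dataclass(frozen=True)
class ExonAnnotation:
    """Annotated exon intervals, 1-based inclusive, sorted, non-overlapping."""

    intervals: tuple[tuple[int, int], ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.intervals:
            if start > end:
                raise ValueError(f"interval ({start}, {end}) has start > end")
            if start <= prev_end:
                raise ValueError("exon intervals must be sorted and non-overlapping")
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class PredictedRegions:
    """Called regions, each carrying exactly one representative peak."""

    peaks: tuple[tuple[int, float], ...]  # (position, value)
    regions: tuple[tuple[int, int], ...]  # 1-based inclusive
    threshold_used: float | str = "none"


@dataclass(frozen=True)
class ConfusionCounts:
    Tp: int  # exons containing at least one peak
    Fp: int  # peaks outside every exon (= We)
    Fn: int  # exons with no peak (= Me)
    Me: int
    Ae: int
    We: int
    Pe: int
    peaks_in_exons: int  # peak-count conservation: peaks_in_exons + Fp = Pe


@dataclass(frozen=True)
class PredictionMetrics:
    """Exon-level rates; undefined rates (zero denominator) are None."""

    Sn: float | None
    Sp: float | None
    avg: float | None  # (Sn + Sp) / 2
    Mr: float | None
    Wr: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        d = {"Sn": self.Sn, "Sp": self.Sp, "avg": self.avg, "Mr": self.Mr, "Wr": self.Wr}
        d.update(self.counts.__dict__)
        return d


def detect_peaks(
    track: SpectralTrack,
    threshold: float | str = "none",
    min_separation: int | None = None,
    depth_floor: float | None = None,
    min_width: int | None = None,
) -> PredictedRegions:
    """Call peak regions on a spectral track.

    Two modes:

    * numeric ``threshold`` — the track is normalized to unit mean and
      contiguous runs >= threshold become regions (the periodogram
      convention, where dimensionless thresholds like 1.75/1.5 are applied
      to a mean-relative scale);
    * ``threshold='none'`` — a run is above-noise when it exceeds the track
      median by more than ``MAD_PROMINENCE`` median absolute deviations
      (the threshold-free rule used with the least-norm track).

    ``depth_floor`` (optional, same units as the track) additionally
    requires called samples to reach an absolute level.  The least-norm
    pseudo-spectrum has a natural scale — the vector's first element is
    unity, so off-null responses sit near or below 1 (0 dB) — and a genuine
    period-3 null is orders of magnitude deeper; the pipeline passes a
    floor of ``LEAST_NORM_DEPTH_FLOOR_DB`` for least-norm tracks so that
    shallow chance excursions of the background never become calls.

    ``min_width`` (optional, bases) requires a merged region to be
    supported by above-threshold samples spanning at least that many bases.
    A genuine coding region shows the period-3 null in every sliding window
    that covers it, so its support is at least comparable to the window
    length, whereas chance nulls of the background decay as the window
    slides; requiring persistent support is what makes threshold-free
    least-norm calling selective.

    Runs separated by less than ``min_separation`` bases are merged (the
    larger maximum wins as the representative peak).  NaN (masked) samples
    never participate.
    """
    positions = np.asarray(track.positions)
    values = np.asarray(track.values, dtype=float)
    if len(values) == 0:
        raise ValueError("track is empty")
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("track has no finite values")
    if min_separation is None:
        min_separation = max(track.window_length // 4, track.hop)
    if isinstance(threshold, (int, float)):
        mean = np.nanmean(values)
        if mean <= 0:
            raise ValueError("cannot normalize: track mean is not positive")
        above = finite & (values / mean >= float(threshold))
        thr_used: float | str = float(threshold)
    elif threshold == "none":
        med = np.nanmedian(values)
        mad = np.nanmedian(np.abs(values - med))
        above = finite & (values - med > MAD_PROMINENCE * mad)
        thr_used = "none"
    else:
        raise ValueError(f"threshold must be numeric or 'none'; got {threshold!r}")
    if depth_floor is not None:
        above &= values >= depth_floor

    # contiguous above-runs -> candidate regions
    idx = np.flatnonzero(above)
    runs: list[list[int]] = []
    for i in idx:
        if runs and positions[i] - positions[runs[-1][-1]] <= max(track.hop, 1):
            runs[-1].append(i)
        else:
            runs.append([i])
    # merge runs closer than min_separation
    merged: list[list[int]] = []
    for run in runs:
        if merged and positions[run[0]] - positions[merged[-1][-1]] < min_separation:
            merged[-1].extend(run)
        else:
            merged.append(run)

    peaks = []
    regions = []
    half = track.window_length // 2
    for run in merged:
        run_idx = np.asarray(run)
        if min_width is not None and positions[run_idx[-1]] - positions[run_idx[0]] < min_width:
            continue
        best = run_idx[np.argmax(values[run_idx])]
        peaks.append((int(positions[best]), float(values[best])))
        regions.append(
            (max(1, int(positions[run_idx[0]]) - half), int(positions[run_idx[-1]]) + half)
        )
    return PredictedRegions(peaks=tuple(peaks), regions=tuple(regions), threshold_used=thr_used)


def confusion_counts(
    pred: PredictedRegions, truth: ExonAnnotation, slack: int = 0
) -> ConfusionCounts:
    """Exon-level confusion counts by peak containment.

    An annotated exon containing at least one predicted peak (within
    ``slack`` bases of its boundaries) is a true positive, counted once;
    exons with no peak are missed (Fn = Me); peaks inside no exon are false
    (Fp = We).
    """
    intervals = [(s - slack, e + slack) for s, e in truth.intervals]
    peak_pos = [p for p, _ in pred.peaks]
    hit = [False] * len(intervals)
    inside = 0
    for pos in peak_pos:
        matched = False
        for k, (s, e) in enumerate(intervals):
            if s <= pos <= e:
                hit[k] = True
                matched = True
        if matched:
            inside += 1
    Tp = sum(hit)
    Fn = len(intervals) - Tp
    Fp = len(peak_pos) - inside
    return ConfusionCounts(
        Tp=Tp, Fp=Fp, Fn=Fn, Me=Fn, Ae=len(intervals), We=Fp, Pe=len(peak_pos),
        peaks_in_exons=inside,
    )


def _rate(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def prediction_measures(counts: ConfusionCounts) -> PredictionMetrics:
    """Compute Sn, Sp, (Sn+Sp)/2, Mr, Wr from confusion counts.

    Rates with a zero denominator are reported as None (undefined) with a
    warning, never silently as 0.
    """
    Sn = _rate(counts.Tp, counts.Tp + counts.Fn, "Sn")
    Sp = _rate(counts.Tp, counts.Tp + counts.Fp, "Sp")
    avg = (Sn + Sp) / 2 if Sn is not None and Sp is not None else None
    Mr = _rate(counts.Me, counts.Ae, "Mr")
    Wr = _rate(counts.We, counts.Pe, "Wr")
    return PredictionMetrics(Sn=Sn, Sp=Sp, avg=avg, Mr=Mr, Wr=Wr, counts=counts)


def quality_factor(values, convention: str = "var_over_mean_sq") -> float:
    """Spectrum-spikiness quality factor.

    ``var_over_mean_sq`` (default): population variance divided by squared
    mean — zero for a constant spectrum, large for a spiky one.
    ``mean_sq_over_var`` is the reciprocal convention.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty series")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("quality factor requires a positive mean")
    var = v.var()  # population (1/L) variance
    if convention == "var_over_mean_sq":
        return float(var / mean**2)
    if convention == "mean_sq_over_var":
        if var == 0:
            raise ValueError("variance is zero; reciprocal convention undefined")
        return float(mean**2 / var)
    raise ValueError(f"unknown convention {convention!r}")


def percent_rise(qf_new: float, qf_baseline: float) -> float:
    """Percent increase of a quality factor over a baseline."""
    if qf_baseline <= 0:
        raise ValueError("baseline quality factor must be positive")
    return 100.0 * (qf_new - qf_baseline) / qf_baseline


# ---------------------------------------------------------------------------
# interval file I/O (BED is 0-based half-open; TSV is 1-based inclusive)

def read_intervals(path, source_id: str = "") -> ExonAnnotation:
    """Read exon intervals from BED (.bed) or a 1-based inclusive TSV.

    BED coordinates are converted to 1-based inclusive.  A TSV must have
    columns start/end (header optional, first two numeric columns used).
    """
    path = str(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return ExonAnnotation(intervals=(), source_id=source_id)
    if df.empty:
        return ExonAnnotation(intervals=(), source_id=source_id)
    # drop a header row if the numeric columns fail to parse
    if path.endswith(".bed"):
        chrom = df.iloc[0, 0]
        starts = df.iloc[:, 1].astype(int) + 1
        ends = df.iloc[:, 2].astype(int)
        sid = source_id or str(chrom)
    else:
        try:
            float(df.iloc[0, 0])
            body = df
        except ValueError:
            body = df.iloc[1:]
        starts = body.iloc[:, 0].astype(int)
        ends = body.iloc[:, 1].astype(int)
        sid = source_id
    ivals = tuple(sorted(zip(starts.tolist(), ends.tolist())))
    return ExonAnnotation(intervals=ivals, source_id=sid)


def write_bed(path, intervals, chrom: str, scores=None) -> None:
    """Write 1-based inclusive intervals as a BED file (0-based half-open)."""
    rows = []
    for k, (start, end) in enumerate(intervals):
        row = {"chrom": chrom, "start": start - 1, "end": end, "name": f"region_{k + 1}"}
        if scores is not None:
            row["score"] = scores[k]
        rows.append(row)
    cols = ["chrom", "start", "end", "name"] + (["score"] if scores is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", header=False, index=False)
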