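"""Histogram-thresholded epoch detection on normalized band-average traces.

The normalized band average of a sparse recording is baseline most of the
time: its histogram shows a Gaussian bulk (the baseline) with a right tail
contributed by oscillation events. The detector models the baseline as
mode + k*sigma, with sigma estimated from the left half-distribution only
(the right half is event-contaminated), marks suprathreshold runs, merges
runs separated by less than the merge gap, discards merged runs shorter than
the minimum duration, and reports the survivors as epoch events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .trace import SignalTrace
from .wavelet import (
    DEFAULT_ANALYSIS_FS,
    DEFAULT_WAVELET_CYCLES,
    FrequencyGrid,
    Scalogram,
    band_average,
    build_frequency_grid,
    cwt_morlet,
    normalize_segmentwise,
    resample_for_analysis,
)

__all__ = [
    "ThresholdModel",
    "EpochEvent",
    "EpochSet",
    "BandClassSpec",
    "DetectParams",
    "fit_baseline_threshold",
    "fit_segmentwise_thresholds",
    "segment_epochs",
    "detect_band",
    "pan_frequency_scan",
    "pool_class_events",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted baseline model of a normalized band trace: theta = mode + k*sigma."""

    mode: float
    sigma: float
    k: float
    threshold: float
    n_bins: int


@dataclass(frozen=True)
class EpochEvent:
    """One detected oscillation epoch, half-open interval [start_s, end_s)."""

    start_s: float
    end_s: float
    band: tuple[float, float] | None = None
    peak_norm: float = float("nan")
    channel: str = ""
    method: str = "wavelet"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EpochSet:
    """Detected epochs over one trace, sorted by onset, non-overlapping per band."""

    events: list[EpochEvent]
    duration_s: float

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def rate(self) -> float:
        """Epochs per second over the analyzed duration."""
        return len(self.events) / self.duration_s if self.duration_s > 0 else 0.0

    @property
    def mean_duration(self) -> float | None:
        """Mean event duration in seconds; None for an empty set."""
        if not self.events:
            return None
        return float(np.mean([e.duration_s for e in self.events]))


@dataclass(frozen=True)
class BandClassSpec:
    """Frequency classes for pooling: low 0.5-8 Hz, gamma 30-50 Hz by default."""

    low: tuple[float, float] = (0.5, 8.0)
    gamma: tuple[float, float] = (30.0, 50.0)

    def __post_init__(self) -> None:
        if not (self.low[0] < self.low[1] <= self.gamma[0] < self.gamma[1]):
            raise ValueError("class ranges must be ordered and disjoint")


@dataclass(frozen=True)
class DetectParams:
    """Tunables of the wavelet detection pipeline."""

    analysis_fs: float = DEFAULT_ANALYSIS_FS
    wavelet_cycles: float = DEFAULT_WAVELET_CYCLES
    grid_step_octaves: float = 0.25
    segment_s: float = 30.0
    n_bins: int = 200
    threshold_k: float = 3.0
    threshold_estimator: str = "robust"
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.5


_MAD_TO_SIGMA = 1.4826  # Gaussian consistency factor


def fit_baseline_threshold(
    values: np.ndarray, n_bins: int = 200, k: float = 3.0, estimator: str = "robust"
) -> ThresholdModel:
    """Fit the baseline Gaussian bulk of a normalized band trace; theta = mu + k*sigma.

    The default ``estimator='robust'`` locates the bulk by the median and its
    width by the MAD (scaled to Gaussian sigma) — both insensitive to the
    sparse right tail contributed by oscillation events, so the threshold
    tracks the upper edge of the baseline whether or not events are present.
    ``estimator='mode'`` instead uses the histogram mode (midpoint of the
    highest-count of ``n_bins`` equal bins on [0, 1], ties toward the lower
    bin) with sigma as the RMS deviation of values at or below the mode.
    The threshold is clipped to <= 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 samples to fit a baseline")
    if np.ptp(values) == 0:
        raise ValueError("degenerate baseline: constant trace")
    if estimator == "robust":
        mu = float(np.median(values))
        sigma = _MAD_TO_SIGMA * float(np.median(np.abs(values - mu)))
    elif estimator == "mode":
        counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
        i = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
        mu = 0.5 * (edges[i] + edges[i + 1])
        left = values[values <= mu]
        sigma = float(np.sqrt(np.mean((left - mu) ** 2))) if left.size else 0.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if sigma == 0:
        raise ValueError("degenerate baseline: no spread around the bulk")
    theta = min(mu + k * sigma, 1.0)
    return ThresholdModel(mode=float(mu), sigma=sigma, k=k, threshold=theta, n_bins=n_bins)


def fit_segmentwise_thresholds(
    values: np.ndarray,
    fs: float,
    segment_s: float = 30.0,
    n_bins: int = 200,
    k: float = 3.0,
    estimator: str = "robust",
) -> np.ndarray:
    """Per-sample threshold from a baseline fit within each normalization segment.

    Each 30 s segment is normalized by its own maximum, so its baseline level
    is segment-specific; fitting the Gaussian bulk per segment keeps the
    threshold matched to that level (a global fit on the pooled segments sees
    a bimodal mixture when only some segments contain events). Segments too
    short or too degenerate to fit reuse the preceding segment's threshold.
    """
    values = np.asarray(values, dtype=float)
    ns = max(1, int(round(segment_s * fs)))
    theta = np.empty_like(values)
    prev = 1.0
    for start in range(0, values.size, ns):
        seg = values[start : start + ns]
        try:
            prev = fit_baseline_threshold(seg, n_bins, k, estimator).threshold
        except ValueError:
            pass  # keep previous threshold for short/degenerate segments
        theta[start : start + ns] = prev
    return theta


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open sample index pairs [i, j)."""
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_and_filter(
    runs: list[tuple[int, int]], min_len: int, gap_len: int
) -> list[tuple[int, int]]:
    """Merge runs separated by gaps < gap_len, then drop runs shorter than min_len.

    Merging happens before the duration filter, so two sub-minimum runs close
    together can survive as one long epoch. Durations of exactly min_len are
    kept; gaps of exactly gap_len are not merged.
    """
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < gap_len:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return [(s, e) for s, e in merged if e - s >= min_len]


def segment_epochs(
    values: np.ndarray,
    fs: float,
    threshold: float | np.ndarray,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 0.5,
    band: tuple[float, float] | None = None,
    channel: str = "",
    method: str = "wavelet",
    t0: float = 0.0,
) -> EpochSet:
    """Suprathreshold runs -> merge across short gaps -> minimum-duration filter.

    ``threshold`` may be a scalar or a per-sample array (e.g. per-segment
    thresholds). Runs are found over the full trace, so events spanning
    normalization-segment boundaries are handled by the same gap rule as any
    others. Event bounds are half-open sample intervals converted to seconds.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.asarray(threshold) > 0):
        raise ValueError("threshold must be positive")
    min_len = int(round(min_duration_s * fs))
    gap_len = int(round(merge_gap_s * fs))
    runs = _merge_and_filter(_runs_above(values > threshold), min_len, gap_len)
    events = [
        EpochEvent(
            start_s=t0 + s / fs,
            end_s=t0 + e / fs,
            band=band,
            peak_norm=float(values[s:e].max()),
            channel=channel,
            method=method,
        )
        for s, e in runs
    ]
    return EpochSet(events, duration_s=values.size / fs)


def _octave_window(center_hz: float, width_octaves: float) -> tuple[float, float]:
    half = 2 ** (width_octaves / 2.0)
    return center_hz / half, center_hz * half


def detect_band(
    trace: SignalTrace,
    center_hz: float,
    width_octaves: float = 1.0,
    params: DetectParams | None = None,
    channel: str = "",
) -> EpochSet:
    """Full single-band pipeline: resample, Morlet transform, band average
    over the octave window around ``center_hz``, segmentwise normalization,
    histogram thresholding, and run segmentation."""
    p = params or DetectParams()
    f_lo, f_hi = _octave_window(center_hz, width_octaves)
    x = resample_for_analysis(trace, p.analysis_fs, f_max=f_hi)
    grid = build_frequency_grid(f_lo, f_hi, p.grid_step_octaves)
    scal = cwt_morlet(x, grid, p.wavelet_cycles)
    raw = band_average(scal, f_lo, f_hi)
    norm = normalize_segmentwise(raw, x.fs, p.segment_s, band=(f_lo, f_hi), t0=x.t0)
    theta = fit_segmentwise_thresholds(
        norm.values, x.fs, p.segment_s, p.n_bins, p.threshold_k, p.threshold_estimator
    )
    return segment_epochs(
        norm.values,
        x.fs,
        theta,
        p.min_duration_s,
        p.merge_gap_s,
        band=(f_lo, f_hi),
        channel=channel,
        t0=x.t0,
    )


def pan_frequency_scan(
    trace: SignalTrace,
    grid: FrequencyGrid | None = None,
    params: DetectParams | None = None,
    width_octaves: float = 1.0,
    channel: str = "",
) -> dict[float, EpochSet]:
    """Run the detector at every grid center using octave-wide bands.

    A single resample and wavelet transform over the full grid is reused for
    all bands; each band averages the grid columns falling inside its octave
    window. Returns one EpochSet per center.
    """
    p = params or DetectParams()
    grid = grid or build_frequency_grid(0.3, 64.0, p.grid_step_octaves)
    x = resample_for_analysis(trace, p.analysis_fs, f_max=float(grid.centers.max()))
    scal = cwt_morlet(x, grid, p.wavelet_cycles)
    out: dict[float, EpochSet] = {}
    for c in grid.centers:
        f_lo, f_hi = _octave_window(float(c), width_octaves)
        # clip the octave window to the grid so edge centers keep >= 1 column
        cols = (scal.freqs >= f_lo * (1 - 1e-9)) & (scal.freqs <= f_hi * (1 + 1e-9))
        if not np.any(cols):
            out[float(c)] = EpochSet([], duration_s=x.duration)
            continue
        raw = scal.magnitude[:, cols].mean(axis=1)
        norm = normalize_segmentwise(raw, x.fs, p.segment_s, band=(f_lo, f_hi), t0=x.t0)
        if np.ptp(norm.values) == 0:
            out[float(c)] = EpochSet([], duration_s=x.duration)
            continue
        theta = fit_segmentwise_thresholds(
            norm.values, x.fs, p.segment_s, p.n_bins, p.threshold_k, p.threshold_estimator
        )
        out[float(c)] = segment_epochs(
            norm.values,
            x.fs,
            theta,
            p.min_duration_s,
            p.merge_gap_s,
            band=(f_lo, f_hi),
            channel=channel,
            t0=x.t0,
        )
    return out


def pool_class_events(
    band_sets: Mapping[float, EpochSet],
    class_range: tuple[float, float],
    width_octaves: float = 1.0,
    min_duration_s: float = 0.5,
    channel: str = "",
    method: str = "wavelet",
) -> EpochSet:
    """Pool per-band events into one frequency class by time-interval union.

    Bands whose octave window intersects ``class_range`` contribute; one
    physical epoch detected in several adjacent bands is counted once (its
    intervals overlap and merge in the union). Pooled events are re-checked
    against the minimum duration.
    """
    lo, hi = class_range
    if not lo < hi:
        raise ValueError("invalid class range")
    duration = 0.0
    intervals: list[tuple[float, float]] = []
    for center, eset in band_sets.items():
        duration = max(duration, eset.duration_s)
        b_lo, b_hi = _octave_window(float(center), width_octaves)
        if b_hi < lo or b_lo > hi:
            continue
        intervals.extend((e.start_s, e.end_s) for e in eset.events)
    intervals.sort()
    pooled: list[tuple[float, float]] = []
    for s, e in intervals:
        if pooled and s <= pooled[-1][1]:
            pooled[-1] = (pooled[-1][0], max(pooled[-1][1], e))
        else:
            pooled.append((s, e))
    events = [
        EpochEvent(s, e, band=class_range, channel=channel, method=method)
        for s, e in pooled
        if e - s >= min_duration_s - 1e-9
    ]
    return EpochSet(events, duration_s=duration)
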