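"""Comparator analyses: averaged PSD, STFT detection, amplitude-envelope detection.

Three conventional approaches the wavelet detector is benchmarked against:

* segment-averaged power spectral density with a "distinct peak" test
  (good for sustained rhythms, blind to sparse brief epochs),
* a short-time Fourier transform spectrogram run through the same
  thresholding machinery as the wavelet path (temporally accurate but
  spectrally coarse at a 0.125 s window), and
* a sliding-RMS amplitude envelope against a multiple of the whole-trace RMS
  (fails below ~1.5x baseline amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .detect import EpochSet, fit_segmentwise_thresholds, segment_epochs
from .trace import SignalTrace
from .wavelet import (
    DEFAULT_ANALYSIS_FS,
    build_frequency_grid,
    cwt_morlet,
    normalize_segmentwise,
    resample_for_analysis,
)

__all__ = [
    "PsdCurve",
    "SpectrogramResult",
    "average_psd",
    "psd_peak_present",
    "stft_spectrogram",
    "stft_detect",
    "amplitude_envelope",
    "amplitude_detect",
    "spectral_spread",
    "wavelet_spread",
]


@dataclass
class PsdCurve:
    """Mean periodogram over fixed-length non-overlapping segments."""

    frequencies: np.ndarray
    power: np.ndarray  # density units: x^2 / Hz
    n_segments: int
    segment_s: float


@dataclass
class SpectrogramResult:
    """STFT magnitude, time x frequency."""

    magnitude: np.ndarray  # (n_times, n_freqs)
    times: np.ndarray
    frequencies: np.ndarray
    window_s: float
    overlap: float
    analysis_fs: float


def average_psd(trace: SignalTrace, segment_s: float = 10.0, window: str = "boxcar") -> PsdCurve:
    """Average the periodogram over consecutive non-overlapping segments.

    A 1,800 s recording with 10 s segments averages 180 periodograms at
    0.1 Hz resolution. Rectangular windows by default (a taper can be
    requested); density scaling, so a unit sinusoid integrates to ~1/2.
    """
    ns = int(round(segment_s * trace.fs))
    n_segments = trace.n_samples // ns
    if n_segments < 1:
        raise ValueError("trace shorter than one PSD segment")
    segs = trace.samples[: n_segments * ns].reshape(n_segments, ns)
    freqs, power = sps.periodogram(segs, fs=trace.fs, window=window, axis=1)
    return PsdCurve(freqs, power.mean(axis=0), n_segments, segment_s)


def psd_peak_present(
    psd: PsdCurve,
    f0: float,
    min_excess_db: float = 3.0,
    fit_range: tuple[float, float] = (0.5, 20.0),
    guard_octaves: float = 0.5,
) -> tuple[bool, float]:
    """Test for a distinct spectral peak at ``f0`` above the 1/f background.

    A straight line is fitted to log-power vs log-frequency over
    ``fit_range`` excluding a half-octave guard band around ``f0``; the
    excess is the mean dB elevation above that fit inside the guard band.
    """
    f = psd.frequencies
    half = 2 ** (guard_octaves / 2.0)
    band = (f >= f0 / half) & (f <= f0 * half)
    bg = (f >= fit_range[0]) & (f <= fit_range[1]) & ~band & (f > 0) & (psd.power > 0)
    if bg.sum() < 10:
        raise ValueError("insufficient background points for the spectral fit")
    if not np.any(band):
        raise ValueError("f0 outside the PSD frequency range")
    slope, intercept = np.polyfit(np.log10(f[bg]), np.log10(psd.power[bg]), 1)
    fit_db = 10 * (slope * np.log10(f[band]) + intercept)
    excess = float(np.mean(10 * np.log10(psd.power[band]) - fit_db))
    return excess >= min_excess_db, excess


def stft_spectrogram(
    trace: SignalTrace, window_s: float = 0.125, overlap: float = 0.5
) -> SpectrogramResult:
    """Magnitude spectrogram with the benchmark window (0.125 s, 50% overlap).

    At the 256 Hz analysis rate this is a 32-sample window with a 16-sample
    hop and 8 Hz frequency-bin spacing.
    """
    nperseg = int(round(window_s * trace.fs))
    if nperseg > trace.n_samples:
        raise ValueError("STFT window longer than the trace")
    noverlap = int(round(nperseg * overlap))
    freqs, times, Z = sps.spectrogram(
        trace.samples,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        mode="magnitude",
    )
    return SpectrogramResult(Z.T, times + trace.t0, freqs, window_s, overlap, trace.fs)


def spectral_spread(frequencies: np.ndarray, spectrum: np.ndarray) -> float:
    """Full width at half prominence (Hz) of the dominant spectral peak.

    Prominence is measured from the spectrum minimum; crossings are linearly
    interpolated in frequency, and a peak running into the spectrum edge uses
    the edge frequency as its bound.
    """
    f = np.asarray(frequencies, dtype=float)
    s = np.asarray(spectrum, dtype=float)
    if s.size < 2:
        raise ValueError("spectrum too short for a width estimate")
    i = int(np.argmax(s))
    half = 0.5 * (s[i] + s.min())

    def _cross(idx_range, reverse: bool) -> float:
        prev = i
        for j in idx_range:
            if s[j] < half:
                # interpolate between j and prev
                frac = (half - s[j]) / (s[prev] - s[j])
                return f[j] + frac * (f[prev] - f[j])
            prev = j
        return f[0] if reverse else f[-1]

    left = _cross(range(i - 1, -1, -1), reverse=True)
    right = _cross(range(i + 1, s.size), reverse=False)
    return float(right - left)


def stft_detect(
    trace: SignalTrace,
    band: tuple[float, float] = (2.0, 4.0),
    window_s: float = 0.125,
    overlap: float = 0.5,
    analysis_fs: float = DEFAULT_ANALYSIS_FS,
    segment_s: float = 30.0,
    n_bins: int = 200,
    threshold_k: float = 3.0,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 0.5,
    channel: str = "",
) -> tuple[EpochSet, float | None]:
    """STFT comparator: spectrogram band average through the shared
    thresholding machinery; also reports the spectral spread of detections.

    Frequency bins are selected when their +-df/2 extent intersects the band
    (at 8 Hz resolution a 2-4 Hz band is carried almost entirely by the DC
    bin). The spread is the full width at half prominence of the spectrogram
    averaged over detected epoch frames; None when nothing is detected.
    """
    x = resample_for_analysis(trace, analysis_fs, f_max=band[1])
    spec = stft_spectrogram(x, window_s, overlap)
    df = spec.frequencies[1] - spec.frequencies[0]
    cols = (spec.frequencies + df / 2 >= band[0]) & (spec.frequencies - df / 2 <= band[1])
    raw = spec.magnitude[:, cols].mean(axis=1)
    fs_frames = 1.0 / (spec.times[1] - spec.times[0])
    norm = normalize_segmentwise(raw, fs_frames, segment_s, band=band, t0=float(spec.times[0]))
    theta = fit_segmentwise_thresholds(norm.values, fs_frames, segment_s, n_bins, threshold_k)
    eset = segment_epochs(
        norm.values,
        fs_frames,
        theta,
        min_duration_s,
        merge_gap_s,
        band=band,
        channel=channel,
        method="stft",
        t0=float(spec.times[0]),
    )
    spread = None
    if eset.events:
        in_evt = np.zeros(spec.times.size, dtype=bool)
        for e in eset.events:
            in_evt |= (spec.times >= e.start_s) & (spec.times < e.end_s)
        spread = spectral_spread(spec.frequencies, spec.magnitude[in_evt].mean(axis=0))
    return eset, spread


def wavelet_spread(
    trace: SignalTrace,
    events: EpochSet,
    f_min: float = 0.5,
    f_max: float = 16.0,
    step_octaves: float = 0.25,
    analysis_fs: float = DEFAULT_ANALYSIS_FS,
    wavelet_cycles: float = 6.0,
) -> float | None:
    """Spectral spread of the Morlet scalogram averaged over detected epochs.

    The counterpart of the STFT spread measurement: the scalogram (computed
    over ``f_min``–``f_max``) is averaged over event time samples and the full
    width at half prominence of the resulting spectrum is interpolated on the
    grid. None when there are no events.
    """
    if not events.events:
        return None
    x = resample_for_analysis(trace, analysis_fs, f_max=f_max)
    grid = build_frequency_grid(f_min, f_max, step_octaves)
    scal = cwt_morlet(x, grid, wavelet_cycles)
    t = x.t0 + np.arange(x.n_samples) / x.fs
    in_evt = np.zeros(x.n_samples, dtype=bool)
    for e in events.events:
        in_evt |= (t >= e.start_s) & (t < e.end_s)
    if not np.any(in_evt):
        return None
    return spectral_spread(scal.freqs, scal.magnitude[in_evt].mean(axis=0))


def amplitude_envelope(trace: SignalTrace, smooth_s: float = 0.5) -> np.ndarray:
    """Sliding-window RMS envelope, length-preserving with truncated edges."""
    if smooth_s <= 0:
        raise ValueError("smooth_s must be positive")
    w = max(1, int(round(smooth_s * trace.fs)))
    sq = trace.samples**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    n = sq.size
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def amplitude_detect(
    trace: SignalTrace,
    k_amp: float = 1.25,
    smooth_s: float = 0.5,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 0.5,
    contour_hp_hz: float | None = 0.5,
    channel: str = "",
) -> EpochSet:
    """Amplitude comparator: envelope deflections above k_amp x whole-trace RMS.

    The whole-trace RMS stands for baseline noise; sustained envelope
    deflections above ``k_amp`` times it (with the shared duration and merge
    rules) mark epochs. Because 1/f noise carries large sub-0.5 Hz power, the
    raw envelope wanders with the baseline contour by as much as a moderate
    epoch raises it; deflections are therefore measured after removing
    content below ``contour_hp_hz`` (default 0.5 Hz, the lower edge of the
    low-frequency class; set None to disable and threshold the raw envelope).

    The default ``k_amp`` = 1.25 is a tuned constant that reproduces the
    known detection limit of this method: epochs at >= 1.5x baseline RMS are
    caught (in-epoch envelope ~ sqrt(1 + 1.5^2/2) ~ 1.46x), epochs at <= 1x
    are not (~ 1.22x).
    """
    rms = trace.rms()
    if rms == 0:
        raise ValueError("degenerate trace: zero RMS")
    if contour_hp_hz is not None and contour_hp_hz > 0:
        sos = sps.butter(4, contour_hp_hz, btype="highpass", fs=trace.fs, output="sos")
        filtered = SignalTrace(
            sps.sosfiltfilt(sos, trace.samples), trace.fs, t0=trace.t0, label=trace.label
        )
    else:
        filtered = trace
    env = amplitude_envelope(filtered, smooth_s)
    eset = segment_epochs(
        env / rms,
        trace.fs,
        k_amp,
        min_duration_s,
        merge_gap_s,
        band=None,
        channel=channel,
        method="amplitude",
        t0=trace.t0,
    )
    return eset
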