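"""Scoring, rates, the low:high frequency ratio, condition statistics, and PAC.

Downstream quantification: detections are scored against simulation ground
truth by greedy one-to-one interval matching; epoch sets reduce to rates
(epochs/s) and mean durations; low- and gamma-class counts combine into the
low:high frequency ratio (LHR); condition contrasts report percent change,
Cohen's d, paired t, Wilcoxon signed-rank, and Welch tests; and
cross-frequency phase-amplitude coupling is quantified with the phase-binned
Kullback-Leibler modulation index against time-shift surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .detect import EpochSet
from .simulate import GroundTruthEpoch
from .trace import SignalTrace

__all__ = [
    "DetectionScore",
    "LHRResult",
    "PACResult",
    "ConditionComparison",
    "score_detection",
    "epoch_stats",
    "lhr",
    "cohens_d",
    "cohens_d_groups",
    "compare_conditions",
    "time_course",
    "phase_amplitude_coupling",
]


@dataclass(frozen=True)
class DetectionScore:
    """Confusion counts of detected vs ground-truth epochs (TP + FN = n_truth)."""

    n_truth: int
    tp: int
    fp: int
    fn: int
    sensitivity: float
    fp_per_min: float


@dataclass(frozen=True)
class LHRResult:
    """Low:high frequency epoch-number ratio; undefined when high count is 0."""

    low_count: int
    high_count: int
    ratio: float
    undefined: bool


@dataclass
class PACResult:
    """Phase-amplitude coupling summary (KL-based modulation index).

    Whole-trace MI, preferred phase and surrogate p, plus per-segment MI,
    p-values and modulation flags (p < alpha), and the fraction of modulated
    segments.
    """

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    mi: float
    preferred_phase: float
    p_value: float
    segment_mi: list[float] = field(default_factory=list)
    segment_p: list[float] = field(default_factory=list)
    segment_preferred_phase: list[float] = field(default_factory=list)
    modulated: list[bool] = field(default_factory=list)
    fraction_modulated: float = 0.0


@dataclass(frozen=True)
class ConditionComparison:
    """Paired condition contrast (rates in A vs B) with effect size and tests."""

    mean_a: float
    mean_b: float
    percent_change: float
    cohens_d: float
    t_stat: float
    t_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    welch_stat: float
    welch_p: float


def score_detection(
    detected: EpochSet,
    truth: Sequence[GroundTruthEpoch],
    min_overlap_s: float = 0.0,
) -> DetectionScore:
    """Greedy one-to-one matching of detections to truth intervals by onset.

    A detection is a true positive if it overlaps an as-yet-unmatched truth
    interval by more than ``min_overlap_s`` (default: any positive overlap,
    i.e. at least one analysis sample). A detection spanning two truths
    matches only one; the other counts as a miss.
    """
    dets = sorted(detected.events, key=lambda e: e.start_s)
    truths = sorted(truth, key=lambda g: g.onset_s)
    matched = [False] * len(truths)
    tp = 0
    for d in dets:
        for i, g in enumerate(truths):
            if matched[i]:
                continue
            if g.onset_s >= d.end_s:
                break
            overlap = min(d.end_s, g.offset_s) - max(d.start_s, g.onset_s)
            if overlap > min_overlap_s:
                matched[i] = True
                tp += 1
                break
    fp = len(dets) - tp
    fn = len(truths) - tp
    sens = tp / len(truths) if truths else float("nan")
    fp_per_min = fp / (detected.duration_s / 60.0) if detected.duration_s > 0 else float("nan")
    return DetectionScore(len(truths), tp, fp, fn, sens, fp_per_min)


def epoch_stats(eset: EpochSet) -> tuple[float, float | None]:
    """(rate in epochs/s, mean duration in s; None for an empty set)."""
    if eset.duration_s <= 0:
        raise ValueError("epoch set has non-positive duration")
    return eset.rate, eset.mean_duration


def lhr(low: EpochSet, high: EpochSet) -> LHRResult:
    """Low:high frequency epoch-number ratio."""
    nl, nh = len(low), len(high)
    if nh == 0:
        return LHRResult(nl, nh, float("nan"), True)
    return LHRResult(nl, nh, nl / nh, False)


def cohens_d(mean_diff: float, sd_pooled: float) -> float:
    """|difference of means| / pooled standard deviation."""
    if sd_pooled <= 0:
        raise ValueError("pooled SD must be positive")
    return abs(mean_diff) / sd_pooled


def cohens_d_groups(
    samples_a: Sequence[float], samples_b: Sequence[float], pooling: str = "independent"
) -> float:
    """Cohen's d from raw samples.

    ``pooling='independent'`` uses the Bessel-weighted pooled SD
    sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2)); ``pooling='paired'`` uses the
    two-variance mean form sqrt((s1^2 + s2^2)/2).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    if pooling == "independent":
        n1, n2 = a.size, b.size
        sd = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    elif pooling == "paired":
        sd = math.sqrt((s1**2 + s2**2) / 2.0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return cohens_d(float(a.mean() - b.mean()), sd)


def compare_conditions(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> ConditionComparison:
    """Paired contrast of per-unit rates between two conditions.

    Reports percent change 100*(B-A)/A, Cohen's d with paired pooling, the
    paired t-test, the Wilcoxon signed-rank test, and Welch's unequal-variance
    t-test (the independent-groups companion).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 paired observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else float("nan")
    if np.allclose(a, b):
        d = 0.0
    else:
        try:
            d = cohens_d_groups(a, b, pooling="paired")
        except ValueError:  # zero within-condition variance
            d = float("nan")
    t_stat, t_p = stats.ttest_rel(a, b)
    try:
        w_stat, w_p = stats.wilcoxon(a, b)
    except ValueError:  # all differences zero
        w_stat, w_p = 0.0, 1.0
    welch_stat, welch_p = stats.ttest_ind(a, b, equal_var=False)
    return ConditionComparison(
        mean_a,
        mean_b,
        pct,
        float(d),
        float(t_stat),
        float(t_p),
        float(w_stat),
        float(w_p),
        float(welch_stat),
        float(welch_p),
    )


def time_course(
    event_times: Sequence[float], duration_s: float, bin_s: float = 600.0
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch rate per consecutive time bin (default 10-minute bins).

    Returns (bin start times, rates in epochs/s); a partial final bin is
    normalized by its actual length.
    """
    if bin_s <= 0 or duration_s <= 0:
        raise ValueError("bin_s and duration_s must be positive")
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    edges[-1] = min(edges[-1], duration_s) if edges[-1] > duration_s else edges[-1]
    if edges[-1] < duration_s:
        edges = np.append(edges, duration_s)
    edges = np.unique(edges)
    counts, _ = np.histogram(np.asarray(event_times, dtype=float), bins=edges)
    widths = np.diff(edges)
    return edges[:-1], counts / widths


def _octave_band(center_hz: float, width_octaves: float) -> tuple[float, float]:
    half = 2 ** (width_octaves / 2.0)
    return center_hz / half, center_hz * half


def _kl_modulation_index(phase: np.ndarray, amp: np.ndarray, n_bins: int) -> float:
    """Tort-style KL-based modulation index of the phase-binned amplitude mean."""
    bins = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    m = np.bincount(bins, weights=amp, minlength=n_bins)
    c = np.bincount(bins, minlength=n_bins)
    mean_amp = np.where(c > 0, m / np.maximum(c, 1), 0.0)
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    p = mean_amp / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float((math.log(n_bins) - entropy) / math.log(n_bins))


def phase_amplitude_coupling(
    slow_trace: SignalTrace,
    fast_trace: SignalTrace,
    phase_center_hz: float = 1.5,
    amp_center_hz: float = 3.0,
    width_octaves: float = 1.0,
    segment_s: float = 30.0,
    n_bins: int = 18,
    n_surrogates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> PACResult:
    """Cross-frequency coupling of a slow rhythm's phase with a fast rhythm's
    amplitude (e.g. thalamic 1.5 Hz phase vs cortical 3 Hz amplitude).

    Both traces are band-passed to octave-wide bands around their centers;
    the slow signal's instantaneous phase and the fast signal's amplitude
    envelope come from the analytic signal. Coupling per 30 s segment is the
    18-bin KL modulation index; significance comes from circular time-shift
    surrogates of the amplitude series; the preferred phase is the
    amplitude-weighted circular mean. The whole-trace statistics use the same
    procedure over the full series.
    """
    if slow_trace.fs != fast_trace.fs or slow_trace.n_samples != fast_trace.n_samples:
        raise ValueError("traces must be time-aligned with identical fs and length")
    fs = slow_trace.fs
    if segment_s < 3.0 / phase_center_hz:
        raise ValueError("segment shorter than 3 cycles of the phase frequency")

    def _bandpass(x: np.ndarray, center: float) -> np.ndarray:
        lo, hi = _octave_band(center, width_octaves)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x)

    slow_f = _bandpass(slow_trace.samples, phase_center_hz)
    fast_f = _bandpass(fast_trace.samples, amp_center_hz)
    phase = np.angle(sps.hilbert(slow_f))
    amp = np.abs(sps.hilbert(fast_f))
    if np.max(amp) == 0:
        raise ValueError("degenerate amplitude: fast trace has zero envelope")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def _mi_p_phase(ph: np.ndarray, am: np.ndarray) -> tuple[float, float, float]:
        mi = _kl_modulation_index(ph, am, n_bins)
        n = am.size
        lo, hi = max(1, n // 10), max(2, 9 * n // 10)
        shifts = rng.integers(lo, hi, size=n_surrogates)
        exceed = sum(
            _kl_modulation_index(ph, np.roll(am, int(s)), n_bins) >= mi for s in shifts
        )
        p = (1 + exceed) / (1 + n_surrogates)
        pref = float(np.angle(np.sum(am * np.exp(1j * ph))))
        return mi, p, pref

    mi_all, p_all, pref_all = _mi_p_phase(phase, amp)

    ns = int(round(segment_s * fs))
    n_segments = slow_trace.n_samples // ns
    seg_mi: list[float] = []
    seg_p: list[float] = []
    seg_pref: list[float] = []
    flags: list[bool] = []
    for k in range(n_segments):
        sl = slice(k * ns, (k + 1) * ns)
        mi, p, pref = _mi_p_phase(phase[sl], amp[sl])
        seg_mi.append(mi)
        seg_p.append(p)
        seg_pref.append(pref)
        flags.append(p < alpha)
    frac = float(np.mean(flags)) if flags else 0.0
    return PACResult(
        phase_band=_octave_band(phase_center_hz, width_octaves),
        amp_band=_octave_band(amp_center_hz, width_octaves),
        mi=mi_all,
        preferred_phase=pref_all,
        p_value=p_all,
        segment_mi=seg_mi,
        segment_p=seg_p,
        segment_preferred_phase=seg_pref,
        modulated=flags,
        fraction_modulated=frac,
    )
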