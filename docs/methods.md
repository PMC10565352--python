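# Methods

## Synthetic benchmark

The generator emulates the statistical skeleton of a band-limited
(0.1–300 Hz) extracellular LFP recording: stationary 1/f-distributed
baseline noise with sparse, brief, band-limited oscillation epochs added on
top. Defaults are the benchmark conditions: 600 s at 12.5 kHz, unit noise
RMS, twenty 2 s epochs of a 3 Hz sinusoid, peak amplitudes swept over
{2, 1, 0.5, 0.25, 0.125, 0.0625, 0.03125}× the noise RMS.

**1/f noise.** Gaussian white noise is filtered through a linear-phase FIR
whose amplitude response is f^(−α/2) (power ∝ 1/f^α, α = 1 by default),
specified on a log-spaced grid from 0.1 Hz to Nyquist and held flat below
0.1 Hz to avoid DC blow-up; a Kaiser(9) window keeps leakage from the
high-gain low-frequency region out of the upper band. The filter impulse
response is 5 s long (62,501 taps at 12.5 kHz) — length in *seconds*, not
taps, because the spectral resolution of the shaping is ~1/length Hz and the
power law must be rendered down to ~1 Hz for the slope check (a fixed
4,097-tap filter at 12.5 kHz would smear everything below ~3 Hz). The
start-up transient is excluded ('valid' convolution over an over-generated
white sequence) and the stationary output is rescaled so its RMS equals the
requested value exactly. Verified property: least-squares slope of
log₁₀ PSD vs log₁₀ f over 1–100 Hz = −1.0 ± 0.1.

**Epochs.** Plain sinusoidal segments (no taper; onsets/offsets are abrupt),
peak amplitude a × noise RMS, each with an independent uniform random phase
(phase coherence between nearby epochs would otherwise be an artifact; a
fixed-zero-phase mode exists). Onsets are drawn uniformly over
[0, T − d]; overlaps are allowed by default, and the non-overlap mode uses
the exact slack-space construction (sorted uniforms in [0, T − n·d] shifted
by i·d) rather than rejection sampling. Embedding is strictly additive, so
trace − noise vanishes outside the truth intervals — the contract the scorer
relies on. All randomness derives from one seed via three split substreams
(noise, placements, phases), so an amplitude sweep with a shared seed reuses
identical noise and epoch positions across amplitudes (paired comparisons).

**SNR convention.** Empirical SNR = 10·log₁₀(mean power of the epoch
component over the full trace / mean power of the noise component). The
closed form for unit-RMS noise and no overlaps is
10·log₁₀((a²/2)·n·d/T): −8.75 dB (≈ −9 dB) at a = 2 and −20.8 dB at
a = 0.5, matching the empirical value within 0.3 dB. No single convention
reproduces all three published operating-point figures (−9, −20.9,
−11.7 dB); the first two agree with this convention to ~0.1 dB and the
third (1.5×; closed form −11.25 dB) is treated as an empirical value of a
particular realization, not a target.

## Wavelet detection

**Analysis rate.** Recordings are decimated to 256 Hz (zero-phase order-8
Butterworth at 0.35 × 256 ≈ 90 Hz, then polyphase resampling). All analysis
content is ≤ 64 Hz; 256 Hz keeps a 600 s × 31-frequency transform small, and
makes the 0.125 s STFT window exactly 32 samples. In-band amplitudes are
preserved within 1%; content at the new Nyquist and above is attenuated by
more than 40 dB.

**Transform.** Complex Morlet with ω₀ = 6 cycles (the standard
time/frequency compromise; configurable), evaluated at 31 geometric centers
0.3·2^(k/4) Hz, k = 0…30. The transform is computed by frequency-domain
multiplication over the *full* trace with reflection padding of one wavelet
support per end: at 0.3 Hz the wavelet support (~13 s each side) is
comparable to a 30 s segment, so per-segment transforms would be
edge-dominated. The wavelet's frequency response is scaled to peak at 2 on
the analytic half, so a unit-amplitude sinusoid at a center frequency has
magnitude ≈ 1 in its column and magnitude is linear in input amplitude.

**Band average and normalization.** Detection operates on octave-wide bins
centered on grid points (the window [c/√2, c·√2] averaged across the grid
columns it contains). Each 30 s segment of the band average is divided by
its own maximum (a 99.9th-percentile alternative for artifact-heavy real
data can be obtained by pre-clipping; the maximum is the default).

**Threshold.** θ = μ + kσ with k = 3, clipped to ≤ 1, where (μ, σ) describe
the Gaussian bulk of the normalized band magnitude — baseline — and are
fitted **per 30 s segment** using the median and the MAD (scaled by 1.4826).
Two operationalizations were evaluated for locating the bulk:

* a global histogram fit (200 bins, mode = highest-count bin, σ from the
  RMS deviation below the mode) is unstable on this statistic: the
  normalized pure-noise distribution is right-skewed with a flat plateau at
  its peak, so the argmax-bin mode jitters by ±0.06 and the left-sided σ
  underestimates the bulk's right extent, producing threshold swings between
  ~0.7 (false-positive storms) and 1.0. It is retained as
  `estimator="mode"` for comparison.
* the default per-segment median/MAD fit. Each segment is normalized by its
  own maximum, so its baseline level is segment-specific; fitting per
  segment keeps θ matched to that level, and median/MAD ignore the sparse
  right tail contributed by events. On pure noise, θ rises to ~1 (nothing
  to detect); in segments containing epochs the compressed baseline pulls
  θ down and the epochs stand clear of it. This self-scaling is what lets
  the same k = 3 rule produce ≤ 2 false events per 10 min on pure noise
  *and* ≥ 18/20 recovery at 2× amplitude — no fixed threshold does both.

**Segmentation.** Suprathreshold runs are merged when separated by less
than 0.5 s (merging first), then runs shorter than 0.5 s are discarded;
a run of exactly 0.5 s is kept, a gap of exactly 0.5 s is not merged.
Intervals are half-open in seconds. Runs are found over the full trace, so
events spanning segment boundaries obey the same gap rule. Pan-frequency
scanning reuses one resample + transform across all 31 bins; class pooling
(low 0.5–8 Hz, gamma 30–50 Hz) unions the event intervals of every bin whose
octave window intersects the class range, so one physical epoch detected in
several adjacent bins counts once. Per-bin counts are reported without
deduplication.

## Comparator methods

**Averaged PSD.** Non-overlapping rectangular-window periodograms of 10 s
segments, averaged (180 segments for a 1,800 s recording); density scaling,
so a unit sinusoid integrates to ~1/2. The "distinct peak" judgment the
original analysis made by eye is operationalized as: fit a line to
log-power vs log-frequency over 0.5–20 Hz excluding a half-octave guard band
around the probe frequency; the peak excess is the mean dB elevation above
the fit inside the guard band, flagged at ≥ 3 dB. On the benchmark this
yields ~5 dB at 2× epochs and ~0.8 dB at 0.5× — a clean separation around
the default.

**STFT.** Magnitude spectrogram with a 0.125 s Hann window and 50% overlap
(32-sample window, 16-sample hop, 8 Hz bins at 256 Hz). Detection reuses the
wavelet path's segmentwise normalization and thresholding so the method
comparison isolates the time-frequency representation, not the
post-processing. The spectral spread of detections — full width at half
prominence of the spectrogram averaged over detected frames — is ~8–16 Hz,
versus ~1–2 Hz for the wavelet scalogram of the same epochs.

**Amplitude envelope.** Sliding-RMS envelope (0.5 s window, truncated
edges), thresholded at k_amp × the whole-trace RMS with the shared
duration/merge rules. Because 1/f noise carries large sub-0.5 Hz power, the
raw envelope wanders with the slow baseline contour by as much as a moderate
epoch elevates it (99th percentile ≈ 1.65× RMS, versus ≈ 1.46× inside a 1.5×
epoch); deflections are therefore measured after removing content below
0.5 Hz — the lower edge of the low-frequency class (configurable;
`contour_hp_hz=None` restores the raw envelope). k_amp = 1.25 is a tuned
constant chosen so the method's known detection limit is reproduced: epochs
at ≥ 1.5× baseline RMS are caught, epochs at ≤ 1× are not, and 0.5× epochs
are never recovered.

## Scoring and downstream metrics

Detections are matched to truth intervals greedily, one-to-one, in onset
order, with any positive overlap counting (a ≥ 50%-overlap rule can be had
by raising `min_overlap_s`). A detection spanning two truths matches one and
the other counts as a miss; with uniformly random placement ~1.6 truth pairs
per realization fall < 0.5 s apart and merge into a single detection, which
caps mean recovery near 18.4/20 even for a perfect detector and makes
recovery dip slightly (≲ 0.5 epochs) at the highest amplitudes as detections
widen. Rates are epochs/s; LHR is the ratio of pooled low-class to
gamma-class counts, per recording, flagged undefined when the gamma count is
zero (per-recording ratios are averaged across slices; pooled-count LHR can
be formed from the counts directly). Cohen's d uses Bessel-weighted pooling
for independent groups and the two-variance mean form for paired designs.
Time courses bin event rates in 10-minute bins, the final partial bin
normalized by its actual length.

**Phase-amplitude coupling.** Both channels are band-passed to octave-wide
bands (order-4 zero-phase Butterworth) around the phase center (default
1.5 Hz) and amplitude center (default 3 Hz); phase and envelope come from
the analytic signal. Coupling per 30 s segment is the Kullback–Leibler
modulation index of the 18-bin phase-binned mean amplitude; significance is
the rank of the observed index among 200 circular time-shift surrogates of
the amplitude series (shift uniform in the middle 80% of the segment,
p = (1+exceed)/(1+N)); the preferred phase is the amplitude-weighted
circular mean. A segment must contain at least 3 cycles of the phase
frequency. Note that time-shift surrogates are only meaningful for rhythms
with phase diffusion: for a strictly periodic deterministic carrier every
circular shift preserves the coupling and p ≈ 1 by construction, so
validation constructs use a noisy band-limited carrier.

## Problem sizes used in the tests

Detector benchmarks simulate at 1.25 kHz (600 s, seeds 0–9, shared noise
across the amplitude sweep): the analysis never looks above 64 Hz, so
simulating below the 12.5 kHz hardware rate changes nothing but the
decimation ratio; SNR targets and simulator-fidelity checks run at the full
12.5 kHz. Statistics quoted from the benchmark are means over the ten-seed
panel.

## Known limitations

* The per-segment maximum normalization guarantees each segment touches 1,
  so false-positive behavior depends on the band's envelope statistics. At
  the validated low-frequency bins (2–4 Hz) the pure-noise rate is
  ≤ 2 events/10 min; at higher centers (> 20 Hz), where envelope
  excursions are numerous and closely spaced, the merge rule can chain
  noise excursions and per-bin false-positive rates are higher. Class-level
  comparisons on synthetic data are differential and unaffected, but
  absolute per-bin counts above ~20 Hz should be interpreted against a
  noise floor measured on matched noise.
* The generator emulates stationary noise with identical, abruptly gated
  sinusoidal epochs. Real slice recordings add nonstationary baselines,
  electrode artifacts, line noise, variable epoch morphology and amplitude;
  passing the synthetic benchmark demonstrates detector calibration and
  ordering, not field performance on artifact-heavy data.
* EDF files are read (via MNE) but not written; the HDF5 layout
  (`/signal` channels × samples, `/channel_labels`, attrs `fs_hz`,
  `units`) and CSV are the native round-trip formats.
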