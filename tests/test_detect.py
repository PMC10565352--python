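"""Detector: baseline threshold fitting, run segmentation, merging, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpwave import (
    DetectParams,
    EpochEvent,
    EpochSet,
    SignalTrace,
    build_frequency_grid,
    detect_band,
    fit_baseline_threshold,
    fit_segmentwise_thresholds,
    pan_frequency_scan,
    pool_class_events,
    segment_epochs,
)


class TestBaselineThreshold:
    @pytest.mark.parametrize("estimator", ["robust", "mode"])
    def test_gaussian_parameter_recovery(self, estimator):
        rng = np.random.default_rng(42)
        v = np.clip(rng.normal(0.3, 0.05, 200_000), 0, 1)
        m = fit_baseline_threshold(v, estimator=estimator)
        assert m.mode == pytest.approx(0.3, abs=0.01)
        assert m.sigma == pytest.approx(0.05, abs=0.005)
        assert m.threshold == pytest.approx(0.3 + 3 * 0.05, abs=0.02)

    def test_gaussian_exceedance_bounded(self):
        rng = np.random.default_rng(7)
        v = np.clip(rng.normal(0.3, 0.05, 200_000), 0, 1)
        m = fit_baseline_threshold(v)
        assert np.mean(v > m.threshold) <= 0.005

    def test_threshold_clipped_to_one(self):
        rng = np.random.default_rng(3)
        v = np.clip(rng.normal(0.9, 0.2, 10_000), 0, 1)
        assert fit_baseline_threshold(v).threshold <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline_threshold(np.full(1000, 0.5))
        with pytest.raises(ValueError):
            fit_baseline_threshold(np.random.default_rng(0).random(50))

    def test_segmentwise_adapts_per_segment(self):
        # two segments with very different baseline levels get different thetas
        rng = np.random.default_rng(5)
        seg1 = np.clip(rng.normal(0.2, 0.04, 3000), 0, 1)
        seg2 = np.clip(rng.normal(0.6, 0.1, 3000), 0, 1)
        theta = fit_segmentwise_thresholds(np.concatenate([seg1, seg2]), fs=100.0, segment_s=30.0)
        assert theta[0] == pytest.approx(0.32, abs=0.03)
        assert theta[-1] == pytest.approx(0.9, abs=0.06)


def _naive_segment(values, fs, theta, min_dur, gap):
    """Independent exhaustive run-length oracle for segment_epochs."""
    above = [v > theta for v in values]
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) / fs < gap - 1e-12:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    kept = [r for r in merged if (r[1] - r[0]) / fs >= min_dur - 1e-12]
    return [(r[0] / fs, r[1] / fs) for r in kept]


class TestSegmentEpochs:
    def test_sub_minimum_run_dropped(self):
        fs = 100.0
        v = np.zeros(1000)
        v[100:140] = 1.0  # 0.4 s
        assert len(segment_epochs(v, fs, 0.5)) == 0

    def test_runs_with_short_gap_merged(self):
        fs = 100.0
        v = np.zeros(2000)
        v[1000:1070] = 1.0  # 10.0-10.7 s
        v[1100:1160] = 1.0  # 11.0-11.6 s, gap 0.3 s
        es = segment_epochs(v, fs, 0.5)
        assert len(es) == 1
        assert es.events[0].start_s == pytest.approx(10.0)
        assert es.events[0].end_s == pytest.approx(11.6)

    def test_exact_minimum_duration_kept(self):
        fs = 100.0
        v = np.zeros(1000)
        v[200:250] = 1.0  # exactly 0.5 s
        assert len(segment_epochs(v, fs, 0.5)) == 1

    def test_exact_merge_gap_not_merged(self):
        fs = 100.0
        v = np.zeros(2000)
        v[100:160] = 1.0
        v[210:270] = 1.0  # gap exactly 0.5 s
        assert len(segment_epochs(v, fs, 0.5)) == 2

    def test_two_short_runs_survive_as_one(self):
        # merging precedes the duration filter
        fs = 100.0
        v = np.zeros(1000)
        v[100:130] = 1.0  # 0.3 s
        v[150:180] = 1.0  # 0.3 s, gap 0.2 s
        es = segment_epochs(v, fs, 0.5)
        assert len(es) == 1
        assert es.events[0].duration_s == pytest.approx(0.8)

    def test_per_sample_threshold_array(self):
        fs = 100.0
        v = np.full(1000, 0.6)
        v[:100] = 0.0
        theta = np.full(1000, 0.5)
        theta[500:] = 0.7  # second half suprathreshold only under the low theta
        es = segment_epochs(v, fs, theta)
        assert len(es) == 1
        assert es.events[0].end_s == pytest.approx(5.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 1, width=16, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.05, 0.95),
    )
    def test_matches_exhaustive_oracle(self, values, theta):
        fs = 10.0
        es = segment_epochs(np.array(values), fs, theta, 0.5, 0.5)
        expected = _naive_segment(values, fs, theta, 0.5, 0.5)
        assert [(e.start_s, e.end_s) for e in es.events] == [
            (pytest.approx(s), pytest.approx(t)) for s, t in expected
        ]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, width=16, allow_nan=False), min_size=1, max_size=80))
    def test_duration_and_gap_invariants(self, values):
        fs = 10.0
        es = segment_epochs(np.array(values), fs, 0.5, 0.5, 0.5)
        events = es.events
        for e in events:
            assert e.duration_s >= 0.5 - 1e-9
        for a, b in zip(events, events[1:]):
            assert b.start_s - a.end_s >= 0.5 - 1e-9


class TestDetectBand:
    def test_zero_trace_pan_scan_empty(self):
        x = SignalTrace(np.zeros(int(120 * 256.0)), 256.0)
        sets = pan_frequency_scan(x)
        assert len(sets) == 31
        assert all(len(s) == 0 for s in sets.values())

    def test_benchmark_recovery_single_seed(self, small_spec, small_noise):
        from lfpwave import embed_epochs, score_detection

        trace, truth = embed_epochs(small_noise, 3.0, 2.0, 2.0, 1.0, 20, small_spec.seed)
        es = detect_band(trace, center_hz=np.sqrt(8.0))  # 2-4 Hz octave band
        sc = score_detection(es, truth)
        assert sc.tp >= 18

    def test_pure_noise_few_events(self, small_noise):
        es = detect_band(small_noise, center_hz=np.sqrt(8.0))
        assert len(es) <= 3


class TestPoolClassEvents:
    @staticmethod
    def _set(events, duration=600.0):
        return EpochSet(list(events), duration)

    def test_same_event_in_adjacent_bands_counted_once(self):
        e = EpochEvent(10.0, 12.0)
        sets = {2.38: self._set([e]), 2.83: self._set([e]), 3.36: self._set([e])}
        pooled = pool_class_events(sets, (0.5, 8.0))
        assert len(pooled) == 1
        assert pooled.events[0].start_s == 10.0

    def test_disjoint_events_kept_separate(self):
        sets = {
            2.83: self._set([EpochEvent(10.0, 12.0)]),
            4.0: self._set([EpochEvent(20.0, 21.0)]),
        }
        assert len(pool_class_events(sets, (0.5, 8.0))) == 2

    def test_out_of_class_band_excluded(self):
        sets = {40.0: self._set([EpochEvent(10.0, 12.0)])}
        assert len(pool_class_events(sets, (0.5, 8.0))) == 0
        assert len(pool_class_events(sets, (30.0, 50.0))) == 1

    def test_empty_inputs(self):
        assert len(pool_class_events({}, (0.5, 8.0))) == 0
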