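"""Scoring, rates, LHR, effect sizes, condition statistics, and PAC."""

import numpy as np
import pytest
from scipy import signal as sps

from lfpwave import (
    EpochEvent,
    EpochSet,
    GroundTruthEpoch,
    SignalTrace,
    cohens_d,
    cohens_d_groups,
    compare_conditions,
    epoch_stats,
    lhr,
    phase_amplitude_coupling,
    score_detection,
    time_course,
)
from conftest import pink_trace


def _eset(intervals, duration=600.0):
    return EpochSet([EpochEvent(s, e) for s, e in intervals], duration)


def _truth(intervals):
    return [GroundTruthEpoch(s, e, 3.0, 2.0) for s, e in intervals]


class TestScoreDetection:
    def test_perfect_cover(self):
        iv = [(10 * k, 10 * k + 2) for k in range(1, 21)]
        sc = score_detection(_eset(iv), _truth(iv))
        assert (sc.tp, sc.fp, sc.fn, sc.sensitivity) == (20, 0, 0, 1.0)

    def test_no_detections(self):
        sc = score_detection(_eset([]), _truth([(10, 12), (20, 22)]))
        assert (sc.tp, sc.fn, sc.sensitivity) == (0, 2, 0.0)

    def test_one_detection_spanning_two_truths(self):
        sc = score_detection(_eset([(9.0, 14.0)]), _truth([(10, 12), (12.5, 13.5)]))
        assert (sc.tp, sc.fn, sc.fp) == (1, 1, 0)

    def test_bookkeeping_identity_random_cases(self):
        # TP + FN = n_truth; every match implies real overlap (interval oracle)
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_d, n_t = rng.integers(0, 15), rng.integers(1, 15)
            dets = sorted(rng.uniform(0, 580, n_d))
            truths = sorted(rng.uniform(0, 580, n_t))
            d = _eset([(s, s + rng.uniform(0.5, 5)) for s in dets])
            t = _truth([(s, s + 2.0) for s in truths])
            sc = score_detection(d, t)
            assert sc.tp + sc.fn == sc.n_truth == n_t
            assert sc.tp + sc.fp == n_d
            assert 0 <= sc.sensitivity <= 1
            # TP can never exceed the exhaustive count of truths overlapped
            overlapped = sum(
                any(min(e.end_s, g.offset_s) - max(e.start_s, g.onset_s) > 0 for e in d.events)
                for g in t
            )
            assert sc.tp <= overlapped


class TestEpochStats:
    def test_rate_and_mean_duration(self):
        es = _eset([(0, 1.5), (10, 12.5)], duration=600.0)
        rate, dur = epoch_stats(es)
        assert rate == pytest.approx(2 / 600)
        assert dur == pytest.approx(2.0)

    def test_18_epochs_in_600s(self):
        es = _eset([(k * 30, k * 30 + 2) for k in range(18)], duration=600.0)
        assert epoch_stats(es)[0] == pytest.approx(0.03)

    def test_empty_set(self):
        rate, dur = epoch_stats(_eset([], duration=600.0))
        assert rate == 0.0 and dur is None


class TestLhr:
    def test_ratio(self):
        r = lhr(_eset([(k, k + 0.5) for k in range(38)]), _eset([(0, 1), (5, 6)]))
        assert r.ratio == pytest.approx(19.0) and not r.undefined

    def test_equal_counts(self):
        assert lhr(_eset([(0, 1)]), _eset([(2, 3)])).ratio == 1.0

    def test_zero_high_flagged(self):
        r = lhr(_eset([(0, 1)]), _eset([]))
        assert r.undefined and np.isnan(r.ratio)

    def test_directional_property(self):
        # LHR falls when low counts fall and high counts rise
        before = lhr(_eset([(k, k + 0.5) for k in range(30)]), _eset([(0, 1)]))
        after = lhr(_eset([(k, k + 0.5) for k in range(20)]), _eset([(0, 1), (2, 3)]))
        assert after.ratio < before.ratio


class TestCohensD:
    def test_published_worked_examples(self):
        assert cohens_d(6.7, 3.69) == pytest.approx(1.82, abs=0.005)
        assert cohens_d(9.52, 4.61) == pytest.approx(2.06, abs=0.01)

    def test_zero_difference(self):
        assert cohens_d(0.0, 1.3) == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0)

    def test_group_form_scale_invariant_and_nonnegative(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 25)
        d = cohens_d_groups(a, b, "independent")
        assert d >= 0
        assert cohens_d_groups(5 * a, 5 * b, "independent") == pytest.approx(d, rel=1e-12)
        c = rng.normal(1, 2, 30)
        dp = cohens_d_groups(a, c, "paired")
        assert cohens_d_groups(3 * a, 3 * c, "paired") == pytest.approx(dp, rel=1e-12)


class TestCompareConditions:
    def test_identical_pairs(self):
        cc = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cc.percent_change == 0.0 and cc.cohens_d == 0.0

    def test_power_at_two_pooled_sds(self):
        # a 2-SD paired shift at n=6 is significant in >= 80% of replicates
        rng = np.random.default_rng(1)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(10.0, 1.0, 6)
            b = a + rng.normal(2.0, 1.0, 6)
            if compare_conditions(a, b).t_p < 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_monotone_decrease_extreme_wilcoxon(self):
        a = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        b = [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        cc = compare_conditions(a, b)
        assert cc.wilcoxon_stat == 0.0  # all differences one-signed

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [2.0])


class TestTimeCourse:
    def test_six_ten_minute_bins(self):
        starts, rates = time_course([100.0, 500.0, 3599.0], 3600.0, bin_s=600.0)
        assert len(starts) == 6
        assert rates[0] == pytest.approx(2 / 600)

    def test_uniform_rates(self):
        times = np.arange(0.5, 600.0, 1.0)
        _, rates = time_course(times, 600.0, bin_s=100.0)
        assert np.allclose(rates, 1.0, atol=0.01)

    def test_step_change_detected(self):
        rng = np.random.default_rng(2)
        t1 = rng.uniform(0, 1800, 60)
        t2 = rng.uniform(1800, 3600, 240)
        _, rates = time_course(np.concatenate([t1, t2]), 3600.0, bin_s=600.0)
        assert rates[:3].mean() < rates[3:].mean() / 2

    def test_partial_final_bin_normalized(self):
        _, rates = time_course([850.0], 900.0, bin_s=600.0)
        assert rates[1] == pytest.approx(1 / 300.0)


def _coupled_pair(seed, fs=256.0, duration=120.0, phi0=-1.0, depth=0.8):
    """Fast 3 Hz tone whose envelope follows the phase of a noisy 1.5 Hz rhythm."""
    pink = pink_trace(duration, fs, seed).samples
    sos = sps.butter(4, [1.5 / 2**0.5, 1.5 * 2**0.5], btype="bandpass", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos, pink)
    phi = np.angle(sps.hilbert(slow))
    t = np.arange(int(duration * fs)) / fs
    fast = (1 + depth * np.cos(phi - phi0)) * np.cos(2 * np.pi * 3.0 * t)
    fast += 0.3 * pink_trace(duration, fs, seed + 5000).samples
    return SignalTrace(slow, fs), SignalTrace(fast, fs)


class TestPhaseAmplitudeCoupling:
    def test_recovers_preferred_phase(self):
        slow, fast = _coupled_pair(seed=0)
        res = phase_amplitude_coupling(slow, fast, seed=0)
        err = np.angle(np.exp(1j * (res.preferred_phase - (-1.0))))
        assert abs(err) <= np.pi / 8
        assert res.p_value < 0.05
        assert res.mi >= 0

    def test_mi_invariant_to_fast_scaling(self):
        slow, fast = _coupled_pair(seed=1)
        r1 = phase_amplitude_coupling(slow, fast, n_surrogates=20, seed=0)
        fast2 = SignalTrace(10 * fast.samples, fast.fs)
        r2 = phase_amplitude_coupling(slow, fast2, n_surrogates=20, seed=0)
        assert r2.mi == pytest.approx(r1.mi, rel=1e-9)

    def test_independent_noise_not_significant(self):
        slow = pink_trace(60.0, 256.0, seed=21)
        fast = pink_trace(60.0, 256.0, seed=22)
        res = phase_amplitude_coupling(slow, fast, seed=5)
        assert res.p_value > 0.05
        assert res.mi < 0.01

    def test_degenerate_amplitude_rejected(self):
        slow = pink_trace(60.0, 256.0, seed=23)
        fast = SignalTrace(np.zeros(slow.n_samples), 256.0)
        with pytest.raises(ValueError):
            phase_amplitude_coupling(slow, fast)

    def test_short_segment_rejected(self):
        slow = pink_trace(60.0, 256.0, seed=24)
        with pytest.raises(ValueError):
            phase_amplitude_coupling(slow, slow, segment_s=1.0)
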