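"""Shared fixtures: small, programmatically generated signals."""

import numpy as np
import pytest

from lfpwave import SignalTrace, SimulationSpec, generate_baseline_noise


@pytest.fixture(scope="session")
def small_spec():
    """A fast simulation spec: 600 s at 1.25 kHz (analysis band unchanged)."""
    return SimulationSpec(duration_s=600.0, fs=1250.0, seed=1)


@pytest.fixture(scope="session")
def small_noise(small_spec):
    return generate_baseline_noise(small_spec)


@pytest.fixture()
def sine_trace():
    """60 s unit-amplitude 3 Hz sinusoid at the analysis rate."""
    fs = 256.0
    t = np.arange(int(60 * fs)) / fs
    return SignalTrace(np.sin(2 * np.pi * 3.0 * t), fs)


def pink_trace(duration_s, fs, seed, rms=1.0):
    """Short 1/f helper used by several test modules."""
    spec = SimulationSpec(
        duration_s=duration_s, fs=fs, seed=seed, noise_rms=rms, filter_seconds=4.0
    )
    return generate_baseline_noise(spec)
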