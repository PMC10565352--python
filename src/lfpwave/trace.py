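"""Uniformly sampled signal container used throughout the package.

A :class:`SignalTrace` is the universal currency of every operation: a 1-D
real-valued series with a sampling rate in Hz, an optional start time, and a
free-text channel label (MEA grid positions such as ``"11"`` for row 1,
column 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SignalTrace"]


@dataclass
class SignalTrace:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like of float
        Ordered amplitudes (microvolts or arbitrary units). Must be finite.
    fs : float
        Sampling rate in Hz. Must be positive.
    t0 : float, optional
        Start time in seconds (default 0).
    label : str, optional
        Free-text channel identifier, e.g. an electrode grid position.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("trace must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def rms(self) -> float:
        """Root-mean-square amplitude of the trace."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def copy(self) -> "SignalTrace":
        return replace(self, samples=self.samples.copy())
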