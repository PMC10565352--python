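"""Recording and results I/O.

Open formats only: an HDF5 layout (``/signal`` as channels x samples,
``/channel_labels``, attrs ``fs_hz`` and ``units``), CSV traces with an
``# fs_hz=...`` header line, EDF reading (through MNE, when installed), and
epoch tables as CSV with deterministic row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .detect import EpochEvent, EpochSet
from .trace import SignalTrace

__all__ = [
    "GridRecording",
    "read_recording",
    "write_recording",
    "write_epochs",
    "read_epochs",
    "EPOCH_COLUMNS",
]

EPOCH_COLUMNS = ["channel", "method", "band_lo_hz", "band_hi_hz", "start_s", "end_s", "peak_norm"]


@dataclass
class GridRecording:
    """Multi-channel recording keyed by grid-position labels (e.g. "11")."""

    channels: dict[str, SignalTrace]
    fs: float
    units: str = "uV"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {t.n_samples for t in self.channels.values()}
        rates = {t.fs for t in self.channels.values()}
        if len(lengths) > 1 or len(rates) > 1:
            raise ValueError("all channels must share fs and length")
        if rates and rates != {self.fs}:
            raise ValueError("channel fs inconsistent with recording fs")

    @property
    def labels(self) -> list[str]:
        return list(self.channels)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    return {".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".edf": "edf"}.get(suffix, "hdf5")


def read_recording(path: str | Path, format: str | None = None) -> GridRecording | SignalTrace:
    """Read a recording from HDF5, CSV, or EDF.

    Returns a single :class:`SignalTrace` for one-channel files and a
    :class:`GridRecording` otherwise. CSV files must carry a first line
    ``# fs_hz=<rate>`` (optionally ``units=...``) followed by one column per
    channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_h5(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_h5(path: Path) -> GridRecording | SignalTrace:
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise ValueError(f"{path}: missing /signal dataset")
        sig = np.asarray(f["signal"])
        attrs = dict(f["signal"].attrs) | dict(f.attrs)
        if "fs_hz" not in attrs:
            raise ValueError(f"{path}: missing fs_hz attribute")
        fs = float(attrs["fs_hz"])
        units = str(attrs.get("units", "au"))
        if sig.ndim == 1:
            return SignalTrace(sig, fs, label=str(attrs.get("label", "")))
        labels = [
            l.decode() if isinstance(l, bytes) else str(l)
            for l in (f["channel_labels"][()] if "channel_labels" in f else range(sig.shape[0]))
        ]
        channels = {lab: SignalTrace(sig[i], fs, label=lab) for i, lab in enumerate(labels)}
        return GridRecording(channels, fs, units=units)


def _read_csv(path: Path) -> GridRecording | SignalTrace:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise ValueError(f"{path}: CSV must start with a '# fs_hz=...' metadata line")
    meta = {}
    for tok in first.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing fs_hz in CSV metadata line")
    fs = float(meta["fs_hz"])
    df = pd.read_csv(path, skiprows=1)
    if df.shape[1] == 1:
        col = df.columns[0]
        return SignalTrace(df[col].to_numpy(), fs, label=str(col))
    channels = {str(c): SignalTrace(df[c].to_numpy(), fs, label=str(c)) for c in df.columns}
    return GridRecording(channels, fs, units=meta.get("units", "au"))


def _read_edf(path: Path) -> GridRecording | SignalTrace:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    if data.shape[0] == 1:
        return SignalTrace(data[0], fs, label=raw.ch_names[0])
    channels = {name: SignalTrace(data[i], fs, label=name) for i, name in enumerate(raw.ch_names)}
    return GridRecording(channels, fs)


def write_recording(
    rec: GridRecording | SignalTrace, path: str | Path, units: str | None = None
) -> Path:
    """Write a recording to the HDF5 layout or CSV (chosen by suffix)."""
    path = Path(path)
    fmt = _infer_format(path, None)
    if isinstance(rec, SignalTrace):
        labels = [rec.label or "ch0"]
        sig = rec.samples[None, :]
        fs = rec.fs
        units = units or "au"
    else:
        labels = rec.labels
        sig = np.stack([rec.channels[l].samples for l in labels])
        fs = rec.fs
        units = units or rec.units
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("signal", data=sig)
            f.create_dataset(
                "channel_labels", data=np.array([l.encode() for l in labels])
            )
            f.attrs["fs_hz"] = fs
            f.attrs["units"] = units
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={fs} units={units}\n")
            pd.DataFrame(sig.T, columns=labels).to_csv(fh, index=False)
    else:
        raise ValueError(f"cannot write format {fmt!r} (EDF export is not supported)")
    return path


def epochs_to_frame(esets: Sequence[EpochSet] | EpochSet) -> pd.DataFrame:
    """Flatten epoch sets into the standard epoch table."""
    if isinstance(esets, EpochSet):
        esets = [esets]
    rows = []
    for eset in esets:
        for e in eset.events:
            lo, hi = e.band if e.band is not None else (float("nan"), float("nan"))
            rows.append(
                {
                    "channel": e.channel,
                    "method": e.method,
                    "band_lo_hz": lo,
                    "band_hi_hz": hi,
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "peak_norm": e.peak_norm,
                }
            )
    df = pd.DataFrame(rows, columns=EPOCH_COLUMNS)
    return df.sort_values(["channel", "start_s"], kind="stable").reset_index(drop=True)


def write_epochs(esets: Sequence[EpochSet] | EpochSet, path: str | Path) -> Path:
    """Write an epoch table CSV (sorted by channel then onset, ms precision)."""
    path = Path(path)
    df = epochs_to_frame(esets)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_epochs(path: str | Path) -> pd.DataFrame:
    """Read an epoch table CSV back into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return pd.read_csv(path)
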