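"""Multichannel sampled signals: container, normalization, delimited-text I/O.

A :class:`MultichannelSignal` is the common currency of the package: it is the
teaching signal fed to the oscillator network, the reconstruction the readout
produces, and the free-running continuation the generator emits.  Data is kept
as a ``(n_samples, n_channels)`` float array together with the sampling rate,
channel labels, and a free-form provenance map.

Signals are stored on disk as delimited text (CSV with a header row of channel
labels, one sample per row) plus a JSON sidecar ``<file>.meta.json`` carrying
the sampling rate and provenance.  EDF polysomnograms can be read when an EDF
library (``pyedflib`` or ``mne``) is installed; neither is a hard dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = [
    "MultichannelSignal",
    "read_signal",
    "write_signal",
    "normalize",
    "denormalize",
]


@dataclass
class MultichannelSignal:
    """A finite multichannel time series sampled at a fixed rate.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_channels)``; volts or normalized units.
    fs:
        Sampling rate in Hz, strictly positive.
    labels:
        One name per channel.
    meta:
        Provenance map: source file, normalization constants, ground-truth
        components when the signal is synthetic.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise InputError("signal data must be a 2-D (time x channel) array")
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise InputError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise InputError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by (case-insensitive) label."""
        low = [l.lower() for l in self.labels]
        try:
            return self.data[:, low.index(label.lower())]
        except ValueError:
            raise InputError(f"no channel named {label!r}; have {self.labels}")

    def select(self, labels: list[str]) -> "MultichannelSignal":
        cols = np.column_stack([self.channel(l) for l in labels])
        return MultichannelSignal(cols, self.fs, list(labels), dict(self.meta))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_signal(sig: MultichannelSignal, path: str | Path) -> None:
    """Write a signal as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(sig.data, columns=sig.labels)
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {"fs": sig.fs, "labels": sig.labels, "meta": sig.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def read_signal(
    path: str | Path, format: str = "delimited", fs: float | None = None
) -> MultichannelSignal:
    """Read a signal from disk.

    ``format='delimited'`` expects a header row of labels and one sample per
    row; the sampling rate comes from the sidecar written by
    :func:`write_signal` or from the ``fs`` argument.  ``format='edf'``
    requires an optional EDF library.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such signal file: {path}")
    if format == "edf":
        return _read_edf(path)
    if format != "delimited":
        raise FormatError(f"unknown signal format {format!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a typed parse error
        raise FormatError(f"could not parse {path}: {exc}") from exc
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        info = json.loads(side.read_text())
        fs = fs if fs is not None else info.get("fs")
        meta = info.get("meta", {})
    if fs is None:
        raise InputError(
            f"sampling rate unknown for {path}: pass fs= or provide {side.name}"
        )
    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path} contains non-numeric samples: {exc}") from exc
    if data.ndim != 2 or not np.all(np.isfinite(data)):
        raise FormatError(f"{path} does not contain a finite numeric matrix")
    return MultichannelSignal(data, float(fs), list(df.columns), meta)


def _read_edf(path: Path) -> MultichannelSignal:
    try:
        import pyedflib  # type: ignore
    except ImportError:
        pyedflib = None
    if pyedflib is not None:
        reader = pyedflib.EdfReader(str(path))
        try:
            labels = reader.getSignalLabels()
            fs = float(reader.getSampleFrequency(0))
            data = np.column_stack(
                [reader.readSignal(i) for i in range(reader.signals_in_file)]
            )
        finally:
            reader.close()
        return MultichannelSignal(data, fs, labels, {"source": str(path)})
    try:
        import mne  # type: ignore
    except ImportError:
        raise FormatError(
            "reading EDF requires the optional 'pyedflib' or 'mne' package"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelSignal(
        raw.get_data().T, float(raw.info["sfreq"]), list(raw.ch_names),
        {"source": str(path)},
    )


def normalize(sig: MultichannelSignal, mode: str = "maxabs") -> MultichannelSignal:
    """Remove per-channel DC offset, then rescale.

    ``maxabs`` divides by the per-channel maximum absolute value (constant
    channels map to zeros, recorded with scale 0); ``zscore`` divides by the
    standard deviation and refuses constant channels.  The offsets and scales
    are stored in ``meta['normalization']`` so :func:`denormalize` can invert.
    """
    if mode not in ("maxabs", "zscore"):
        raise InputError(f"unknown normalization mode {mode!r}")
    offsets = sig.data.mean(axis=0)
    centred = sig.data - offsets
    if mode == "maxabs":
        scales = np.max(np.abs(centred), axis=0) if sig.n_samples else np.zeros(sig.n_channels)
    else:
        scales = centred.std(axis=0)
        flat = np.flatnonzero(scales == 0)
        if flat.size:
            raise InputError(
                f"constant channel {sig.labels[flat[0]]!r} cannot be z-scored"
            )
    safe = np.where(scales == 0, 1.0, scales)
    out = centred / safe
    meta = dict(sig.meta)
    meta["normalization"] = {
        "mode": mode,
        "offset": offsets.tolist(),
        "scale": scales.tolist(),
    }
    return MultichannelSignal(out, sig.fs, list(sig.labels), meta)


def denormalize(sig: MultichannelSignal) -> MultichannelSignal:
    """Invert :func:`normalize` using the constants recorded in ``meta``."""
    try:
        norm = sig.meta["normalization"]
    except KeyError:
        raise InputError("signal carries no normalization record to invert")
    scales = np.asarray(norm["scale"], dtype=float)
    offsets = np.asarray(norm["offset"], dtype=float)
    safe = np.where(scales == 0, 1.0, scales)
    data = sig.data * safe + offsets
    meta = {k: v for k, v in sig.meta.items() if k != "normalization"}
    return MultichannelSignal(data, sig.fs, list(sig.labels), meta)
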