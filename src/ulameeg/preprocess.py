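"""EEG loading, line-noise/artifact filtering, and fixed-length segmentation.

Recordings are channel-major microvolt matrices with a sampling rate and a
class label (``"ADHD"`` or ``"normal"``).  Cleaning applies a narrow 50 Hz
IIR notch followed by a 6th-order Butterworth low-pass at 60 Hz, both run
forward-and-backward (zero phase) per channel so that the scalogram's time
axis is undistorted.  Cleaned recordings are cut into non-overlapping 512
sample (4 s at 128 Hz) epochs; a trailing remainder shorter than one window
is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

__all__ = [
    "EEGRecording",
    "Segment",
    "LoadError",
    "notch_filter",
    "butterworth_lowpass",
    "clean_recording",
    "segment_recording",
    "load_recording",
]

LABELS = ("ADHD", "normal")


class LoadError(ValueError):
    """A recording file or its sidecar failed validation."""


@dataclass
class EEGRecording:
    """A labeled multichannel EEG recording.

    data : (channels, samples) float array, microvolts
    fs : sampling rate in Hz
    channel_names : one name per row of ``data``
    label : "ADHD" or "normal"
    subject_id : free-form identifier
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(
                f"recording data must be a (channels, samples) matrix with at "
                f"least one channel and one sample, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise LoadError(
                f"recording {self.subject_id!r} contains a non-finite value at "
                f"channel {bad[0]}, sample {bad[1]}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Segment:
    """One fixed-length epoch cut from a recording."""

    data: np.ndarray
    window_len: int
    parent_id: str
    label: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.window_len:
            raise ValueError(
                f"segment has {self.data.shape[1]} samples, expected "
                f"window_len={self.window_len}"
            )


def _require_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains NaN or Inf")
    return x


def notch_filter(x: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` Hz (power-line removal).

    Quality factor ``q`` sets the -3 dB bandwidth f0/q; the default 30 gives
    a ~1.7 Hz notch at 50 Hz, narrow enough to leave the EEG bands intact.
    Applied with ``filtfilt`` so the net phase response is zero.
    """
    if not fs > 2 * f0:
        raise ValueError(
            f"notch frequency {f0} Hz requires fs > {2 * f0} Hz, got fs={fs}"
        )
    x = _require_finite(x)
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, x, axis=-1)


def butterworth_lowpass(
    x: np.ndarray, fs: float, order: int = 6, cutoff: float = 60.0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (default 6th order, 60 Hz).

    If the requested cutoff reaches or exceeds Nyquist it is clamped to
    0.99 * Nyquist with a warning, so the 60 Hz passband edge stays usable
    at the nominal 128 Hz sampling rate.
    """
    x = _require_finite(x)
    nyq = fs / 2.0
    if cutoff >= nyq:
        clamped = 0.99 * nyq
        warnings.warn(
            f"low-pass cutoff {cutoff} Hz >= Nyquist {nyq} Hz; clamping to "
            f"{clamped:.3f} Hz",
            stacklevel=2,
        )
        cutoff = clamped
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def clean_recording(
    rec: EEGRecording,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    lowpass_hz: float = 60.0,
    lowpass_order: int = 6,
) -> EEGRecording:
    """Notch then low-pass every channel; returns a new recording."""
    data = notch_filter(rec.data, rec.fs, f0=notch_hz, q=notch_q)
    data = butterworth_lowpass(data, rec.fs, order=lowpass_order, cutoff=lowpass_hz)
    return EEGRecording(
        data=data,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        label=rec.label,
        subject_id=rec.subject_id,
    )


def segment_recording(rec: EEGRecording, window_len: int = 512) -> list[Segment]:
    """Cut non-overlapping windows of ``window_len`` samples, in order.

    Returns floor(samples / window_len) segments; a recording shorter than
    one window yields an empty list.
    """
    if window_len < 1:
        raise ValueError(f"window_len must be >= 1, got {window_len}")
    n = rec.n_samples // window_len
    return [
        Segment(
            data=rec.data[:, i * window_len : (i + 1) * window_len].copy(),
            window_len=window_len,
            parent_id=rec.subject_id,
            label=rec.label,
            index=i,
        )
        for i in range(n)
    ]


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise LoadError(f"no YAML sidecar found for {path} (missing sampling rate)")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    if "fs" not in meta:
        raise LoadError(f"sidecar {sidecar} is missing required field 'fs'")
    return meta


def load_recording(path: str | Path, label: str | None = None) -> EEGRecording:
    """Load an EDF file or a CSV/NPY matrix with its YAML sidecar.

    CSV/NPY matrices are channel-major unless the sidecar declares
    ``orientation: samples_x_channels``, in which case they are transposed.
    The sidecar must declare ``fs``; ``label``, ``subject_id`` and
    ``channel_names`` are read from it unless given here.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _load_edf(path, label)
    meta = _load_sidecar(path)
    if suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
    orientation = meta.get("orientation", "channels_x_samples")
    if orientation == "samples_x_channels":
        data = data.T
    elif orientation != "channels_x_samples":
        raise LoadError(f"unknown orientation {orientation!r} in sidecar for {path}")
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise LoadError(
            f"{path} contains a non-finite value at row {bad[0]}, column {bad[1]} "
            "(channel-major orientation)"
        )
    label = label or meta.get("label")
    if label is None:
        raise LoadError(f"no class label given for {path} and none in sidecar")
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[0])]
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(names),
        label=label,
        subject_id=str(meta.get("subject_id", path.stem)),
    )


def _load_edf(path: Path, label: str | None) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise LoadError("EDF support requires the 'mne' package") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise LoadError(f"could not read EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    if label is None:
        raise LoadError(f"EDF file {path} requires an explicit class label")
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        label=label,
        subject_id=path.stem,
    )
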