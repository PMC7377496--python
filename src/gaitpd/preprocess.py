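"""Synchronization, uniform resampling and low-pass filtering of raw IMU recordings.

Raw smartphone recordings arrive with slightly asynchronous per-sensor
timestamps.  The pipeline brings them onto a common time span, interpolates
every channel onto a uniform 100 Hz grid, and smooths with a fourth-order
low-pass Butterworth filter at 20 Hz (meaningful human movement lives below
20 Hz).  Filtering defaults to zero-phase (forward-backward) application so
that heel-strike/toe-off timing is not delayed; a causal mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal
from scipy.interpolate import interp1d

CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: accelerometer channels are in g, gyroscope in deg/s; acc_x is vertical (up +)
N_CHANNELS = 6


class AlignmentError(ValueError):
    """Raised when two sensor streams share no common time span."""


@dataclass
class Recording:
    """Timestamped 6-channel IMU recording with subject metadata.

    ``channels`` has shape (n_samples, 6) ordered as :data:`CHANNEL_NAMES`;
    ``t`` is strictly increasing, in seconds.
    """

    t: np.ndarray
    channels: np.ndarray
    subject_id: str = "unknown"
    group: str = "unknown"  # {"PD", "control", "unknown"}
    updrs: Optional[float] = None
    recording_id: str = "rec0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("need at least 2 samples")
        if self.channels.shape != (self.t.size, N_CHANNELS):
            raise ValueError(
                f"channels must have shape ({self.t.size}, {N_CHANNELS}), "
                f"got {self.channels.shape}"
            )
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.group not in ("PD", "control", "unknown"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, CHANNEL_NAMES.index(name)]


@dataclass
class UniformRecording:
    """6-channel recording on a uniform grid: t[k] = t0 + k / fs."""

    fs: float
    channels: np.ndarray
    t0: float = 0.0
    subject_id: str = "unknown"
    group: str = "unknown"
    updrs: Optional[float] = None
    recording_id: str = "rec0"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channels.ndim != 2 or self.channels.shape[1] != N_CHANNELS:
            raise ValueError("channels must be (n, 6)")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.channels[:, CHANNEL_NAMES.index(name)]


def synchronize(acc_rec: Recording, gyr_rec: Recording) -> Recording:
    """Merge separate accelerometer and gyroscope streams.

    Both streams are trimmed to the common time span
    ``[max(starts), min(ends)]`` (excess leading/trailing samples of either
    file are discarded) and the gyroscope is linearly interpolated onto the
    accelerometer's surviving timestamps.

    Raises
    ------
    AlignmentError
        If the two streams do not overlap in time.
    """
    start = max(acc_rec.t[0], gyr_rec.t[0])
    end = min(acc_rec.t[-1], gyr_rec.t[-1])
    if end <= start:
        raise AlignmentError(
            f"no temporal overlap: acc [{acc_rec.t[0]:.3f}, {acc_rec.t[-1]:.3f}] "
            f"vs gyr [{gyr_rec.t[0]:.3f}, {gyr_rec.t[-1]:.3f}]"
        )
    keep = (acc_rec.t >= start) & (acc_rec.t <= end)
    t = acc_rec.t[keep]
    if t.size < 2:
        raise AlignmentError("overlap contains fewer than 2 accelerometer samples")
    out = np.empty((t.size, N_CHANNELS))
    out[:, :3] = acc_rec.channels[keep, :3]
    for j in range(3):
        f = interp1d(gyr_rec.t, gyr_rec.channels[:, 3 + j], kind="linear",
                     bounds_error=False, fill_value=(gyr_rec.channels[0, 3 + j],
                                                     gyr_rec.channels[-1, 3 + j]))
        out[:, 3 + j] = f(t)
    return Recording(
        t=t, channels=out,
        subject_id=acc_rec.subject_id, group=acc_rec.group,
        updrs=acc_rec.updrs, recording_id=acc_rec.recording_id,
    )


def resample_uniform(rec: Recording, fs: float = 100.0, kind: str = "linear") -> UniformRecording:
    """Interpolate every channel onto a uniform ``fs`` grid over [t[0], t[-1]].

    The grid never extends past the original time span (no extrapolation).
    ``kind`` is any 1-D interpolation kind scipy accepts ("linear", "cubic", ...).
    """
    t = rec.t
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    n_out = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n_out) / fs
    out = np.empty((n_out, N_CHANNELS))
    for j in range(N_CHANNELS):
        f = interp1d(t, rec.channels[:, j], kind=kind)
        out[:, j] = f(grid)
    return UniformRecording(
        fs=fs, channels=out, t0=float(t[0]),
        subject_id=rec.subject_id, group=rec.group,
        updrs=rec.updrs, recording_id=rec.recording_id,
    )


def lowpass_filter(rec: UniformRecording, cutoff: float = 20.0, order: int = 4,
                   causal: bool = False) -> UniformRecording:
    """Low-pass Butterworth smoothing of all 6 channels.

    Default applies the ``order``-th order design forward-backward
    (``filtfilt`` with odd reflective padding of length ``3 * order``),
    which squares the magnitude response and cancels phase so that gait
    event timing is preserved.  ``causal=True`` applies a single forward
    pass instead.
    """
    nyq = rec.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    if cutoff <= 0 or order < 1:
        raise ValueError("cutoff must be positive, order >= 1")
    b, a = signal.butter(order, cutoff / nyq, btype="low")
    if causal:
        filtered = signal.lfilter(b, a, rec.channels, axis=0)
    else:
        filtered = signal.filtfilt(b, a, rec.channels, axis=0,
                                   padtype="odd", padlen=3 * order)
    return replace(rec, channels=filtered)


def butter_coefficients(fs: float = 100.0, cutoff: float = 20.0, order: int = 4):
    """Return the (b, a) coefficients :func:`lowpass_filter` uses at this setting."""
    return signal.butter(order, cutoff / (fs / 2.0), btype="low")


def preprocess(rec: Recording, fs: float = 100.0, cutoff: float = 20.0,
               order: int = 4, kind: str = "linear", causal: bool = False) -> UniformRecording:
    """resample_uniform followed by lowpass_filter — the standard chain."""
    return lowpass_filter(resample_uniform(rec, fs=fs, kind=kind),
                          cutoff=cutoff, order=order, causal=causal)
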