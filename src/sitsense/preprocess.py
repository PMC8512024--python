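"""Denoising, amplitude normalization and sliding-window segmentation.

The study pipeline denoises each raw channel, derives one magnitude
channel per sensor, rescales every channel to [-1, 1], and cuts the
stream into fixed-length labelled windows.  Window length is omega_t
seconds, i.e. N = omega_t * fs samples per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, sosfiltfilt

from .synthetic import AXES, SENSORS, ImuRecording

#: Channel order shared by windows and the feature registry: nine raw
#: channels (sensor-major, axes X/Y/Z) followed by three magnitude channels.
RAW_CHANNELS = tuple(f"{axis}-{sensor}" for sensor in SENSORS for axis in AXES)
MAGNITUDE_CHANNELS = ("Total-acceleration", "Total-gyroscope", "Total-magnetometer")
ALL_CHANNELS = RAW_CHANNELS + MAGNITUDE_CHANNELS


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: N = round(omega_t * fs) samples per window."""

    omega_t: float = 1.0
    sample_rate_hz: float = 50.0
    stride: int = 25

    @property
    def n_samples(self) -> int:
        return int(round(self.omega_t * self.sample_rate_hz))

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("window must contain at least 2 samples")
        if not 1 <= self.stride <= self.n_samples:
            raise ValueError("stride must be in [1, n_samples]")


@dataclass
class Window:
    """One labelled segment: 12 named channel arrays of length N."""

    channels: dict[str, np.ndarray]
    label: str
    subject_id: int
    start_index: int

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def denoise(signal: np.ndarray, cutoff_hz: float = 5.0, fs: float = 50.0,
            order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter; preserves DC level exactly
    up to filter numerics, same output length as input."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def normalize(signal: np.ndarray) -> np.ndarray:
    """Max-abs rescale to [-1, 1]; an all-zero input is returned unchanged."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    peak = np.max(np.abs(x))
    if peak == 0:
        return x.copy()
    return x / peak


def preprocess_recording(
    recording: ImuRecording,
    cutoff_hz: float = 5.0,
    apply_normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Denoise raw channels, add per-sensor magnitude channels (computed
    after denoising, before normalization), then max-abs normalize each
    channel over the whole recording."""
    fs = recording.sample_rate_hz
    chans = {
        name: denoise(arr, cutoff_hz=cutoff_hz, fs=fs)
        for name, arr in recording.channels().items()
    }
    for sensor, total in zip(SENSORS, MAGNITUDE_CHANNELS):
        x, y, z = (chans[f"{axis}-{sensor}"] for axis in AXES)
        chans[total] = np.sqrt(x * x + y * y + z * z)
    if apply_normalize:
        chans = {name: normalize(arr) for name, arr in chans.items()}
    return chans


def make_windows(
    recording: ImuRecording,
    spec: WindowSpec,
    cutoff_hz: float = 5.0,
    apply_normalize: bool = True,
) -> list[Window]:
    """Segment a preprocessed recording into pure-label windows.

    Windows start every ``spec.stride`` samples; a window's label is the
    majority per-sample label, and windows whose majority share is below
    100% (mixed activities) are dropped.
    """
    n = spec.n_samples
    L = len(recording)
    if L < n:
        warnings.warn("recording shorter than one window; returning no windows")
        return []
    chans = preprocess_recording(recording, cutoff_hz, apply_normalize)

    starts = np.arange(0, L - n + 1, spec.stride)
    label_views = sliding_window_view(recording.label, n)[starts]
    pure = (label_views == label_views[:, :1]).all(axis=1)

    views = {
        name: sliding_window_view(arr, n)[starts] for name, arr in chans.items()
    }
    windows = []
    for i, start in enumerate(starts):
        if not pure[i]:
            continue
        windows.append(
            Window(
                channels={name: v[i] for name, v in views.items()},
                label=str(label_views[i, 0]),
                subject_id=recording.subject_id,
                start_index=int(start),
            )
        )
    return windows


def window_count(length: int, n_samples: int, stride: int) -> int:
    """Number of window start positions before the purity filter."""
    if length < n_samples:
        return 0
    return (length - n_samples) // stride + 1


def stack_windows(windows: list[Window]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack windows into per-channel (n_windows, N) arrays plus labels."""
    if not windows:
        raise ValueError("no windows to stack")
    names = list(windows[0].channels)
    stacked = {
        name: np.stack([w.channels[name] for w in windows]) for name in names
    }
    labels = np.array([w.label for w in windows])
    return stacked, labels
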