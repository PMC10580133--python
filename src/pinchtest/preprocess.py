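"""Signal preprocessing for touch traces and inertial streams.

Two chains are used:

* touch coordinates — resampled to a uniform 60 Hz grid and low-pass
  filtered with a zero-phase 4th-order Butterworth filter before any
  path/velocity feature is computed;
* inertial stream — 2 s trimmed from each end (to drop the set-up and
  wind-down phases), acceleration magnitude and inclination resampled to a
  20 ms period and smoothed with a 10-sample moving Blackman window.

The configured Butterworth cutoff of fs/2 sits exactly at the Nyquist
frequency, where a low-pass filter is degenerate; the effective cutoff is
therefore clamped to 0.99 x Nyquist (see docs/methods.md).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .model import ImuSample

NYQUIST_CLAMP = 0.99


class PreprocessError(ValueError):
    pass


@dataclass
class UniformTrace:
    """Uniformly sampled, named channels sharing one time grid."""

    t0: float
    fs: float
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class PreprocessConfig:
    touch_fs: float = 60.0           # Hz, touch resampling rate
    butter_order: int = 4
    butter_cutoff: float | None = None  # Hz; None = fs/2, clamped below Nyquist
    imu_trim: float = 2.0            # s removed from each end of the stream
    imu_period: float = 0.020        # s, inertial resampling period
    blackman_len: int = 10           # samples, smoothing window

    def validate(self) -> "PreprocessConfig":
        if self.touch_fs <= 0 or self.imu_trim < 0 or self.imu_period <= 0:
            raise PreprocessError("preprocessing parameters must be positive")
        if self.butter_order < 1 or self.blackman_len < 1:
            raise PreprocessError("butter_order and blackman_len must be >= 1")
        return self

    def effective_cutoff(self, fs: float) -> float:
        cutoff = fs / 2 if self.butter_cutoff is None else self.butter_cutoff
        nyq = fs / 2
        if cutoff <= 0:
            raise PreprocessError("butter_cutoff must be positive")
        return min(cutoff, NYQUIST_CLAMP * nyq)


def resample_uniform(
    t: Sequence[float], values: dict[str, Sequence[float]], fs: float
) -> UniformTrace:
    """Linearly interpolate irregular samples onto a uniform grid.

    The grid starts at the first sample time with spacing 1/fs; the output
    length is floor((t_last - t_first) * fs) + 1, so the grid never
    extrapolates past the last sample.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise PreprocessError("resampling needs at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise PreprocessError("sample times must be strictly increasing")
    # interpolate in time relative to the first sample so that the result is
    # exactly invariant under time translation of the input
    rel = t - t[0]
    n_out = int(np.floor(rel[-1] * fs)) + 1
    grid = np.arange(n_out) / fs
    channels = {
        name: np.interp(grid, rel, np.asarray(v, dtype=float))
        for name, v in values.items()
    }
    return UniformTrace(t0=float(t[0]), fs=float(fs), channels=channels)


@lru_cache(maxsize=64)
def _butter_design(order: int, cutoff: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Cached second-order-sections design plus its steady-state filter
    state (for step-matched initial conditions)."""
    sos = sp_signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    zi = sp_signal.sosfilt_zi(sos)
    return sos, zi


def _filtfilt_sos(sos: np.ndarray, zi: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward filtering with odd-extension padding along axis 0
    (columns filtered together).  x must be longer than the pad."""
    padlen = 3 * (2 * len(sos) + 1)
    top = 2 * x[0] - x[padlen:0:-1]
    bottom = 2 * x[-1] - x[-2 : -padlen - 2 : -1]
    ext = np.concatenate([top, x, bottom], axis=0)
    zi_shaped = zi[..., None] if ext.ndim == 2 else zi
    y, _ = sp_signal.sosfilt(sos, ext, axis=0, zi=zi_shaped * ext[0])
    y = y[::-1]
    y, _ = sp_signal.sosfilt(sos, y, axis=0, zi=zi_shaped * y[0])
    y = y[::-1]
    return y[padlen : padlen + len(x)]


def lowpass_butterworth(
    trace: UniformTrace, order: int = 4, cutoff: float | None = None
) -> UniformTrace:
    """Zero-phase (forward-backward) Butterworth low-pass, per channel.

    The cutoff is clamped below the Nyquist frequency; zero-phase filtering
    is used so that timing landmarks are not shifted.  Output length equals
    input length.  Traces too short to pad are returned unchanged.
    """
    nyq = trace.fs / 2
    if cutoff is None:
        cutoff = trace.fs / 2
    cutoff = min(cutoff, NYQUIST_CLAMP * nyq)
    if cutoff <= 0 or cutoff >= nyq:
        raise PreprocessError(f"cutoff {cutoff} Hz not in (0, Nyquist={nyq})")
    sos, zi = _butter_design(order, float(cutoff), float(trace.fs))
    padlen = 3 * (2 * len(sos) + 1)
    out: dict[str, np.ndarray] = {}
    for name, ch in trace.channels.items():
        ch = np.asarray(ch, dtype=float)
        if ch.size <= padlen:
            out[name] = ch.copy()
        else:
            out[name] = _filtfilt_sos(sos, zi, ch)
    return UniformTrace(t0=trace.t0, fs=trace.fs, channels=out)


def smooth_blackman(values: np.ndarray, window_len: int) -> np.ndarray:
    """Convolve with a unit-sum Blackman window, same-length output,
    reflect-padded edges.  A constant input is returned unchanged."""
    if window_len <= 1 or values.size == 0:
        return values.copy()
    win = np.blackman(window_len)
    win = win / win.sum()
    pad = window_len  # enough for either parity
    padded = np.pad(values, pad, mode="reflect") if values.size > 1 else np.repeat(values, 2 * pad + 1)
    sm = np.convolve(padded, win, mode="same")
    return sm[pad : pad + values.size]


def preprocess_imu(samples: Sequence[ImuSample], cfg: PreprocessConfig) -> UniformTrace:
    """Trim, resample and smooth the inertial stream.

    Returns a UniformTrace with channels ``magnitude`` (acceleration
    magnitude, g) and ``inclination`` (rad).  Raises PreprocessError when the
    stream is shorter than twice the trim (the run is then unprocessable and
    its inertial features are missing).
    """
    cfg.validate()
    if len(samples) < 2:
        raise PreprocessError("imu stream has fewer than 2 samples")
    t = np.array([s.t for s in samples], dtype=float)
    if t[-1] - t[0] <= 2 * cfg.imu_trim:
        raise PreprocessError(
            f"imu stream spans {t[-1] - t[0]:.2f} s, needs > {2 * cfg.imu_trim:.0f} s"
        )
    mag = np.array([s.magnitude for s in samples])
    inc = np.array([s.inclination for s in samples])
    keep = (t >= t[0] + cfg.imu_trim) & (t <= t[-1] - cfg.imu_trim)
    # strictly increasing times required by the resampler
    t_k, idx = np.unique(t[keep], return_index=True)
    if t_k.size < 2:
        raise PreprocessError("too few imu samples after trimming")
    trace = resample_uniform(
        t_k, {"magnitude": mag[keep][idx], "inclination": inc[keep][idx]}, 1.0 / cfg.imu_period
    )
    return UniformTrace(
        t0=trace.t0,
        fs=trace.fs,
        channels={
            name: smooth_blackman(ch, cfg.blackman_len)
            for name, ch in trace.channels.items()
        },
    )
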