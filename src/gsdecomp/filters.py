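"""Shared low-level signal helpers (zero-phase filtering, Hampel, z-scoring)."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import DegenerateSignalError, InputError

__all__ = [
    "zscore",
    "bandpass",
    "lowpass",
    "hampel",
    "moving_average",
    "resample_uniform",
    "mad",
]


def zscore(x: np.ndarray, *, name: str = "series") -> np.ndarray:
    """Normalise to zero mean, unit variance; constant input is an error."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        raise DegenerateSignalError(f"{name} is (near-)constant; cannot z-score")
    return (x - x.mean()) / sd


def mad(x: np.ndarray) -> float:
    """Median absolute deviation (unscaled)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def _sos(kind: str, cutoff, fs: float, order: int = 4):
    return signal.butter(order, cutoff, btype=kind, fs=fs, output="sos")


def bandpass(x: np.ndarray, lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if not 0 < lo < hi < fs / 2:
        raise InputError(f"band ({lo}, {hi}) Hz invalid for fs = {fs} Hz")
    return signal.sosfiltfilt(_sos("bandpass", [lo, hi], fs, order), x)


def lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    if not 0 < cutoff < fs / 2:
        raise InputError(f"cutoff {cutoff} Hz invalid for fs = {fs} Hz")
    return signal.sosfiltfilt(_sos("lowpass", cutoff, fs, order), x)


def hampel(x: np.ndarray, window: int = 11, n_mad: float = 3.0) -> np.ndarray:
    """Hampel outlier-replacement filter.

    Samples deviating from their windowed median by more than ``n_mad``
    times the windowed MAD are replaced by that median.  The window is
    centred and truncated at the edges.
    """
    x = np.asarray(x, dtype=float).copy()
    n = x.size
    half = window // 2
    med = np.empty(n)
    dev = np.empty(n)
    for i in range(n):
        seg = x[max(0, i - half): i + half + 1]
        m = np.median(seg)
        med[i] = m
        dev[i] = np.median(np.abs(seg - m))
    bad = np.abs(x - med) > n_mad * dev
    x[bad] = med[bad]
    return x


def moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centred moving-average with edge truncation (same length as input)."""
    if width_samples < 1:
        raise InputError("moving-average window must be >= 1 sample")
    kernel = np.ones(width_samples)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def resample_uniform(x: np.ndarray, fs_in: float, fs_out: float,
                     t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform ``fs_out`` grid spanning the input.

    Returns ``(values, times)``; times start at ``t0``.
    """
    t_in = t0 + np.arange(x.size) / fs_in
    t_out = t0 + np.arange(0, x.size / fs_in - 1e-9, 1.0 / fs_out)
    return np.interp(t_out, t_in, x), t_out
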