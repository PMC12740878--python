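"""Heart rate, respiratory flow, and scan-specific physiological response
functions (PRFs).

Systemic low-frequency oscillations (SLFOs) are the slow (< 0.15 Hz) BOLD
fluctuations driven by beat-to-beat heart-rate variation and by changes in
breathing depth/rate.  This module extracts heart rate (from a pulse
oximeter trace) and respiratory flow (squared derivative of the smoothed
belt signal), estimates per-scan PRF curves by fitting the fMRI global
signal, and builds the combined SLFO regressor at the volume sampling rate.

Each PRF is modelled as a difference of two gamma-shaped terms

    prf(t) = a1 * g(t; ttp1, tau1) - a2 * g(t; ttp2, tau2),

where ``g`` peaks at time-to-peak ``ttp`` (bounded 1-20 s) with width set
by ``tau`` (bounded 0.3-3.5 s so the curve decays essentially to zero
within the 60 s support).  The gamma shape parameters are optimised by a
bounded quasi-Newton search from a fixed 8-point starting grid, while the
four amplitudes are profiled out by ordinary least squares at every
objective evaluation; the procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, signal

from .datatypes import PhysioTrace, RegressorSeries
from .errors import (
    DegenerateSignalError,
    EstimationError,
    InputError,
    SignalQualityError,
)
from .filters import hampel, lowpass, mad, moving_average, zscore

__all__ = [
    "HeartRateSeries",
    "RespiratoryFlowSeries",
    "PRFPair",
    "detect_beats",
    "beats_to_heart_rate",
    "compute_respiratory_flow",
    "estimate_prfs",
    "build_slfo",
    "gamma_kernel",
    "PRF_GRID_FS",
    "PRF_SUPPORT_S",
]

PRF_GRID_FS = 10.0      # Hz; grid for HR/flow series and PRF kernels
PRF_SUPPORT_S = 60.0    # seconds; PRF kernel support

HR_BOUNDS_BPM = (30.0, 220.0)

#: (time-to-peak, tau) bounds for each gamma term
_TTP_BOUNDS = (1.0, 20.0)
_TAU_BOUNDS = (0.3, 3.5)

#: fixed multi-start grid over (ttp1, tau1, ttp2, tau2) x {cardiac, resp}
_STARTS: tuple[tuple[float, ...], ...] = tuple(
    tuple(c) + tuple(r)
    for c in ((4.0, 1.5, 12.0, 2.5), (2.0, 0.8, 8.0, 1.5),
              (8.0, 2.5, 16.0, 3.0), (3.0, 1.2, 6.0, 1.0))
    for r in ((3.0, 1.0, 10.0, 2.0), (9.0, 2.0, 18.0, 3.0))
)[:8]


@dataclass
class HeartRateSeries:
    """Instantaneous heart rate (bpm) on a uniform 10 Hz grid."""

    values: np.ndarray
    t0: float = 0.0
    fs: float = PRF_GRID_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = HR_BOUNDS_BPM
        if np.any(~np.isfinite(self.values)):
            raise InputError("heart-rate series contains non-finite values")
        if np.any((self.values <= lo) | (self.values >= hi)):
            raise SignalQualityError(
                f"heart rate outside physiological bounds ({lo}, {hi}) bpm"
            )


@dataclass
class RespiratoryFlowSeries:
    """Squared derivative of the smoothed belt signal, 10 Hz, non-negative."""

    values: np.ndarray
    t0: float = 0.0
    fs: float = PRF_GRID_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("respiratory flow must be finite and non-negative")


@dataclass
class PRFPair:
    """Estimated cardiac and respiratory PRFs for one scan.

    ``*_params`` are ``(ttp1, tau1, a1, ttp2, tau2, a2)``; ``*_curve`` are
    the impulse responses sampled on the 0-60 s grid at 10 Hz; ``fit_r`` is
    the Pearson correlation of the modelled against the observed global
    signal.
    """

    cardiac_params: np.ndarray
    respiratory_params: np.ndarray
    cardiac_curve: np.ndarray
    respiratory_curve: np.ndarray
    fit_r: float
    tau_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0, PRF_SUPPORT_S + 1e-9, 1 / PRF_GRID_FS)
    )


def gamma_kernel(ttp: float, tau: float,
                 grid: np.ndarray | None = None) -> np.ndarray:
    """Gamma-shaped kernel with unit peak at ``t = ttp``, width ``tau``."""
    if grid is None:
        grid = np.arange(0, PRF_SUPPORT_S + 1e-9, 1 / PRF_GRID_FS)
    p = ttp / tau
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.exp(p * np.log(grid / ttp) + p - grid / tau)
    g[grid == 0] = 0.0
    return g


# ------------------------------------------------------------- beat picking

def detect_beats(
    ppg: PhysioTrace,
    *,
    min_separation_s: float = 0.3,
    height_fraction: float = 0.25,
) -> np.ndarray:
    """Detect beat times (s) from a pulse-oximeter trace.

    Local maxima separated by at least ``min_separation_s`` are gated by an
    adaptive amplitude threshold placed ``height_fraction`` of the way from
    the signal baseline (median) to the systolic amplitude (98th
    percentile).  The quantile-based gate discards low-amplitude spurious
    maxima between beats regardless of how tightly the true beat heights
    cluster.
    """
    if ppg.modality != "cardiac":
        raise InputError("beat detection requires a cardiac trace")
    if ppg.fs < 50:
        raise InputError(f"pulse trace sampling rate {ppg.fs} Hz < 50 Hz")
    x = ppg.samples
    if x.std() < 1e-12:
        raise SignalQualityError("flat-line pulse trace; no beats detectable")
    baseline = float(np.median(x))
    amplitude = float(np.percentile(x, 98))
    thr = baseline + height_fraction * (amplitude - baseline)
    dist = max(1, int(round(min_separation_s * ppg.fs)))
    peaks, _ = signal.find_peaks(x, distance=dist, height=thr)
    if peaks.size < 2:
        raise SignalQualityError(
            f"only {peaks.size} beats detected; signal quality too poor"
        )
    return ppg.start_time + peaks / ppg.fs


def beats_to_heart_rate(
    beat_times: np.ndarray,
    *,
    hampel_window: int = 11,
    hampel_n_mad: float = 3.0,
) -> HeartRateSeries:
    """Convert beat times to an outlier-cleaned 10 Hz heart-rate series.

    Each inter-beat interval (IBI) contributes the value ``60 / IBI`` bpm at
    the interval midpoint; spurious values (missed/extra beats) are replaced
    with the local windowed median (Hampel rule), and the result is
    interpolated to a uniform 0.1 s grid with a shape-preserving piecewise
    cubic (PCHIP), which cannot overshoot the data.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 2:
        raise InputError("need at least 2 beats to form a heart-rate series")
    if np.any(np.diff(t) <= 0):
        raise InputError("beat times must be strictly increasing")
    ibi = np.diff(t)
    hr = 60.0 / ibi
    hr = hampel(hr, window=hampel_window, n_mad=hampel_n_mad)
    mid = 0.5 * (t[:-1] + t[1:])
    grid = mid[0] + np.arange(0, mid[-1] - mid[0] + 1e-9, 1 / PRF_GRID_FS)
    if mid.size >= 2:
        vals = interpolate.PchipInterpolator(mid, hr)(grid)
    else:  # pragma: no cover - guarded by t.size check
        vals = np.full(grid.size, hr[0])
    return HeartRateSeries(values=vals, t0=float(grid[0]))


# --------------------------------------------------------- respiratory flow

def compute_respiratory_flow(
    resp: PhysioTrace,
    *,
    smooth_window_s: float = 1.5,
    lowpass_hz: float = 5.0,
) -> RespiratoryFlowSeries:
    """Respiratory flow: squared derivative of the cleaned belt signal.

    Processing order: linear detrend, Hampel outlier replacement, 5 Hz
    low-pass, z-score, 1.5 s moving average, time derivative, square, and
    resampling to 10 Hz.  The square makes the result invariant to the sign
    convention of the belt.
    """
    if resp.modality != "respiratory":
        raise InputError("respiratory flow requires a respiratory trace")
    x = signal.detrend(resp.samples, type="linear")
    x = hampel(x, window=11, n_mad=3.0) if x.size <= 200_000 else _hampel_fast(x)
    if lowpass_hz < resp.fs / 2:
        x = lowpass(x, lowpass_hz, resp.fs)
    x = zscore(x, name="breathing signal")
    x = moving_average(x, max(1, int(round(smooth_window_s * resp.fs))))
    flow = np.gradient(x) * resp.fs
    flow = flow**2
    # flow is slow after smoothing; decimate by interpolation onto 10 Hz
    t_in = np.arange(flow.size) / resp.fs
    t_out = np.arange(0, t_in[-1] + 1e-9, 1 / PRF_GRID_FS)
    vals = np.interp(t_out, t_in, flow)
    return RespiratoryFlowSeries(values=vals, t0=resp.start_time)


def _hampel_fast(x: np.ndarray, window: int = 11, n_mad: float = 3.0) -> np.ndarray:
    """Strided Hampel for long traces (interior points only)."""
    from numpy.lib.stride_tricks import sliding_window_view

    half = window // 2
    out = x.copy()
    win = sliding_window_view(x, window)
    med = np.median(win, axis=1)
    dev = np.median(np.abs(win - med[:, None]), axis=1)
    centre = x[half: half + med.size]
    bad = np.abs(centre - med) > n_mad * dev
    out[half: half + med.size][bad] = med[bad]
    return out


# ------------------------------------------------------------ PRF estimation

def _grid_series(series, n10: int, name: str) -> np.ndarray:
    """Z-scored copy of a 10 Hz series, trimmed/edge-padded to n10 samples."""
    v = np.asarray(series.values if hasattr(series, "values") else series,
                   dtype=float)
    if v.std() < 1e-12:
        raise InputError(f"{name} series is constant; PRF fit is degenerate")
    if v.size < n10:
        v = np.concatenate([v, np.full(n10 - v.size, v[-1])])
    return zscore(v[:n10], name=name)


def _convolved_regressors(hr10, rf10, theta, kernel_grid, vol_idx, keep):
    """Four PRF-basis regressors sampled at the kept volume times.

    Input series are padded at the start by holding their first value for
    one kernel length, so onset transients do not dominate the fit.
    """
    npad = kernel_grid.size - 1
    cols = []
    for x, (ttp, tau) in (
        (hr10, theta[0:2]), (hr10, theta[2:4]),
        (rf10, theta[4:6]), (rf10, theta[6:8]),
    ):
        g = gamma_kernel(ttp, tau, kernel_grid)
        xp = np.concatenate([np.full(npad, x[0]), x])
        c = signal.oaconvolve(xp, g)[npad: npad + x.size]
        cols.append(c[vol_idx])
    X = np.stack(cols, axis=1)
    return X[keep]


def estimate_prfs(
    hr: HeartRateSeries,
    rf: RespiratoryFlowSeries,
    gs: np.ndarray,
    tr: float,
    censor_mask: np.ndarray | None = None,
    *,
    maxiter: int = 80,
) -> PRFPair:
    """Estimate cardiac and respiratory PRFs from the global signal.

    The gamma shape parameters maximise the Pearson correlation between
    ``hr * prf_c + rf * prf_r`` (evaluated at the kept volume times) and the
    observed global signal; amplitudes are profiled out by OLS.
    """
    gs = np.asarray(gs, dtype=float)
    if censor_mask is None:
        keep = np.ones(gs.size, dtype=bool)
        n_vol = gs.size
    else:
        keep = np.asarray(censor_mask, dtype=bool)
        n_vol = keep.size
        if gs.size == n_vol:
            gs = gs[keep]
        elif gs.size != int(keep.sum()):
            raise InputError("global signal length matches neither T nor T'")
    if gs.std() < 1e-12:
        raise InputError("global signal is constant")

    n10 = int(round(n_vol * tr * PRF_GRID_FS))
    hr10 = _grid_series(hr, n10, "heart-rate")
    rf10 = _grid_series(rf, n10, "respiratory-flow")
    kernel_grid = np.arange(0, PRF_SUPPORT_S + 1e-9, 1 / PRF_GRID_FS)
    vol_idx = np.minimum(
        np.round(np.arange(n_vol) * tr * PRF_GRID_FS).astype(int), n10 - 1
    )
    keep_idx = keep
    gsz = zscore(gs, name="global signal")

    ones = np.ones(gsz.size)

    def neg_r(theta: np.ndarray) -> float:
        X = _convolved_regressors(hr10, rf10, theta, kernel_grid, vol_idx, keep_idx)
        A = np.column_stack([ones, X])
        coef, *_ = np.linalg.lstsq(A, gsz, rcond=None)
        fit = A @ coef
        sd = fit.std()
        if sd < 1e-12:
            return 1.0
        return -float(np.corrcoef(fit, gsz)[0, 1])

    bounds = [_TTP_BOUNDS, _TAU_BOUNDS] * 4
    best = None
    for start in _STARTS:
        try:
            res = optimize.minimize(
                neg_r, np.asarray(start), bounds=bounds, method="L-BFGS-B",
                options={"maxiter": maxiter, "eps": 1e-3},
            )
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("PRF optimisation failed on every start point")

    theta = best.x
    X = _convolved_regressors(hr10, rf10, theta, kernel_grid, vol_idx, keep_idx)
    A = np.column_stack([ones, X])
    coef, *_ = np.linalg.lstsq(A, gsz, rcond=None)
    g = [gamma_kernel(theta[2 * i], theta[2 * i + 1], kernel_grid) for i in range(4)]
    cardiac_curve = coef[1] * g[0] + coef[2] * g[1]
    resp_curve = coef[3] * g[2] + coef[4] * g[3]
    return PRFPair(
        cardiac_params=np.array([theta[0], theta[1], coef[1],
                                 theta[2], theta[3], -coef[2]]),
        respiratory_params=np.array([theta[4], theta[5], coef[3],
                                     theta[6], theta[7], -coef[4]]),
        cardiac_curve=cardiac_curve,
        respiratory_curve=resp_curve,
        fit_r=-float(best.fun),
        tau_grid=kernel_grid,
    )


# ------------------------------------------------------------ SLFO building

def convolve_at_volumes(
    series10: np.ndarray,
    kernel: np.ndarray,
    tr: float,
    n_volumes: int,
) -> np.ndarray:
    """Convolve a 10 Hz series with a kernel and read out at volume times.

    The series is padded at the start by holding its first value for one
    kernel length (onset-transient suppression).
    """
    npad = kernel.size - 1
    xp = np.concatenate([np.full(npad, series10[0]), series10])
    c = signal.oaconvolve(xp, kernel)[npad: npad + series10.size]
    idx = np.minimum(
        np.round(np.arange(n_volumes) * tr * PRF_GRID_FS).astype(int),
        series10.size - 1,
    )
    return c[idx]


def build_slfo(
    hr: HeartRateSeries,
    rf: RespiratoryFlowSeries,
    prfs: PRFPair,
    tr: float,
    n_volumes: int,
    censor_mask: np.ndarray | None = None,
) -> RegressorSeries:
    """Combined SLFO regressor: HR and flow convolved with their PRFs.

    Both inputs are z-scored at 10 Hz, convolved, summed, sampled at the
    volume times, censored, and z-scored.  All-zero PRFs yield a constant
    output and raise :class:`DegenerateSignalError`.
    """
    n10 = int(round(n_volumes * tr * PRF_GRID_FS))
    hr10 = _grid_series(hr, n10, "heart-rate")
    rf10 = _grid_series(rf, n10, "respiratory-flow")
    total = (
        convolve_at_volumes(hr10, prfs.cardiac_curve, tr, n_volumes)
        + convolve_at_volumes(rf10, prfs.respiratory_curve, tr, n_volumes)
    )
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.size != n_volumes:
            raise InputError("censor mask length does not match volume count")
        total = total[censor_mask]
    if total.std() < 1e-12:
        raise DegenerateSignalError("SLFO series is constant (zero PRFs?)")
    return RegressorSeries(values=zscore(total, name="slfo"), name="slfo", tr=tr)
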