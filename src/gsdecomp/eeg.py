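"""EEG band-power extraction and conversion to BOLD-resolution regressors.

Channel-level EEG (assumed artifact-corrected and downsampled to ~200 Hz)
is decomposed with an analytic Morlet continuous wavelet transform on a
log-spaced frequency grid (10 voices per octave).  Channel power
spectrograms are pooled by root-mean-square, averaged inside canonical
frequency bands, convolved with a canonical double-gamma haemodynamic
response function (HRF), and sampled at the fMRI volume times.

The Morlet centre-frequency constant defaults to the conventional
``omega0 = 6``; it is exposed as a parameter because small changes trade
temporal against spectral resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from .datatypes import RegressorSeries
from .errors import InputError
from .filters import lowpass, zscore

__all__ = [
    "Spectrogram",
    "BandDefinition",
    "DEFAULT_BANDS",
    "cwt_spectrogram",
    "global_spectrogram",
    "band_power_series",
    "canonical_hrf",
    "to_bold_regressor",
]


@dataclass
class Spectrogram:
    """Time-frequency power (squared CWT magnitude), F x T."""

    power: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.power.shape != (self.freqs_hz.size, self.times_s.size):
            raise InputError("power shape does not match frequency/time grids")
        if np.any(self.power < 0):
            raise InputError("spectrogram power must be non-negative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise InputError("frequency grid must be strictly increasing")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise InputError(
                f"band {self.name}: need 0 < lo < hi, got ({self.lo_hz}, {self.hi_hz})"
            )


DEFAULT_BANDS = (
    BandDefinition("delta", 1.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 15.0),
    BandDefinition("beta", 15.0, 26.0),
)


def _morlet_name(w0: float) -> str:
    # pywt's cmorB-C wavelet: psi(t) ~ exp(2i*pi*C*t) exp(-t^2/B).  The
    # classic Morlet with angular centre frequency w0 has unit time std,
    # i.e. B = 2 and C = w0 / (2*pi).
    return f"cmor2.0-{w0 / (2 * np.pi):.6f}"


def _frequency_grid(f_min: float, f_max: float, voices: int) -> np.ndarray:
    n_oct = np.log2(f_max / f_min)
    exps = np.arange(0, int(np.floor(n_oct * voices)) + 1)
    return f_min * 2.0 ** (exps / voices)


def cwt_spectrogram(
    channel: np.ndarray,
    fs: float,
    *,
    f_min: float = 1.0,
    f_max: float = 40.0,
    voices_per_octave: int = 10,
    w0: float = 6.0,
) -> Spectrogram:
    """Squared-magnitude Morlet CWT of one channel on a log frequency grid.

    Raises
    ------
    InputError
        If the signal is shorter than the support of the longest (lowest
        frequency) wavelet, taken as 8 periods of ``f_min``.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise InputError("channel must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise InputError("channel contains non-finite samples")
    min_len = int(np.ceil(8 * fs / f_min))
    if x.size < min_len:
        raise InputError(
            f"signal of {x.size} samples shorter than longest wavelet "
            f"support ({min_len} samples at f_min = {f_min} Hz)"
        )
    wavelet = _morlet_name(w0)
    freqs = _frequency_grid(f_min, f_max, voices_per_octave)
    # map frequencies to scales through the discretised wavelet's measured
    # centre frequency so the output grid is exact
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2
    # pywt returns rows ordered like `scales` (descending frequency here
    # would require reversal; our scales are descending <=> freqs ascending)
    return Spectrogram(
        power=power,
        freqs_hz=freqs,
        times_s=np.arange(x.size) / fs,
        fs=fs,
    )


def global_spectrogram(per_channel: list[Spectrogram]) -> Spectrogram:
    """Entrywise root-mean-square across channel power spectrograms."""
    if not per_channel:
        raise InputError("need at least one channel spectrogram")
    ref = per_channel[0]
    for sp in per_channel[1:]:
        if (
            sp.power.shape != ref.power.shape
            or not np.allclose(sp.freqs_hz, ref.freqs_hz)
            or not np.allclose(sp.times_s, ref.times_s)
        ):
            raise InputError("channel spectrograms have mismatched grids")
    stack = np.stack([sp.power for sp in per_channel])
    return Spectrogram(
        power=np.sqrt(np.mean(stack**2, axis=0)),
        freqs_hz=ref.freqs_hz.copy(),
        times_s=ref.times_s.copy(),
        fs=ref.fs,
    )


def band_power_series(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    """Mean spectrogram power across bins with lo <= f <= hi, per time point."""
    f = spec.freqs_hz
    if band.lo_hz < f[0] - 1e-9 or band.hi_hz > f[-1] + 1e-9:
        raise InputError(
            f"band {band.name} ({band.lo_hz}-{band.hi_hz} Hz) exceeds "
            f"spectrogram range ({f[0]:.3g}-{f[-1]:.3g} Hz)"
        )
    sel = (f >= band.lo_hz) & (f <= band.hi_hz)
    if not np.any(sel):
        raise InputError(f"band {band.name} contains no frequency bins")
    return spec.power[sel].mean(axis=0)


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds.

    Response peak at 6 s, undershoot peak at 16 s, undershoot ratio 1/6;
    normalised to unit peak.
    """
    t = np.arange(0, duration + dt / 2, dt)
    # shapes chosen so the summed curve peaks at 6 s with its undershoot
    # trough at 16 s (the undershoot gamma alone would trough later)
    h = stats.gamma.pdf(t, a=7.0, scale=1.0) - stats.gamma.pdf(t, a=15.5, scale=1.0) / 6.0
    return h / h.max()


def to_bold_regressor(
    power: np.ndarray,
    fs: float,
    tr: float,
    n_volumes: int,
    censor_mask: np.ndarray | None = None,
    *,
    name: str = "alpha",
    antialias_hz: float = 0.2,
) -> RegressorSeries:
    """HRF-convolve a band-power series and sample it at the volume times.

    The convolved series is zero-phase low-pass filtered at ``antialias_hz``
    (safely below the volume-sampling Nyquist rate) before being read out at
    ``t = k * tr``; censored frames are then removed and the remainder
    z-scored.  A constant power input yields the LTI steady state and is
    rejected as degenerate by the z-scoring step.
    """
    x = np.asarray(power, dtype=float)
    if x.ndim != 1:
        raise InputError("power series must be one-dimensional")
    scan_len = n_volumes * tr
    if x.size / fs < scan_len - tr:
        raise InputError(
            f"power series covers {x.size / fs:.1f} s < scan {scan_len:.1f} s"
        )
    h = canonical_hrf(1.0 / fs)
    # hold the first value for one kernel length so onset transients do
    # not leak into the scan (and a constant input stays exactly constant)
    npad = h.size - 1
    xp = np.concatenate([np.full(npad, x[0]), x])
    conv = np.convolve(xp, h)[npad: npad + x.size]
    if antialias_hz and antialias_hz < fs / 2:
        conv = lowpass(conv, antialias_hz, fs)
    idx = np.minimum(np.round(np.arange(n_volumes) * tr * fs).astype(int), x.size - 1)
    at_tr = conv[idx]
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.size != n_volumes:
            raise InputError("censor mask length does not match volume count")
        at_tr = at_tr[censor_mask]
    return RegressorSeries(values=zscore(at_tr, name=f"{name} regressor"),
                           name=name, tr=tr)
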