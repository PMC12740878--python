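"""Synthetic EEG-fMRI cohorts with known ground truth.

The generator emulates the statistical structure the decomposition
analysis assumes: ~15-minute scans at TR = 2.12 s in which

* heart rate carries slow (0.01-0.15 Hz) fluctuations around a resting
  baseline, and breathing is a quasi-sinusoid with slowly modulated depth
  and rate;
* the systemic component (SLFO) of every ROI is the heart-rate and
  respiratory-flow series convolved with fixed "true" double-gamma
  physiological response functions;
* EEG band power is a positive log-normal slow process per band, whose
  HRF-convolved regressor enters the BOLD data with a per-ROI coupling;
  the alpha/beta couplings have a controlled (weakly negative by default)
  network-wide mean, while regional deviations around that mean sum to
  zero, so the global-signal coupling equals the configured target while
  regional couplings of both signs remain (mirroring the polarity
  cancellation seen empirically);
* within-network latent factors give block-structured neural covariance,
  a slow spatially-uniform nuisance adds unexplained global variance, and
  per-ROI AR(1) noise fills the remainder;
* white-matter channels carry lagged copies of the SLFO plus shared
  non-neural latents, so WM-PCA denoising removes the systemic component
  only partially (as it does in practice), leaving room for GSR to act;
* motion is a smooth drift plus Poisson-placed displacement spikes whose
  frames are recorded as ground truth for the censoring tests.

Everything is deterministic given ``(spec, seed)``; subjects draw from
independent substreams spawned from the cohort seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .datatypes import PhysioTrace, RoiDataset
from .eeg import to_bold_regressor
from .errors import InputError
from .filters import bandpass, zscore
from .physio import PRF_GRID_FS, convolve_at_volumes, gamma_kernel

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectData",
    "true_prf_curves",
    "gen_heart_rate",
    "gen_breathing",
    "gen_eeg_power",
    "gen_motion",
    "gen_subject",
    "gen_cohort",
    "write_cohort",
    "BAND_BASELINES",
]

#: "true" generative PRF parameters (ttp1, tau1, a1, ttp2, tau2, a2)
TRUE_CARDIAC_PRF = (3.5, 1.2, 1.0, 11.0, 2.5, 0.5)
TRUE_RESP_PRF = (2.5, 1.0, 1.0, 8.0, 2.0, 0.8)

#: arbitrary band-power baselines (a.u.); delta largest, beta smallest
BAND_BASELINES = {"delta": 20.0, "theta": 10.0, "alpha": 8.0, "beta": 4.0}

_BOLD_BASELINE = 100.0  # arbitrary; every analysis stage is shift-invariant


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    The defaults mirror the desk-scale study conditions: 11 subjects,
    15-minute scans (T = 425 volumes at TR = 2.12 s), 30 ROIs in 5
    networks, resting heart rate ~70 bpm with 3 bpm slow variability,
    breathing at 0.3 Hz, and a weak negative alpha/beta-to-global-signal
    coupling targeting a partial correlation of about -0.1.
    """

    n_subjects: int = 11
    n_rois: int = 30
    n_networks: int = 5
    n_volumes: int = 425
    tr: float = 2.12
    hr_baseline: float = 70.0       # bpm
    hr_lf_sd: float = 3.0           # bpm, slow-fluctuation amplitude
    resp_rate: float = 0.3          # Hz
    resp_amp_mod: float = 0.25      # breathing-depth modulation depth
    resp_rate_mod: float = 0.1      # breathing-rate modulation depth
    coupling_eeg_gs: float = -0.1   # target partial r of alpha/beta with gs
    motion_spike_rate: float = 3.0  # expected spikes per scan
    motion_spike_fd: float = 0.6    # mm
    seed: int = 0
    # signal-composition parameters
    beta_slfo_mean: float = 1.0
    beta_sd: float = 0.7            # per-ROI spread of all couplings
    latent_strength: float = 0.4    # within-network factor loading
    noise_sd: float = 0.85
    noise_ar1: float = 0.3
    global_nuisance_sd: float = 0.3
    eeg_power_sigma: float = 0.4    # log-amplitude of band-power fluctuations
    # white-matter channel composition
    n_wm_channels: int = 30
    wm_slfo_gain: float = 0.8
    wm_max_lag_s: float = 4.0
    wm_n_latents: int = 5
    wm_latent_sd: float = 0.8
    wm_noise_sd: float = 0.8
    physio_fs: float = 1000.0       # Hz, raw physio sampling rate

    def __post_init__(self) -> None:
        positive = (
            "n_subjects", "n_rois", "n_networks", "n_volumes", "tr",
            "hr_baseline", "resp_rate", "noise_sd", "physio_fs",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InputError(f"CohortSpec.{name} must be positive")
        if self.n_rois % self.n_networks != 0:
            raise InputError("n_rois must divide evenly into n_networks")
        for name in ("hr_lf_sd", "motion_spike_rate", "latent_strength",
                     "global_nuisance_sd", "eeg_power_sigma", "beta_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"CohortSpec.{name} must be non-negative")

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr

    @property
    def n10(self) -> int:
        """Samples on the 10 Hz physiological grid covering the scan."""
        return int(round(self.scan_duration * PRF_GRID_FS))

    def network_of(self, roi: int) -> int:
        return roi // (self.n_rois // self.n_networks)

    @property
    def network_labels(self) -> list[str]:
        return [f"net{self.network_of(i)}" for i in range(self.n_rois)]

    @property
    def roi_ids(self) -> list[str]:
        return [f"roi{i:03d}" for i in range(self.n_rois)]


@dataclass
class GroundTruth:
    """Generative parameters stored alongside every synthetic subject."""

    betas: np.ndarray                   # N x 3: (slfo, alpha, beta)
    prf_cardiac: np.ndarray             # curve on the 0-60 s grid at 10 Hz
    prf_respiratory: np.ndarray
    network_assignments: dict[str, str]
    latent_strength: float
    noise_sd: np.ndarray                # per ROI
    seed: int

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k in ("betas", "prf_cardiac", "prf_respiratory", "noise_sd"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SubjectData:
    """Everything generated for one synthetic subject."""

    roi: RoiDataset
    motion: np.ndarray                  # T x 6
    spike_frames: np.ndarray
    wm: np.ndarray                      # T x M
    band_power: dict[str, np.ndarray]   # TR-locked, length T, positive
    regressors: dict[str, np.ndarray]   # full-length z-scored, length T
    truth: GroundTruth
    cardiac: PhysioTrace | None = None
    respiratory: PhysioTrace | None = None


def true_prf_curves(grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """The generative cardiac and respiratory PRF impulse responses."""
    def curve(params):
        ttp1, tau1, a1, ttp2, tau2, a2 = params
        return a1 * gamma_kernel(ttp1, tau1, grid) - a2 * gamma_kernel(ttp2, tau2, grid)

    return curve(TRUE_CARDIAC_PRF), curve(TRUE_RESP_PRF)


def _slow_noise(rng: np.random.Generator, n: int, lo: float, hi: float,
                fs: float = PRF_GRID_FS) -> np.ndarray:
    """Band-limited unit-variance Gaussian noise (edge-padded filtering)."""
    pad = max(2000, int(2 * fs / lo))
    x = rng.standard_normal(n + 2 * pad)
    y = bandpass(x, lo, hi, fs)[pad: pad + n]
    return zscore(y)


# ------------------------------------------------------------- physiology

def gen_heart_rate(spec: CohortSpec, seed_or_rng) -> np.ndarray:
    """Heart rate (bpm) on the 10 Hz grid: baseline + 0.01-0.15 Hz noise."""
    rng = _as_rng(seed_or_rng)
    n = spec.n10
    if spec.hr_lf_sd == 0:
        return np.full(n, spec.hr_baseline)
    hr = spec.hr_baseline + spec.hr_lf_sd * _slow_noise(rng, n, 0.01, 0.15)
    return np.clip(hr, 32.0, 218.0)


def _breathing_modulators(spec: CohortSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """(amplitude, rate) of the breathing quasi-sinusoid on the 10 Hz grid."""
    n = spec.n10
    if spec.resp_amp_mod == 0 and spec.resp_rate_mod == 0:
        return np.ones(n), np.full(n, spec.resp_rate)
    amp = 1.0 + spec.resp_amp_mod * np.clip(_slow_noise(rng, n, 0.01, 0.05), -2.5, 2.5)
    rate = spec.resp_rate * (
        1.0 + spec.resp_rate_mod * np.clip(_slow_noise(rng, n, 0.01, 0.05), -2.5, 2.5)
    )
    return np.clip(amp, 0.1, None), np.clip(rate, 0.05, None)


def _breathing_trace(spec: CohortSpec, amp10, rate10, rng) -> PhysioTrace:
    fs = spec.physio_fs
    n = int(round(spec.scan_duration * fs))
    t10 = np.arange(spec.n10) / PRF_GRID_FS
    t = np.arange(n) / fs
    amp = np.interp(t, t10, amp10)
    rate = np.interp(t, t10, rate10)
    phase = 2 * np.pi * np.cumsum(rate) / fs
    x = amp * np.sin(phase) + 0.02 * rng.standard_normal(n)
    return PhysioTrace(samples=x, fs=fs, modality="respiratory")


def gen_breathing(spec: CohortSpec, seed_or_rng) -> PhysioTrace:
    """Respiratory-belt trace: modulated sinusoid at ``resp_rate``."""
    rng = _as_rng(seed_or_rng)
    amp10, rate10 = _breathing_modulators(spec, rng)
    return _breathing_trace(spec, amp10, rate10, rng)


def _true_respiratory_flow(amp10: np.ndarray, rate10: np.ndarray) -> np.ndarray:
    """Ground-truth flow on the 10 Hz grid: (d/dt breathing)^2 envelope."""
    phase = 2 * np.pi * np.cumsum(rate10) / PRF_GRID_FS
    return (amp10 * 2 * np.pi * rate10 * np.cos(phase)) ** 2


def _cardiac_trace(spec: CohortSpec, hr10: np.ndarray, rng) -> PhysioTrace:
    """Pulse-oximeter-like waveform whose peak times follow ``hr10``."""
    fs = spec.physio_fs
    n = int(round(spec.scan_duration * fs))
    t10 = np.arange(spec.n10) / PRF_GRID_FS
    t = np.arange(n) / fs
    hr = np.interp(t, t10, hr10)
    phase = 2 * np.pi * np.cumsum(hr / 60.0) / fs
    # peaked periodic waveform (von-Mises-like) + measurement noise
    x = np.exp(4.0 * (np.cos(phase) - 1.0)) + 0.01 * rng.standard_normal(n)
    return PhysioTrace(samples=x, fs=fs, modality="cardiac")


# -------------------------------------------------------------- EEG power

def gen_eeg_power(spec: CohortSpec, seed_or_rng) -> dict[str, np.ndarray]:
    """Positive TR-locked band-power series for delta/theta/alpha/beta.

    Each band is an independent log-normal slow process; how strongly the
    alpha/beta regressors load (negatively) on the BOLD global component
    is controlled downstream by :func:`gen_subject` through
    ``coupling_eeg_gs``.
    """
    rng = _as_rng(seed_or_rng)
    vol_idx = np.minimum(
        np.round(np.arange(spec.n_volumes) * spec.tr * PRF_GRID_FS).astype(int),
        spec.n10 - 1,
    )
    out = {}
    for band, base in BAND_BASELINES.items():
        u = _slow_noise(rng, spec.n10, 0.01, 0.1)[vol_idx]
        out[band] = base * np.exp(spec.eeg_power_sigma * zscore(u))
    return out


# ------------------------------------------------------------------ motion

def gen_motion(spec: CohortSpec, seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Motion parameters (T x 6) with smooth drift plus injected spikes.

    Returns ``(motion, spike_frames)``; each spike is a one-frame
    displacement of ``motion_spike_fd`` mm on the x-translation, which
    produces FD exceedances at the spike frame and its successor.
    """
    rng = _as_rng(seed_or_rng)
    t = spec.n_volumes
    drift = np.cumsum(rng.normal(0.0, 0.003, size=(t, 6)), axis=0)
    drift[:, 3:] *= 1e-2 / 50.0  # rotations: keep FD contribution tiny
    motion = drift
    n_spikes = rng.poisson(spec.motion_spike_rate)
    frames = np.array([], dtype=int)
    if n_spikes > 0 and t > 6:
        frames = np.unique(rng.integers(2, t - 3, size=n_spikes))
        motion[frames, 0] += spec.motion_spike_fd
    return motion, frames


# ------------------------------------------------------------ white matter

def _gen_wm(spec: CohortSpec, rng, slfo10: np.ndarray) -> np.ndarray:
    """WM channels: lagged SLFO copies + shared latents + channel noise."""
    t, m = spec.n_volumes, spec.n_wm_channels
    vol_idx = np.minimum(
        np.round(np.arange(t) * spec.tr * PRF_GRID_FS).astype(int),
        spec.n10 - 1,
    )
    lags = rng.uniform(0.0, spec.wm_max_lag_s, size=m)
    latents = np.column_stack(
        [_slow_noise(rng, t, 0.01, 0.1, fs=1.0 / spec.tr)
         for _ in range(spec.wm_n_latents)]
    ) if spec.wm_n_latents else np.zeros((t, 0))
    loadings = rng.normal(0.0, spec.wm_latent_sd, size=(spec.wm_n_latents, m))
    wm = np.empty((t, m))
    for j in range(m):
        shift = int(round(lags[j] * PRF_GRID_FS))
        lagged = np.concatenate([np.full(shift, slfo10[0]), slfo10])[: spec.n10]
        wm[:, j] = spec.wm_slfo_gain * zscore(lagged[vol_idx])
    wm += latents @ loadings
    wm += rng.normal(0.0, spec.wm_noise_sd, size=(t, m))
    return wm


# --------------------------------------------------------------- subjects

def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def coupling_loading(spec: CohortSpec) -> float:
    """Uniform alpha/beta BOLD loading that realises the target partial r.

    After controlling for the SLFO and the other band, the residual
    global-signal variance is (analytically, with unit-variance z-scored
    regressors) the within-network latent mean, the noise mean, and the
    uniform nuisance:  v = l^2/K + sigma^2/N + g^2.  The loading ``c``
    with ``r = c / sqrt(c^2 + v)`` then hits the requested coupling.
    """
    r = spec.coupling_eeg_gs
    if r == 0:
        return 0.0
    if not -1 < r < 1:
        raise InputError("coupling_eeg_gs must lie in (-1, 1)")
    v_rest = (
        spec.latent_strength**2 / spec.n_networks
        + spec.noise_sd**2 / spec.n_rois
        + spec.global_nuisance_sd**2
    )
    return np.sign(r) * abs(r) * np.sqrt(v_rest / (1 - r**2))


def _ar1_noise(rng, phi: float, shape: tuple[int, int]) -> np.ndarray:
    from scipy.signal import lfilter

    e = rng.standard_normal(shape)
    x = lfilter([1.0], [1.0, -phi], np.sqrt(1 - phi**2) * e, axis=0)
    x[0] = e[0]  # stationary start (unit marginal variance)
    return x


def gen_subject(
    spec: CohortSpec,
    subject_index: int,
    *,
    raw_physio: bool = True,
    scan_id: str = "rest1",
) -> SubjectData:
    """Generate one subject: BOLD, physiology, EEG power, motion, WM, truth."""
    if not 0 <= subject_index:
        raise InputError("subject_index must be non-negative")
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_index,))
    (ss_hr, ss_resp, ss_eeg, ss_motion, ss_beta,
     ss_latent, ss_noise, ss_wm, ss_gnuis) = ss.spawn(9)
    rng_hr, rng_resp = map(np.random.default_rng, (ss_hr, ss_resp))

    t, n = spec.n_volumes, spec.n_rois

    # --- physiological ground truth and the SLFO regressor
    hr10 = gen_heart_rate(spec, rng_hr)
    amp10, rate10 = _breathing_modulators(spec, rng_resp)
    rf10 = _true_respiratory_flow(amp10, rate10)
    prf_c, prf_r = true_prf_curves()
    slfo_at_vol = (
        convolve_at_volumes(zscore(hr10), prf_c, spec.tr, t)
        + convolve_at_volumes(zscore(rf10), prf_r, spec.tr, t)
    )
    x_slfo = zscore(slfo_at_vol)
    # 10 Hz SLFO (pre-sampling) reused for the WM channels
    kernel_pad = prf_c.size - 1
    slfo10 = (
        np.convolve(np.concatenate([np.full(kernel_pad, zscore(hr10)[0]),
                                    zscore(hr10)]), prf_c)[kernel_pad: kernel_pad + spec.n10]
        + np.convolve(np.concatenate([np.full(kernel_pad, zscore(rf10)[0]),
                                      zscore(rf10)]), prf_r)[kernel_pad: kernel_pad + spec.n10]
    )

    # --- EEG band power and its BOLD-resolution regressors
    powers = gen_eeg_power(spec, np.random.default_rng(ss_eeg))
    regressors: dict[str, np.ndarray] = {"slfo": x_slfo}
    for band, p in powers.items():
        regressors[band] = to_bold_regressor(
            p, fs=1.0 / spec.tr, tr=spec.tr, n_volumes=t, name=band
        ).values

    # --- couplings: slfo spread freely, alpha/beta spread centred so the
    #     subject's network-wide mean equals the configured loading exactly
    rng_beta = np.random.default_rng(ss_beta)
    c_band = coupling_loading(spec)
    b_slfo = spec.beta_slfo_mean + spec.beta_sd * rng_beta.standard_normal(n)
    dev_a = spec.beta_sd * rng_beta.standard_normal(n)
    dev_b = spec.beta_sd * rng_beta.standard_normal(n)
    b_alpha = c_band + dev_a - dev_a.mean()
    b_beta = c_band + dev_b - dev_b.mean()

    # --- structured + unstructured residual signal
    rng_latent = np.random.default_rng(ss_latent)
    latents = np.column_stack(
        [_slow_noise(rng_latent, t, 0.01, 0.2, fs=1.0 / spec.tr)
         for _ in range(spec.n_networks)]
    )
    loadings = np.zeros((spec.n_networks, n))
    for i in range(n):
        loadings[spec.network_of(i), i] = spec.latent_strength
    gnuis = spec.global_nuisance_sd * _slow_noise(
        np.random.default_rng(ss_gnuis), t, 0.01, 0.2, fs=1.0 / spec.tr
    )
    noise = spec.noise_sd * _ar1_noise(
        np.random.default_rng(ss_noise), spec.noise_ar1, (t, n)
    )

    bold = (
        _BOLD_BASELINE
        + np.outer(x_slfo, b_slfo)
        + np.outer(regressors["alpha"], b_alpha)
        + np.outer(regressors["beta"], b_beta)
        + latents @ loadings
        + gnuis[:, None]
        + noise
    )

    motion, spikes = gen_motion(spec, np.random.default_rng(ss_motion))
    wm = _gen_wm(spec, np.random.default_rng(ss_wm), slfo10)

    subject_id = f"sub-{subject_index:02d}"
    roi = RoiDataset(
        data=bold,
        tr=spec.tr,
        roi_ids=spec.roi_ids,
        network_labels=spec.network_labels,
        subject_id=subject_id,
        scan_id=scan_id,
    )
    truth = GroundTruth(
        betas=np.column_stack([b_slfo, b_alpha, b_beta]),
        prf_cardiac=prf_c,
        prf_respiratory=prf_r,
        network_assignments=dict(zip(spec.roi_ids, spec.network_labels)),
        latent_strength=spec.latent_strength,
        noise_sd=np.full(n, spec.noise_sd),
        seed=spec.seed,
    )
    cardiac = respiratory = None
    if raw_physio:
        cardiac = _cardiac_trace(spec, hr10, rng_hr)
        respiratory = _breathing_trace(spec, amp10, rate10, rng_resp)
    return SubjectData(
        roi=roi,
        motion=motion,
        spike_frames=spikes,
        wm=wm,
        band_power=powers,
        regressors=regressors,
        truth=truth,
        cardiac=cardiac,
        respiratory=respiratory,
    )


def gen_cohort(
    spec: CohortSpec, *, raw_physio: bool = True, scan_id: str = "rest1"
) -> list[SubjectData]:
    """All subjects of a cohort (independent substreams of ``spec.seed``)."""
    return [
        gen_subject(spec, i, raw_physio=raw_physio, scan_id=scan_id)
        for i in range(spec.n_subjects)
    ]


def write_cohort(cohort: list[SubjectData], out_dir: str | Path) -> None:
    """Write per-subject files in the package's TSV formats + ground truth."""
    from . import io as gio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_all = {}
    for subj in cohort:
        sid = subj.roi.subject_id
        gio.write_roi_dataset(subj.roi, out / f"{sid}_bold.tsv")
        pd.DataFrame(
            subj.motion,
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        ).to_csv(out / f"{sid}_motion.tsv", sep="\t", index=False)
        pd.DataFrame(subj.wm).to_csv(
            out / f"{sid}_wm.tsv", sep="\t", index=False
        )
        pd.DataFrame(subj.band_power).to_csv(
            out / f"{sid}_bandpower.tsv", sep="\t", index=False
        )
        if subj.cardiac is not None:
            gio.write_physio(subj.cardiac, out / f"{sid}_cardiac.tsv.gz")
        if subj.respiratory is not None:
            gio.write_physio(subj.respiratory, out / f"{sid}_resp.tsv.gz")
        truth_all[sid] = subj.truth.to_jsonable()
        truth_all[sid]["spike_frames"] = subj.spike_frames.tolist()
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=2)
        fh.write("\n")
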