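"""Process-specific synthetic fMRI datasets.

Each ROI time-series is modelled by multiple linear regression on the SLFO
regressor and the alpha/beta band-power regressors,

    y(t) = b0 + b_slfo * x_slfo(t) + b_alpha * x_alpha(t)
              + b_beta * x_beta(t) + e(t).

For a chosen process p (slfo, alpha or beta) the fitted process signal is
``y_pi = b_p * x_p``; the 'clean' series ``y_pi_res`` removes the intercept
and the two *other* fitted terms from y, so it contains only the process
of interest plus the residual.  With

    r_pi  = corr(y_pi, y_pi_res)      and
    y_res = y_pi_res - y_pi,  r_res = corr(y_res, y_pi_res),

the synthetic ROI series preserves the process-attributable fraction of
variance and replaces the remainder with an amplitude-matched AR(1) draw:

    y_synth = r_pi * Z[y_pi] + r_res * Z[psi],

where Z[.] is zero-mean/unit-variance normalisation and psi is an AR(1)
process whose lag-1 coefficient is estimated per ROI from y_res (the
filler should match the temporal autocorrelation of what it replaces).
Because y_res is the OLS residual and hence orthogonal to x_p, the
coefficients satisfy r_pi**2 + r_res**2 = 1 for every ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import RegressorSeries, RoiDataset
from .errors import InputError
from .filters import zscore

__all__ = [
    "ProcessRegressionFit",
    "ProcessSyntheticDataset",
    "PROCESSES",
    "fit_process_regression",
    "make_process_dataset",
    "ar1_fit",
    "ar1_sample",
]

PROCESSES = ("slfo", "alpha", "beta")


@dataclass
class ProcessRegressionFit:
    """Per-ROI OLS estimates of the three-regressor model."""

    beta0: np.ndarray           # N
    betas: np.ndarray           # N x 3, columns (slfo, alpha, beta)
    residuals: np.ndarray       # T' x N
    regressors: dict[str, np.ndarray]   # each T'
    roi_ids: list[str]
    network_labels: list[str]
    tr: float


@dataclass
class ProcessSyntheticDataset:
    """One process-specific synthetic dataset (and its building blocks)."""

    process: str
    y_pi: np.ndarray            # T' x N, fitted process signal
    y_clean: np.ndarray         # T' x N, process + residual
    y_synth: np.ndarray         # T' x N
    r_pi: np.ndarray            # N
    r_res: np.ndarray           # N
    phi: np.ndarray             # N, AR(1) coefficients of the filler
    seed: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    roi_ids: list[str] = field(default_factory=list)
    network_labels: list[str] = field(default_factory=list)
    tr: float = 1.0

    def to_roi_dataset(self, subject_id: str = "", scan_id: str = "") -> RoiDataset:
        return RoiDataset(
            data=self.y_synth,
            tr=self.tr,
            roi_ids=list(self.roi_ids),
            network_labels=list(self.network_labels),
            subject_id=subject_id,
            scan_id=scan_id,
        )


def _reg_values(reg) -> np.ndarray:
    return np.asarray(
        reg.values if isinstance(reg, RegressorSeries) else reg, dtype=float
    )


def fit_process_regression(
    data: RoiDataset,
    slfo,
    alpha,
    beta,
) -> ProcessRegressionFit:
    """Per-ROI OLS of the BOLD data on [1, slfo, alpha, beta].

    ``data`` must already be censored; regressor lengths must equal the
    kept-frame count.  Perfectly collinear regressors are rejected.
    """
    y = data.kept_data()
    regs = {
        "slfo": _reg_values(slfo),
        "alpha": _reg_values(alpha),
        "beta": _reg_values(beta),
    }
    t = y.shape[0]
    for name, v in regs.items():
        if v.size != t:
            raise InputError(
                f"regressor {name!r} length {v.size} != kept frames {t}"
            )
    x = np.column_stack(list(regs.values()))
    cc = np.corrcoef(x, rowvar=False)
    off = np.abs(cc[np.triu_indices(3, k=1)])
    if np.any(off > 1 - 1e-10):
        raise InputError("regressors are perfectly collinear")
    design = np.column_stack([np.ones(t), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return ProcessRegressionFit(
        beta0=coef[0],
        betas=coef[1:].T.copy(),
        residuals=resid,
        regressors=regs,
        roi_ids=list(data.roi_ids),
        network_labels=list(data.network_labels),
        tr=data.tr,
    )


def ar1_fit(x: np.ndarray) -> tuple[float, bool]:
    """Lag-1 sample autocorrelation, clipped to (-0.999, 0.999).

    Returns ``(phi, degenerate)``; a zero-variance input yields
    ``(0.0, True)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise InputError("AR(1) fit needs at least 10 samples")
    if x.std() < 1e-12:
        return 0.0, True
    xc = x - x.mean()
    phi = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
    return float(np.clip(phi, -0.999, 0.999)), False


def ar1_sample(phi: float, t: int, rng: np.random.Generator | int) -> np.ndarray:
    """Stationary unit-variance AR(1) draw of length ``t``, Z-normalised."""
    if not abs(phi) < 1:
        raise InputError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    innov_sd = np.sqrt(1.0 - phi**2)
    e = rng.standard_normal(t)
    x = np.empty(t)
    x[0] = e[0]
    for k in range(1, t):
        x[k] = phi * x[k - 1] + innov_sd * e[k]
    return zscore(x, name="AR(1) draw")


def make_process_dataset(
    fit: ProcessRegressionFit,
    process: str,
    seed: int,
) -> ProcessSyntheticDataset:
    """Build the synthetic dataset for one process from a fitted model.

    ROIs whose fitted process coefficient is exactly zero are flagged
    degenerate and emitted as pure AR(1) noise with ``r_pi = 0``.
    Randomness is drawn from a per-process substream of ``seed``, so the
    three processes built from the same seed use independent noise.
    """
    if process not in PROCESSES:
        raise InputError(f"process must be one of {PROCESSES}, got {process!r}")
    p_idx = PROCESSES.index(process)
    x_p = fit.regressors[process]
    b_p = fit.betas[:, p_idx]
    t, n = fit.residuals.shape

    y_pi = np.outer(x_p, b_p)
    y_clean = y_pi + fit.residuals

    r_pi = np.zeros(n)
    r_res = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(p_idx,))
    rng = np.random.default_rng(ss)

    y_synth = np.empty((t, n))
    phis = np.zeros(n)
    for i in range(n):
        clean_i = y_clean[:, i]
        res_i = fit.residuals[:, i]
        phi, _ = ar1_fit(res_i)
        phis[i] = phi
        psi = ar1_sample(phi, t, rng)
        if np.abs(b_p[i]) < 1e-300 or y_pi[:, i].std() < 1e-12:
            degenerate[i] = True
            r_res[i] = 1.0
            y_synth[:, i] = psi
            continue
        r_pi[i] = float(np.corrcoef(y_pi[:, i], clean_i)[0, 1])
        # noiseless limit: a zero residual contributes nothing (r_res -> 0)
        if res_i.std() < 1e-12 * max(1.0, clean_i.std()):
            r_res[i] = 0.0
        else:
            r_res[i] = float(np.corrcoef(res_i, clean_i)[0, 1])
        y_synth[:, i] = r_pi[i] * zscore(y_pi[:, i]) + r_res[i] * psi
    return ProcessSyntheticDataset(
        process=process,
        y_pi=y_pi,
        y_clean=y_clean,
        y_synth=y_synth,
        r_pi=r_pi,
        r_res=r_res,
        phi=phis,
        seed=seed,
        degenerate=degenerate,
        roi_ids=list(fit.roi_ids),
        network_labels=list(fit.network_labels),
        tr=fit.tr,
    )
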