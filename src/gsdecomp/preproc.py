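"""Motion censoring, nuisance regression pipelines, and the functional
connectivity contrast (FCC).

Censoring rules
---------------
A volume is flagged when framewise displacement (FD) exceeds 0.25 mm or
when DVARS exceeds its median by three median absolute deviations.  Both
immediate neighbours of a flagged volume are removed as well, and a
sub-threshold volume whose immediate predecessor and successor are both
flagged is also removed.

Three preprocessing variants are supported on the censored data: MinPrep
(no further denoising), WM10 (top-10 white-matter PCA score series
regressed out), and WM10_GSR (global signal and the same WM components
regressed out in a single joint OLS).  The global signal here is the
unweighted ROI mean, since this pipeline operates on parcellated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FCMatrix, Pipeline, RoiDataset
from .errors import DegenerateSignalError, InputError
from .filters import mad, zscore

__all__ = [
    "CensorReport",
    "framewise_displacement",
    "dvars",
    "build_censor_mask",
    "extract_global_signal",
    "wm_pca_components",
    "nuisance_regress",
    "apply_pipeline",
    "fcc",
    "sweep_wm_components",
    "FD_ROTATION_RADIUS_MM",
]

FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class CensorReport:
    """FD/DVARS traces with the resulting keep-mask (True = kept)."""

    fd: np.ndarray
    dvars: np.ndarray
    mask: np.ndarray
    fraction_censored: float


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """FD in mm from T x 6 rigid-body parameters (3 transl. mm, 3 rot. rad).

    Rotations are converted to arc length on a 50 mm sphere.  FD of the
    first volume is 0 by convention.
    """
    mp = np.asarray(motion, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise InputError(f"motion parameters must be T x 6, got {mp.shape}")
    if mp.shape[0] < 2:
        raise InputError("need at least 2 volumes for FD")
    d = np.abs(np.diff(mp, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(data: RoiDataset | np.ndarray) -> np.ndarray:
    """Root-mean-square frame-to-frame signal change across ROIs."""
    arr = data.data if isinstance(data, RoiDataset) else np.asarray(data, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InputError("DVARS needs a T x N matrix with T >= 2")
    d = np.diff(arr, axis=0)
    out = np.sqrt(np.mean(d**2, axis=1))
    return np.concatenate([[0.0], out])


def build_censor_mask(
    fd: np.ndarray,
    dvars_series: np.ndarray,
    fd_thresh: float = 0.25,
    dvars_mad_factor: float = 3.0,
    *,
    dvars_thresh: float | None = None,
) -> CensorReport:
    """Apply the three censoring rules and return the keep-mask.

    The DVARS cut is ``median + dvars_mad_factor * MAD`` computed from the
    supplied series; pass ``dvars_thresh`` to reuse a threshold computed
    earlier (e.g. when re-applying the rules to already-censored data).
    """
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dvars_series, dtype=float)
    if fd.shape != dv.shape:
        raise InputError("FD and DVARS must have equal length")
    dv_thresh = (
        dvars_thresh if dvars_thresh is not None
        else np.median(dv) + dvars_mad_factor * mad(dv)
    )
    flagged = (fd > fd_thresh) | (dv > dv_thresh)
    removed = flagged.copy()
    # rule (ii): both neighbours of every flagged volume
    removed[:-1] |= flagged[1:]
    removed[1:] |= flagged[:-1]
    # rule (iii): sub-threshold volumes sandwiched between flagged volumes
    sandwich = np.zeros_like(flagged)
    sandwich[1:-1] = flagged[:-2] & flagged[2:]
    removed |= sandwich
    mask = ~removed
    return CensorReport(
        fd=fd, dvars=dv, mask=mask,
        fraction_censored=float(removed.mean()),
    )


def extract_global_signal(data: RoiDataset) -> np.ndarray:
    """Z-scored unweighted ROI mean over the kept frames."""
    gs = data.kept_data().mean(axis=1)
    return zscore(gs, name="global signal")


def wm_pca_components(wm_series: np.ndarray, k: int) -> np.ndarray:
    """Top-k PCA score series of column-standardised WM signals.

    Returns a T' x k matrix of orthonormal score time-series ordered by
    explained variance (descending).
    """
    wm = np.asarray(wm_series, dtype=float)
    if wm.ndim != 2:
        raise InputError("WM series must be a T' x M matrix")
    t, m = wm.shape
    if not 1 <= k <= min(t, m):
        raise InputError(f"k = {k} not in [1, min(T', M) = {min(t, m)}]")
    sd = wm.std(axis=0)
    if np.any(sd < 1e-12):
        raise DegenerateSignalError("constant WM channel cannot be standardised")
    wm_std = (wm - wm.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(wm_std, full_matrices=False)
    return u[:, :k]


def nuisance_regress(data: RoiDataset, nuisance: np.ndarray) -> RoiDataset:
    """Per-ROI OLS residuals after removing ``nuisance`` (plus intercept).

    ``data`` must already be censored (rows = kept frames); ``nuisance`` is
    T' x q and must have full column rank once an intercept is added.
    """
    y = data.kept_data()
    nz = np.asarray(nuisance, dtype=float)
    if nz.ndim == 1:
        nz = nz[:, None]
    if nz.shape[0] != y.shape[0]:
        raise InputError("nuisance rows do not match kept frame count")
    design = np.column_stack([np.ones(y.shape[0]), nz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InputError("nuisance design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return RoiDataset(
        data=resid,
        tr=data.tr,
        roi_ids=list(data.roi_ids),
        network_labels=list(data.network_labels),
        censor_mask=None,
        subject_id=data.subject_id,
        scan_id=data.scan_id,
    )


def apply_pipeline(
    data: RoiDataset,
    wm_series: np.ndarray | None,
    pipeline: Pipeline | str,
    n_wm_components: int = 10,
) -> RoiDataset:
    """Run one of the three preprocessing variants on censored data.

    ``data`` carries its censor mask; the returned dataset holds kept
    frames only.  ``wm_series`` is the full-length T x M white-matter
    matrix (censored here with the same mask).
    """
    pipeline = Pipeline(pipeline)
    kept = data.censored()
    if pipeline is Pipeline.MINPREP:
        return kept
    if wm_series is None:
        raise InputError(f"pipeline {pipeline.value} requires WM series")
    wm = np.asarray(wm_series, dtype=float)
    if wm.shape[0] == data.n_volumes:
        wm = wm[data.censor_mask]
    elif wm.shape[0] != kept.n_volumes:
        raise InputError("WM series length matches neither T nor T'")
    comps = wm_pca_components(wm, n_wm_components)
    if pipeline is Pipeline.WM10:
        return nuisance_regress(kept, comps)
    gs = extract_global_signal(kept)
    return nuisance_regress(kept, np.column_stack([gs, comps]))


def fcc(fc: FCMatrix) -> float:
    """Functional connectivity contrast: standardised rank-sum statistic
    comparing within-network against between-network edge values.

    Uses the strictly-upper-triangle edges only; positive values mean
    within-network edges are systematically larger (better identifiability
    of large-scale networks).
    """
    if not fc.network_labels:
        raise InputError("FCC requires network labels")
    labels = np.asarray(fc.network_labels)
    n = fc.n_rois
    iu, ju = np.triu_indices(n, k=1)
    vals = fc.values[iu, ju]
    within = labels[iu] == labels[ju]
    ok = np.isfinite(vals)
    w = vals[within & ok]
    b = vals[~within & ok]
    if w.size == 0 or b.size == 0:
        raise InputError("need at least one within- and one between-network edge")
    return float(stats.ranksums(w, b).statistic)


def sweep_wm_components(
    datasets: list[RoiDataset],
    wm_series_list: list[np.ndarray],
    k_grid: list[int],
) -> pd.DataFrame:
    """Group-mean FCC as a function of the number of WM components removed.

    ``k = 0`` means no WM regression (baseline).  Returns a DataFrame with
    columns ``k`` and ``mean_fcc``; the maximising ``k`` is in
    ``df.attrs["best_k"]``.
    """
    from .connectivity import fc_matrix

    rows = []
    for k in k_grid:
        vals = []
        for data, wm in zip(datasets, wm_series_list):
            kept = data.censored()
            if k == 0:
                clean = kept
            else:
                wm_arr = np.asarray(wm, dtype=float)
                if wm_arr.shape[0] == data.n_volumes:
                    wm_arr = wm_arr[data.censor_mask]
                clean = nuisance_regress(kept, wm_pca_components(wm_arr, k))
            vals.append(fcc(fc_matrix(clean)))
        rows.append({"k": k, "mean_fcc": float(np.mean(vals))})
    df = pd.DataFrame(rows)
    df.attrs["best_k"] = int(df.loc[df["mean_fcc"].idxmax(), "k"])
    return df
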