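"""Cohort-level orchestration: censoring, signal assembly, group analyses.

Thin glue between the stage modules; every function here simply wires
outputs of one stage into the next in the order the analysis prescribes:
censor -> (global signal, regressors) -> contribution tests, and
censor -> pipelines -> process-synthetic datasets -> FC similarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import fc_matrix, fc_similarity
from .datatypes import Pipeline, RegressorSeries, RoiDataset
from .errors import InputError
from .filters import zscore
from .gsanalysis import (
    SubjectSignals,
    contribution_test,
    observed_contributions,
    surrogate_contributions,
)
from .preproc import (
    apply_pipeline,
    build_censor_mask,
    dvars,
    extract_global_signal,
    framewise_displacement,
)
from .processfc import fit_process_regression, make_process_dataset
from .synth import SubjectData

__all__ = [
    "censor_subject",
    "censored_regressor",
    "subject_signals",
    "cohort_signals",
    "contribution_analysis",
    "similarity_table",
]


def censor_subject(
    subj: SubjectData, fd_thresh: float = 0.25, dvars_mad_factor: float = 3.0
) -> RoiDataset:
    """Attach the FD/DVARS censor mask to a subject's ROI dataset."""
    fd = framewise_displacement(subj.motion)
    dv = dvars(subj.roi)
    report = build_censor_mask(fd, dv, fd_thresh, dvars_mad_factor)
    ds = subj.roi
    return RoiDataset(
        data=ds.data, tr=ds.tr, roi_ids=list(ds.roi_ids),
        network_labels=list(ds.network_labels), censor_mask=report.mask,
        subject_id=ds.subject_id, scan_id=ds.scan_id,
    )


def censored_regressor(
    values_full: np.ndarray, mask: np.ndarray, name: str, tr: float,
    *, rescale: bool = True,
) -> RegressorSeries:
    """Drop censored frames from a full-length regressor and re-z-score.

    ``rescale=False`` keeps the full-series normalisation (only drops
    frames); use it when fitted coefficients must stay on the generative
    scale, e.g. when comparing against ground-truth couplings.  All
    correlation-based analyses are invariant to this choice.
    """
    v = np.asarray(values_full, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if v.size != mask.size:
        raise InputError("regressor length does not match mask length")
    vals = zscore(v[mask], name=name) if rescale else v[mask]
    return RegressorSeries(values=vals, name=name, tr=tr)


def subject_signals(subj: SubjectData, masked: RoiDataset | None = None) -> SubjectSignals:
    """Censored global signal plus censored regressors for one subject."""
    ds = masked if masked is not None else censor_subject(subj)
    mask = ds.censor_mask
    gs = extract_global_signal(ds)
    regs = {
        name: censored_regressor(vals, mask, name, ds.tr).values
        for name, vals in subj.regressors.items()
    }
    return SubjectSignals(subject_id=ds.subject_id, gs=gs, regressors=regs)


def cohort_signals(cohort: list[SubjectData]) -> list[SubjectSignals]:
    return [subject_signals(s) for s in cohort]


def contribution_analysis(
    cohort: list[SubjectData],
    regressor_names: tuple[str, ...] = ("slfo", "delta", "theta", "alpha", "beta"),
) -> pd.DataFrame:
    """Observed vs inter-subject-surrogate contributions for a whole cohort."""
    signals = cohort_signals(cohort)
    observed = {n: observed_contributions(signals, n) for n in regressor_names}
    null = {n: surrogate_contributions(signals, n) for n in regressor_names}
    return contribution_test(observed, null)


def similarity_table(
    cohort: list[SubjectData],
    processes: tuple[str, ...] = ("slfo", "alpha", "beta"),
    *,
    n_wm_components: int = 10,
    fit_on: Pipeline = Pipeline.MINPREP,
    synth_seed: int = 0,
) -> pd.DataFrame:
    """Similarity of process-synthetic FC to each pipeline's FC, per subject.

    The per-ROI regression model is fitted on the ``fit_on`` dataset
    (minimally preprocessed by default, where the full signal is present);
    the resulting process-synthetic FC matrix is compared against the FC
    matrices of all three pipelines.
    """
    rows = []
    for k, subj in enumerate(cohort):
        masked = censor_subject(subj)
        mask = masked.censor_mask
        pipe_data = {
            p: apply_pipeline(masked, subj.wm, p, n_wm_components)
            for p in Pipeline
        }
        pipe_fc = {p: fc_matrix(d) for p, d in pipe_data.items()}
        regs = {
            name: censored_regressor(subj.regressors[name], mask, name, masked.tr)
            for name in ("slfo", "alpha", "beta")
        }
        fit = fit_process_regression(
            pipe_data[fit_on], regs["slfo"], regs["alpha"], regs["beta"]
        )
        for process in processes:
            synth = make_process_dataset(fit, process, seed=synth_seed + 1000 * k)
            syn_fc = fc_matrix(
                synth.to_roi_dataset(subject_id=masked.subject_id)
            )
            for p in Pipeline:
                rows.append({
                    "subject_id": masked.subject_id,
                    "scan_id": masked.scan_id,
                    "process": process,
                    "pipeline": p.value,
                    "similarity_r": fc_similarity(syn_fc, pipe_fc[p]),
                })
    return pd.DataFrame(rows)
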