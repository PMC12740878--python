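"""Static functional connectivity, synthetic-vs-experimental similarity,
and pipeline comparison statistics.

Similarity between two FC matrices is the Pearson correlation between
their strictly-upper-triangle entries (no Fisher transform by default,
matching the literal definition; a flag enables it).  Pipeline contrasts
use the unpaired two-sided Wilcoxon rank-sum test; a paired signed-rank
alternative is available behind a flag since subjects are in fact paired
across pipelines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FCMatrix, Pipeline, RoiDataset
from .errors import InputError

__all__ = [
    "fc_matrix",
    "fc_similarity",
    "average_fc",
    "pipeline_comparison",
]

_PIPELINE_PAIRS = (
    (Pipeline.MINPREP, Pipeline.WM10),
    (Pipeline.WM10, Pipeline.WM10_GSR),
)


def fc_matrix(data: RoiDataset | np.ndarray, roi_ids=None,
              network_labels=None, tr: float | None = None) -> FCMatrix:
    """Pearson correlation matrix over the kept frames.

    Zero-variance ROIs yield NaN rows/columns (flagged as undefined) and
    are excluded pairwise from similarity computations downstream.
    """
    if isinstance(data, RoiDataset):
        arr = data.kept_data()
        roi_ids = list(data.roi_ids)
        network_labels = list(data.network_labels)
    else:
        arr = np.asarray(data, dtype=float)
        if roi_ids is None:
            roi_ids = [f"roi{i:03d}" for i in range(arr.shape[1])]
        network_labels = list(network_labels) if network_labels else []
    if arr.shape[0] < 3:
        raise InputError("need at least 3 kept frames for a correlation matrix")
    sd = arr.std(axis=0)
    degenerate = sd < 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.corrcoef(arr, rowvar=False)
    vals = np.clip(vals, -1.0, 1.0)
    if np.any(degenerate):
        vals[degenerate, :] = np.nan
        vals[:, degenerate] = np.nan
    np.fill_diagonal(vals, 1.0)
    return FCMatrix(values=vals, roi_ids=list(roi_ids),
                    network_labels=network_labels)


def fc_similarity(a: FCMatrix, b: FCMatrix, *, fisher_z: bool = False) -> float:
    """Pearson correlation between the upper-triangle vectors of two FCs.

    Pairs where either matrix is undefined (NaN) are excluded; the diagonal
    is never included.
    """
    if a.roi_ids != b.roi_ids:
        raise InputError("FC matrices cover different ROI sets")
    va = a.upper_values()
    vb = b.upper_values()
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise InputError("fewer than 3 defined edge pairs in common")
    va, vb = va[ok], vb[ok]
    if fisher_z:
        va = np.arctanh(np.clip(va, -0.999999, 0.999999))
        vb = np.arctanh(np.clip(vb, -0.999999, 0.999999))
    return float(np.corrcoef(va, vb)[0, 1])


def average_fc(mats: list[FCMatrix]) -> FCMatrix:
    """Entrywise mean of raw correlation values (no Fisher transform)."""
    if not mats:
        raise InputError("no FC matrices to average")
    ref = mats[0]
    for m in mats[1:]:
        if m.roi_ids != ref.roi_ids:
            raise InputError("FC matrices cover different ROI sets")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(np.stack([m.values for m in mats]), axis=0)
    np.fill_diagonal(vals, 1.0)
    # averaging can leave tiny asymmetries from NaN patterns; symmetrise
    vals = 0.5 * (vals + vals.T)
    return FCMatrix(values=vals, roi_ids=list(ref.roi_ids),
                    network_labels=list(ref.network_labels))


def pipeline_comparison(
    table: pd.DataFrame,
    process: str,
    scan: str | None = None,
    *,
    paired: bool = False,
) -> pd.DataFrame:
    """Contrast similarity values between preprocessing pipelines.

    ``table`` needs columns ``subject_id, scan_id, process, pipeline,
    similarity_r``.  For each adjacent pipeline pair (MinPrep vs WM10,
    WM10 vs WM10_GSR) a two-sided Wilcoxon rank-sum p-value is reported
    together with group means and SDs.  With ``paired=True`` a Wilcoxon
    signed-rank test is used instead (subjects are paired across
    pipelines; the unpaired default matches common reporting practice).
    """
    sub = table[table["process"] == process]
    if scan is not None:
        sub = sub[sub["scan_id"] == scan]
    rows = []
    for p1, p2 in _PIPELINE_PAIRS:
        x = sub.loc[sub["pipeline"] == p1.value, "similarity_r"].to_numpy(float)
        y = sub.loc[sub["pipeline"] == p2.value, "similarity_r"].to_numpy(float)
        if x.size < 2 or y.size < 2:
            raise InputError(
                f"need >= 2 subjects per pipeline, got {x.size} vs {y.size}"
            )
        if paired:
            if x.size != y.size:
                raise InputError("paired test requires equal group sizes")
            warnings.warn("signed-rank comparison is a non-default variant")
            p = float(stats.wilcoxon(x, y).pvalue) if np.any(x != y) else 1.0
        else:
            p = float(stats.ranksums(x, y).pvalue)
        rows.append({
            "pipeline_a": p1.value, "pipeline_b": p2.value,
            "mean_a": float(x.mean()), "sd_a": float(x.std(ddof=1)),
            "mean_b": float(y.mean()), "sd_b": float(y.std(ddof=1)),
            "p_value": p,
        })
    return pd.DataFrame(rows)
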