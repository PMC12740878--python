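"""Core in-memory containers for the pipeline.

All time axes are expressed in seconds relative to the first retained fMRI
volume; volume ``k`` is sampled at ``t = k * tr`` (0-based).  Censoring is
carried as a boolean keep-mask alongside the data rather than by deleting
rows, so downstream stages can be re-run with a different mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import InputError

__all__ = [
    "PhysioTrace",
    "RoiDataset",
    "RegressorSeries",
    "FCMatrix",
    "Pipeline",
    "REGRESSOR_NAMES",
]

REGRESSOR_NAMES = ("slfo", "delta", "theta", "alpha", "beta")


class Pipeline(str, Enum):
    """The three preprocessing variants compared throughout.

    MinPrep: censored data with no further denoising.
    WM10: censored data with the top-10 white-matter PCA score series
        regressed out.
    WM10_GSR: the global signal and the same 10 WM components regressed
        out jointly.
    """

    MINPREP = "MinPrep"
    WM10 = "WM10"
    WM10_GSR = "WM10_GSR"


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise InputError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains NaN or infinite values")
    return arr


@dataclass
class PhysioTrace:
    """A raw cardiac (pulse oximeter) or respiratory (belt) recording.

    Parameters
    ----------
    samples : array
        Raw samples in arbitrary units.
    fs : float
        Sampling rate in Hz.
    modality : {"cardiac", "respiratory"}
    start_time : float
        Onset in seconds relative to the first fMRI volume.
    """

    samples: np.ndarray
    fs: float
    modality: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples, "samples", 1)
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size < 2:
            raise InputError("physiological trace needs at least 2 samples")
        if self.modality not in ("cardiac", "respiratory"):
            raise InputError(f"unknown physio modality {self.modality!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class RoiDataset:
    """A volumes-by-ROIs BOLD matrix with its censor mask and network labels."""

    data: np.ndarray            # T x N
    tr: float
    roi_ids: list[str]
    network_labels: list[str]
    censor_mask: np.ndarray | None = None   # True = kept
    subject_id: str = ""
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data", 2)
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise InputError(f"RoiDataset needs T >= 2 and N >= 2, got {t} x {n}")
        if self.tr <= 0:
            raise InputError(f"TR must be positive, got {self.tr}")
        self.roi_ids = [str(r) for r in self.roi_ids]
        self.network_labels = [str(l) for l in self.network_labels]
        if len(self.roi_ids) != n:
            raise InputError(f"{len(self.roi_ids)} ROI ids for {n} columns")
        if len(self.network_labels) != n:
            raise InputError(
                f"{len(self.network_labels)} network labels for {n} ROIs"
            )
        if self.censor_mask is None:
            self.censor_mask = np.ones(t, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (t,):
                raise InputError(
                    f"censor mask length {self.censor_mask.size} != T = {t}"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_kept(self) -> int:
        return int(self.censor_mask.sum())

    def kept_data(self) -> np.ndarray:
        """Data restricted to retained volumes (T' x N)."""
        return self.data[self.censor_mask]

    def censored(self, mask: np.ndarray | None = None) -> "RoiDataset":
        """Return a dataset whose rows are the kept frames of ``mask``.

        The result carries an all-true mask of length T'; the original
        full-length mask is consumed at this point.
        """
        m = self.censor_mask if mask is None else np.asarray(mask, dtype=bool)
        if m.shape != (self.n_volumes,):
            raise InputError("mask length does not match number of volumes")
        return RoiDataset(
            data=self.data[m],
            tr=self.tr,
            roi_ids=list(self.roi_ids),
            network_labels=list(self.network_labels),
            censor_mask=None,
            subject_id=self.subject_id,
            scan_id=self.scan_id,
        )


@dataclass
class RegressorSeries:
    """A TR-locked nuisance/interest regressor after censoring.

    ``values`` has one entry per *kept* volume of its paired RoiDataset.
    """

    values: np.ndarray
    name: str
    tr: float

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values", 1)
        if self.tr <= 0:
            raise InputError(f"TR must be positive, got {self.tr}")
        if self.name not in REGRESSOR_NAMES:
            raise InputError(
                f"regressor name {self.name!r} not in {REGRESSOR_NAMES}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FCMatrix:
    """A static functional-connectivity (Pearson) matrix.

    Entries for degenerate (zero-variance) ROIs may be NaN; such rows are
    excluded pairwise from similarity computations.
    """

    values: np.ndarray
    roi_ids: list[str]
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise InputError(f"FC matrix must be square, got shape {vals.shape}")
        n = vals.shape[0]
        self.roi_ids = [str(r) for r in self.roi_ids]
        if len(self.roi_ids) != n:
            raise InputError(f"{len(self.roi_ids)} ROI ids for {n} x {n} matrix")
        if self.network_labels and len(self.network_labels) != n:
            raise InputError("network label count does not match matrix size")
        finite = np.isfinite(vals)
        if np.any(finite & (np.abs(vals) > 1.0 + 1e-9)):
            raise InputError("correlation entries must lie in [-1, 1]")
        both = finite & finite.T
        if np.nanmax(np.abs(np.where(both, vals - vals.T, 0.0)), initial=0.0) > 1e-12:
            raise InputError("FC matrix is asymmetric beyond 1e-12")
        d = np.diag(vals)
        if np.any(np.isfinite(d) & (np.abs(d - 1.0) > 1e-9)):
            raise InputError("FC matrix diagonal must be 1")
        self.values = vals

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        """Strictly-upper-triangle entries as a flat vector."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]
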