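"""Readers and writers for the on-disk TSV + JSON-sidecar formats.

The formats are deliberately plain-text and BIDS-flavoured so that fixtures
are diffable: a data TSV (optionally gzipped) accompanied by a JSON sidecar
carrying sampling metadata.  An HDF5 mirror of the ROI-dataset schema is
provided for large cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import FCMatrix, PhysioTrace, RegressorSeries, RoiDataset
from .errors import FormatError, InputError

__all__ = [
    "read_roi_dataset", "write_roi_dataset",
    "read_physio", "write_physio",
    "read_fc_matrix", "write_fc_matrix",
    "read_regressor", "write_regressor",
    "read_roi_dataset_h5", "write_roi_dataset_h5",
    "load_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing JSON sidecar {sc}")
    with open(sc) as fh:
        return json.load(fh)


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------- ROI data

def write_roi_dataset(ds: RoiDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(ds.data, columns=ds.roi_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    _write_sidecar(path, {
        "TR": ds.tr,
        "NetworkLabels": list(ds.network_labels),
        "CensorMask": [bool(v) for v in ds.censor_mask],
        "SubjectID": ds.subject_id,
        "ScanID": ds.scan_id,
    })


def read_roi_dataset(path: str | Path) -> RoiDataset:
    path = Path(path)
    meta = _read_sidecar(path)
    if "TR" not in meta:
        raise FormatError(f"sidecar for {path} lacks TR")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    mask = meta.get("CensorMask")
    try:
        return RoiDataset(
            data=df.to_numpy(dtype=float),
            tr=float(meta["TR"]),
            roi_ids=list(df.columns),
            network_labels=list(meta.get("NetworkLabels", [])),
            censor_mask=None if mask is None else np.asarray(mask, dtype=bool),
            subject_id=str(meta.get("SubjectID", "")),
            scan_id=str(meta.get("ScanID", "")),
        )
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ------------------------------------------------------------ physio traces

def write_physio(trace: PhysioTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({trace.modality: trace.samples}).to_csv(
        path, sep="\t", index=False, header=False
    )
    _write_sidecar(path, {
        "SamplingFrequency": trace.fs,
        "StartTime": trace.start_time,
        "Columns": [trace.modality],
    })


_MODALITY_ALIASES = {
    "cardiac": "cardiac", "pulse": "cardiac", "ppg": "cardiac",
    "respiratory": "respiratory", "resp": "respiratory",
    "respiration": "respiratory", "breathing": "respiratory",
}


def read_physio(path: str | Path) -> PhysioTrace:
    path = Path(path)
    meta = _read_sidecar(path)
    if "SamplingFrequency" not in meta:
        raise FormatError(f"sidecar for {path} lacks SamplingFrequency")
    if "Columns" not in meta or not meta["Columns"]:
        raise FormatError(f"sidecar for {path} lacks Columns")
    col = str(meta["Columns"][0]).lower()
    modality = _MODALITY_ALIASES.get(col)
    if modality is None:
        raise FormatError(f"unrecognised physio column name {col!r}")
    df = pd.read_csv(path, sep="\t", header=None, float_precision="round_trip")
    if df.isna().any().any():
        raise FormatError(f"{path} contains missing values")
    try:
        return PhysioTrace(
            samples=df.iloc[:, 0].to_numpy(dtype=float),
            fs=float(meta["SamplingFrequency"]),
            modality=modality,
            start_time=float(meta.get("StartTime", 0.0)),
        )
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# -------------------------------------------------------------- FC matrices

def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(fc.values, index=fc.roi_ids, columns=fc.roi_ids)
    df.to_csv(path, sep="\t")
    if fc.network_labels:
        _write_sidecar(path, {"NetworkLabels": list(fc.network_labels)})


def read_fc_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sc = _sidecar_path(path)
    labels: list[str] = []
    if sc.exists():
        with open(sc) as fh:
            labels = json.load(fh).get("NetworkLabels", [])
    try:
        return FCMatrix(
            values=df.to_numpy(dtype=float),
            roi_ids=list(df.columns),
            network_labels=labels,
        )
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- regressors

def write_regressor(reg: RegressorSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({reg.name: reg.values}).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"TR": reg.tr, "Name": reg.name})


def read_regressor(path: str | Path) -> RegressorSeries:
    path = Path(path)
    meta = _read_sidecar(path)
    if "TR" not in meta:
        raise FormatError(f"sidecar for {path} lacks TR")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    try:
        return RegressorSeries(
            values=df.iloc[:, 0].to_numpy(dtype=float),
            name=str(meta.get("Name", df.columns[0])),
            tr=float(meta["TR"]),
        )
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------- HDF5 mirror

def write_roi_dataset_h5(ds: RoiDataset, path: str | Path) -> None:
    """HDF5 mirror of the TSV + sidecar schema (one dataset per field)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ds.data)
        fh.create_dataset("censor_mask", data=ds.censor_mask)
        fh.attrs["tr"] = ds.tr
        fh.attrs["roi_ids"] = ds.roi_ids
        fh.attrs["network_labels"] = ds.network_labels
        fh.attrs["subject_id"] = ds.subject_id
        fh.attrs["scan_id"] = ds.scan_id


def read_roi_dataset_h5(path: str | Path) -> RoiDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        return RoiDataset(
            data=fh["data"][()],
            tr=float(fh.attrs["tr"]),
            roi_ids=[str(s) for s in fh.attrs["roi_ids"]],
            network_labels=[str(s) for s in fh.attrs["network_labels"]],
            censor_mask=fh["censor_mask"][()],
            subject_id=str(fh.attrs["subject_id"]),
            scan_id=str(fh.attrs["scan_id"]),
        )


# ------------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must hold a mapping at top level")
    return cfg
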