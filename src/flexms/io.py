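"""Readers and writers for ROI time series and cohort tables.

Series live in HDF5 (dataset ``roi_by_time`` with ``sampling_rate_hz`` and
``roi_labels`` attributes) or delimited text with one ROI per row; cohort
tables are CSV with the fixed clinical schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .avalanches import RoiTimeSeries
from .synthetic import COHORT_COLUMNS, GROUPS

__all__ = [
    "write_series_hdf5",
    "read_series_hdf5",
    "write_series_text",
    "read_series_text",
    "read_series",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_json_report",
]


def write_series_hdf5(series: RoiTimeSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("roi_by_time", data=series.values)
        dset.attrs["sampling_rate_hz"] = series.sampling_rate
        dset.attrs["roi_labels"] = [str(x) for x in series.roi_labels]
        dset.attrs["subject_id"] = series.subject_id
        dset.attrs["recording_id"] = series.recording_id


def read_series_hdf5(path: str | Path) -> RoiTimeSeries:
    try:
        with h5py.File(path, "r") as f:
            if "roi_by_time" not in f:
                raise ValueError(f"{path}: missing dataset 'roi_by_time'")
            dset = f["roi_by_time"]
            labels = [
                x.decode() if isinstance(x, bytes) else str(x)
                for x in dset.attrs.get("roi_labels", [])
            ]
            return RoiTimeSeries(
                values=dset[()],
                sampling_rate=float(dset.attrs.get("sampling_rate_hz", 1024.0)),
                roi_labels=labels or None,
                subject_id=str(dset.attrs.get("subject_id", "")),
                recording_id=str(dset.attrs.get("recording_id", "")),
            )
    except OSError as exc:
        raise ValueError(f"cannot read HDF5 series {path}: {exc}") from exc


def write_series_text(series: RoiTimeSeries, path: str | Path, delimiter: str = "\t") -> None:
    """One ROI per row; a leading '#' header line carries the ROI labels."""
    header = delimiter.join(series.roi_labels)
    np.savetxt(path, series.values, delimiter=delimiter, header=header)


def read_series_text(path: str | Path, delimiter: str = "\t", sampling_rate: float = 1024.0) -> RoiTimeSeries:
    path = Path(path)
    labels: list[str] | None = None
    with open(path) as f:
        first = f.readline()
    if first.startswith("#"):
        labels = first[1:].strip().split(delimiter)
    try:
        values = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed series file {path}: {exc}") from exc
    if labels is not None and len(labels) != values.shape[0]:
        labels = None
    return RoiTimeSeries(values=values, sampling_rate=sampling_rate, roi_labels=labels,
                         subject_id=path.stem)


def read_series(path: str | Path) -> RoiTimeSeries:
    """Dispatch on extension: .h5/.hdf5 -> HDF5, otherwise delimited text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_series_hdf5(path)
    return read_series_text(path)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False)


def read_cohort_csv(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Load and validate a cohort table.

    Always checks the schema, unique subject ids, and group labels; with
    ``strict=True`` additionally enforces plausible clinical ranges
    (EDSS 0-10, nonnegative scores and durations).
    """
    cohort = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table {path} is missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dupes = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad = set(cohort["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if (cohort["repertoire_size"] < 0).any():
        raise ValueError("repertoire_size must be >= 0")
    if strict:
        edss = cohort["edss"].dropna()
        if ((edss < 0) | (edss > 10)).any():
            raise ValueError("EDSS outside the 0-10 scale")
        for col in ("fss", "sdmt", "bdi", "disease_duration_months"):
            if (cohort[col].dropna() < 0).any():
                raise ValueError(f"{col} must be nonnegative")
    return cohort


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=default) + "\n")
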