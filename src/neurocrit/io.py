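"""HDF5 / CSV / JSON containers for pipeline artifacts.

Schemas are versioned; readers refuse files whose schema tag differs so a
stale artifact fails loudly rather than silently misparsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .criticality import CritMaps
from .signal import ParcelTimeSeries

SCHEMA_VERSION = "1"


def _check_schema(f: h5py.File, path: str | Path) -> None:
    found = f.attrs.get("schema_version")
    if found != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema mismatch (expected {SCHEMA_VERSION!r}, found {found!r})"
        )


def write_timeseries(path: str | Path, ts: ParcelTimeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("data", data=ts.data)
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("parcel_ids", data=np.array(ts.parcel_ids, dtype="S"))
        f.create_dataset("system_ids", data=np.array(ts.system_ids, dtype="S"))
        f.create_dataset("subject_id", data=np.bytes_(ts.subject_id))


def read_timeseries(path: str | Path) -> ParcelTimeSeries:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        return ParcelTimeSeries(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            parcel_ids=[s.decode() for s in f["parcel_ids"][()]],
            system_ids=[s.decode() for s in f["system_ids"][()]],
            subject_id=f["subject_id"][()].decode(),
        )


def read_timeseries_csv(path: str | Path, fs: float) -> ParcelTimeSeries:
    """Plain single-or-few-parcel CSV fixture reader (columns = parcels)."""
    df = pd.read_csv(path)
    return ParcelTimeSeries(data=df.to_numpy(dtype=float), fs=fs,
                            parcel_ids=list(df.columns))


def write_critmaps(path: str | Path, cm: CritMaps) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("dfa", data=cm.dfa)
        f.create_dataset("fei", data=cm.fei)
        f.create_dataset("valid", data=cm.valid)
        f.create_dataset("freqs", data=cm.freqs)
        f.create_dataset("parcel_ids", data=np.array(cm.parcel_ids, dtype="S"))
        f.create_dataset("system_ids", data=np.array(cm.system_ids, dtype="S"))
        f.create_dataset("subject_id", data=np.bytes_(cm.subject_id))


def read_critmaps(path: str | Path) -> CritMaps:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        return CritMaps(
            dfa=f["dfa"][()],
            fei=f["fei"][()],
            valid=f["valid"][()].astype(bool),
            freqs=f["freqs"][()],
            parcel_ids=[s.decode() for s in f["parcel_ids"][()]],
            system_ids=[s.decode() for s in f["system_ids"][()]],
            subject_id=f["subject_id"][()].decode(),
        )


BAND_MEANS_COLUMNS = ["subject", "metric", "band", "system", "value"]


def write_band_means(path: str | Path, table: pd.DataFrame) -> None:
    missing = set(BAND_MEANS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"band-means table missing columns: {sorted(missing)}")
    table[BAND_MEANS_COLUMNS].to_csv(path, index=False)


def read_band_means(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BAND_MEANS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_report(path: str | Path, report: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def read_report(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: schema mismatch")
    return payload


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
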