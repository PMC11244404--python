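"""HDF5 container and TSV event I/O.

The package's boundary formats are a small HDF5 container for continuous
recordings (dataset ``data`` of shape channels x samples with ``fs``,
``channel_names``, ``reference`` and ``history`` attributes) and a TSV file
for event annotations (columns ``onset_s``, ``label``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ValidationError
from .recording import EventList, RawRecording


def save_recording(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        d.attrs["channel_names"] = json.dumps(list(rec.channel_names))
        d.attrs["reference"] = rec.reference
        d.attrs["history"] = json.dumps(list(rec.history))
    return path


def load_recording(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValidationError(f"{path}: no 'data' dataset")
        d = f["data"]
        return RawRecording(
            data=d[()],
            fs=float(d.attrs["fs"]),
            channel_names=tuple(json.loads(d.attrs["channel_names"])),
            reference=str(d.attrs["reference"]),
            history=tuple(json.loads(d.attrs["history"])),
        )


def save_events(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_frame().to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path) -> EventList:
    frame = pd.read_csv(path, sep="\t")
    missing = {"onset_s", "label"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return EventList.from_frame(frame)


def save_array_group(path: str | Path, arrays: dict, attrs: dict | None = None) -> Path:
    """Write a flat dict of numpy arrays (plus JSON-able attrs) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for key, value in arrays.items():
            f.create_dataset(key, data=np.asarray(value))
        for key, value in (attrs or {}).items():
            f.attrs[key] = json.dumps(value)
    return path


def load_array_group(path: str | Path) -> tuple[dict, dict]:
    with h5py.File(path, "r") as f:
        arrays = {key: f[key][()] for key in f.keys()}
        attrs = {key: json.loads(f.attrs[key]) for key in f.attrs.keys()}
    return arrays, attrs
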