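"""Reading and writing recordings, ground truth and study bundles.

Formats:

* raw recording: CSV with header ``time_s,ax_g,ay_g,az_g`` (uniform rate);
* study bundle: HDF5 laid out ``/{subject}/{visit}/{task}/{location}`` with
  an ``fs_hz`` attribute per dataset;
* metadata: tidy CSV ``subject,visit,task,location,age,height_m,file``;
* ground truth: one JSON per recording (events, bouts, per-stride truth).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import AccelRecording, GaitEvents, GroundTruth

__all__ = [
    "write_recording_csv", "read_recording_csv",
    "write_study_hdf5", "read_recording_hdf5",
    "write_ground_truth_json", "read_ground_truth_json",
    "load_yaml", "dump_yaml",
]

CSV_HEADER = ["time_s", "ax_g", "ay_g", "az_g"]


def write_recording_csv(rec: AccelRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.time, "ax_g": rec.accel[:, 0],
                       "ay_g": rec.accel[:, 1], "az_g": rec.accel[:, 2]})
    df.to_csv(path, index=False, float_format="%.8f")


def read_recording_csv(path: str | Path, fs: float | None = None,
                       **meta) -> AccelRecording:
    df = pd.read_csv(path)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV missing columns {missing}")
    t = df["time_s"].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from < 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy()
    return AccelRecording(time=t, accel=accel, fs=float(round(fs, 6)), **meta)


def write_study_hdf5(recordings: dict, path: str | Path) -> None:
    """Write ``{(subject, visit, task, location): AccelRecording}`` to HDF5."""
    with h5py.File(path, "w") as f:
        for (subject, visit, task, location), rec in recordings.items():
            grp = f.require_group(f"{subject}/{visit}/{task}")
            ds = grp.create_dataset(location, data=rec.accel,
                                    compression="gzip", compression_opts=4)
            ds.attrs["fs_hz"] = rec.fs
            if rec.sensor_height is not None:
                ds.attrs["sensor_height_m"] = rec.sensor_height


def read_recording_hdf5(path: str | Path, subject: str, visit: int,
                        task: str, location: str) -> AccelRecording:
    with h5py.File(path, "r") as f:
        ds = f[f"{subject}/{visit}/{task}/{location}"]
        accel = ds[()]
        fs = float(ds.attrs["fs_hz"])
        sh = float(ds.attrs["sensor_height_m"]) if "sensor_height_m" in ds.attrs else None
    t = np.arange(accel.shape[0]) / fs
    return AccelRecording(time=t, accel=accel, fs=fs, subject=subject,
                          visit=visit, task=task, location=location,
                          sensor_height=sh)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "initial_contacts_s": truth.events.initial_contacts.tolist(),
        "final_contacts_s": truth.events.final_contacts.tolist(),
        "bouts_s": [[float(a), float(b)] for a, b in truth.bouts],
        "step_count": truth.step_count,
        "params": {k: float(v) if isinstance(v, (int, float, np.floating)) else v
                   for k, v in truth.params.items()},
        "strides": truth.strides.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        events=GaitEvents(
            initial_contacts=np.array(payload["initial_contacts_s"]),
            final_contacts=np.array(payload["final_contacts_s"])),
        bouts=[tuple(b) for b in payload["bouts_s"]],
        strides=pd.DataFrame(payload["strides"]),
        step_count=int(payload["step_count"]),
        params=payload.get("params", {}))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
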