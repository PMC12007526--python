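"""On-disk formats: HDF5 recordings, WAV stimuli, CSV/TSV tables.

Recording layout (one HDF5 file per block)::

    /data        float32, usable channels x samples, tesla
    /fs          scalar, Hz
    /events      int64 (n, 1) sample indices + string labels attribute
    /headpos     (2, 3, 3): pre/post x coils x axes, mm
    /truth_json  generator ground-truth sidecar (JSON string)
    /sensors     channel positions, normals, baseline, disabled list
    /preproc     optional provenance group written after cleaning
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import HeadModel, SensorArray
from .simulate import SensorRecording

__all__ = ["save_recording", "load_recording", "write_wav",
           "write_events_tsv", "save_cohort_csv"]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_recording(path: str | Path, rec: SensorRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f["fs"] = rec.fs
        samples = np.array([s for s, _ in rec.events], dtype=np.int64)
        ev = f.create_dataset("events", data=samples)
        ev.attrs["labels"] = json.dumps([lab for _, lab in rec.events])
        f.create_dataset("headpos", data=np.stack([rec.headpos_pre,
                                                   rec.headpos_post]))
        f.attrs["condition"] = rec.condition
        f.attrs["block_id"] = rec.block_id
        f["truth_json"] = json.dumps(rec.truth, default=_json_default)
        g = f.create_group("sensors")
        g.create_dataset("positions_mm", data=rec.array.positions_mm)
        g.create_dataset("normals", data=rec.array.normals)
        g.attrs["baseline_mm"] = rec.array.baseline_mm
        g.attrs["disabled"] = rec.array.disabled
        g.attrs["head_center_mm"] = list(rec.head.center_mm)
        g.attrs["head_radius_mm"] = rec.head.radius_mm


def load_recording(path: str | Path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        g = f["sensors"]
        array = SensorArray(
            positions_mm=g["positions_mm"][()], normals=g["normals"][()],
            baseline_mm=float(g.attrs["baseline_mm"]),
            disabled=list(g.attrs["disabled"]))
        head = HeadModel(center_mm=tuple(g.attrs["head_center_mm"]),
                         radius_mm=float(g.attrs["head_radius_mm"]))
        labels = json.loads(f["events"].attrs["labels"])
        events = list(zip(f["events"][()].tolist(), labels))
        return SensorRecording(
            data=f["data"][()].astype(np.float64), fs=float(f["fs"][()]),
            events=events, headpos_pre=f["headpos"][0],
            headpos_post=f["headpos"][1],
            condition=str(f.attrs["condition"]),
            block_id=int(f.attrs["block_id"]), array=array, head=head,
            truth=json.loads(f["truth_json"][()]))


def write_wav(path: str | Path, waveform: np.ndarray, fs_hz: float) -> None:
    """16-bit PCM export, peak-normalized to -1 dBFS."""
    from scipy.io import wavfile
    peak = np.max(np.abs(waveform))
    scaled = waveform / peak * 10 ** (-1 / 20) if peak > 0 else waveform
    wavfile.write(path, int(fs_hz), (scaled * 32767).astype(np.int16))


def write_events_tsv(path: str | Path, events: list[tuple[float, str]]) -> None:
    with open(path, "w") as f:
        f.write("onset_ms\tlabel\n")
        for onset, label in events:
            f.write(f"{onset:g}\t{label}\n")


def save_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
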