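"""Reading and writing the pipeline's on-disk formats.

Tabular data (isotopomer panels, trial tables, Ct tables, event lists,
tracks) travel as delimited CSV; trace containers (sweep sets, holding-
current traces) as HDF5 with sampling-rate and protocol metadata; ground
truth as JSON or YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import EventSeries
from .intrinsic import StepProtocol, SweepSet

__all__ = [
    "save_sweepset",
    "load_sweepset",
    "save_trace",
    "load_trace",
    "events_to_frame",
    "ground_truth_to_dict",
    "save_ground_truth",
    "load_ground_truth_dict",
]


def save_sweepset(path: str | Path, ss: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps", data=ss.sweeps)
        f.attrs["fs"] = ss.fs
        f.attrs["currents"] = list(ss.protocol.currents)
        f.attrs["step_start"] = ss.protocol.step_start
        f.attrs["step_dur"] = ss.protocol.step_dur
        f.attrs["sweep_dur"] = ss.protocol.sweep_dur
        if ss.spike_times is not None:
            g = f.create_group("spike_times")
            for i, st in enumerate(ss.spike_times):
                g.create_dataset(str(i), data=np.asarray(st))


def load_sweepset(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        protocol = StepProtocol(
            currents=tuple(float(c) for c in f.attrs["currents"]),
            step_start=float(f.attrs["step_start"]),
            step_dur=float(f.attrs["step_dur"]),
            sweep_dur=float(f.attrs["sweep_dur"]),
        )
        spikes = None
        if "spike_times" in f:
            g = f["spike_times"]
            spikes = [np.asarray(g[str(i)]) for i in range(len(g))]
        return SweepSet(np.asarray(f["sweeps"]), protocol, float(f.attrs["fs"]),
                        spike_times=spikes)


def save_trace(path: str | Path, trace: np.ndarray, fs: float, **meta) -> None:
    """One named-channel current/voltage trace with metadata attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trace", data=np.asarray(trace))
        f.attrs["fs"] = fs
        for k, v in meta.items():
            f.attrs[k] = v


def load_trace(path: str | Path) -> tuple[np.ndarray, float, dict]:
    with h5py.File(path, "r") as f:
        meta = {k: f.attrs[k] for k in f.attrs if k != "fs"}
        return np.asarray(f["trace"]), float(f.attrs["fs"]), meta


def events_to_frame(series: EventSeries) -> pd.DataFrame:
    """Per-event table (onset s, amplitude pA, preceding IEI ms)."""
    iei = np.concatenate([[np.nan], series.iei_ms]) if len(series) else np.array([])
    return pd.DataFrame(
        {
            "onset_s": series.onsets,
            "amplitude_pa": series.amplitudes,
            "iei_ms": iei,
            "cell_id": series.cell_id,
            "condition": series.condition,
        }
    )


def ground_truth_to_dict(truth) -> dict:
    return dataclasses.asdict(truth)


def save_ground_truth(path: str | Path, truth) -> None:
    """Serialise ground truth as JSON or YAML depending on the suffix."""
    path = Path(path)
    d = ground_truth_to_dict(truth)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_ground_truth_dict(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)
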