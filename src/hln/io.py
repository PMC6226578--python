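"""File formats: spike sets and voltage traces as HDF5 or CSV, YAML configs.

Spike sets
----------
HDF5 layout: one group per synapse under ``/spikes`` holding a ragged
``times`` dataset (ms) with ``label`` and ``ensemble_id`` attributes.
CSV layout: long format with header ``synapse_id,time_ms,label,ensemble_id``,
comma-separated, times printed with 3 decimals (bit-exact round trips at
millisecond-grid precision); a synapse with no spikes appears as a single
row with an empty ``time_ms`` field.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .signals import SpikeTrain, SpikeTrainSet, TimeGrid

__all__ = [
    "read_spike_set",
    "write_spike_set",
    "read_voltage",
    "write_voltage",
    "load_yaml",
    "save_yaml",
    "config_hash",
]

_TIME_FMT = "%.3f"


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5", ".hdf")


def write_spike_set(path: str | Path, spikes: SpikeTrainSet, attrs: dict | None = None) -> None:
    """Write a spike set as HDF5 or CSV (chosen by extension)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            grp = f.create_group("spikes")
            for sid, tr in spikes.items():
                g = grp.create_group(str(sid))
                g.create_dataset("times", data=tr.times)
                g.attrs["label"] = tr.label
                g.attrs["ensemble_id"] = tr.ensemble_id
            for k, v in (attrs or {}).items():
                f.attrs[k] = v
    else:
        rows = []
        for sid, tr in spikes.items():
            if len(tr) == 0:
                rows.append((sid, "", tr.label, tr.ensemble_id))
            for t in tr.times:
                rows.append((sid, _TIME_FMT % t, tr.label, tr.ensemble_id))
        df = pd.DataFrame(rows, columns=["synapse_id", "time_ms", "label", "ensemble_id"])
        df.to_csv(path, index=False)


def read_spike_set(path: str | Path) -> SpikeTrainSet:
    """Read a spike set written by :func:`write_spike_set`.

    Unsorted spike times are sorted with a warning; unknown labels raise a
    ``ValueError`` naming the offending record.
    """
    path = Path(path)
    out = SpikeTrainSet()
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "spikes" not in f:
                raise ValueError(f"{path}: no /spikes group")
            for name, g in f["spikes"].items():
                sid = int(name)
                label = g.attrs.get("label", "excitatory")
                if isinstance(label, bytes):
                    label = label.decode()
                eid = int(g.attrs.get("ensemble_id", 0))
                times = np.asarray(g["times"][()], dtype=float)
                _check(sid, label, times)
                out.add(sid, SpikeTrain(times, label, eid))
    else:
        df = pd.read_csv(path)
        required = {"synapse_id", "time_ms", "label", "ensemble_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        for sid, sub in df.groupby("synapse_id"):
            label = str(sub["label"].iloc[0])
            eid = int(sub["ensemble_id"].iloc[0])
            times = sub["time_ms"].dropna().to_numpy(dtype=float)
            _check(int(sid), label, times)
            out.add(int(sid), SpikeTrain(times, label, eid))
    return out


def _check(sid: int, label: str, times: np.ndarray) -> None:
    if label not in SpikeTrain.VALID_LABELS:
        raise ValueError(f"synapse {sid}: unknown label {label!r}")
    if times.size and np.any(np.diff(times) < 0):
        warnings.warn(f"synapse {sid}: spike times were not sorted; sorting", stacklevel=3)


def write_voltage(path: str | Path, v: np.ndarray, grid: TimeGrid) -> None:
    """Write a voltage trace (mV) as HDF5 or CSV (time_ms, mv)."""
    path = Path(path)
    v = np.asarray(v, dtype=float)
    if v.shape[0] != grid.n_bins:
        raise ValueError("trace length does not match the grid")
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("voltage", data=v)
            d.attrs["dt"] = grid.dt
            d.attrs["t0"] = grid.t0
    else:
        pd.DataFrame({"time_ms": grid.times(), "mv": v}).to_csv(path, index=False)


def read_voltage(path: str | Path) -> tuple[np.ndarray, TimeGrid]:
    """Read a voltage trace; returns (values, grid)."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            d = f["voltage"]
            v = np.asarray(d[()], dtype=float)
            grid = TimeGrid(dt=float(d.attrs["dt"]), n_bins=v.shape[0], t0=float(d.attrs.get("t0", 0.0)))
        return v, grid
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    v = df["mv"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return v, TimeGrid(dt=dt, n_bins=v.shape[0], t0=float(t[0] - dt / 2) if t.size else 0.0)


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (embedded in artifacts)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
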