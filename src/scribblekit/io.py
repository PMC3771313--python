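"""Readers, writers and run configuration.

All artifacts are plain CSV (time unit: seconds) so every intermediate
is inspectable; a run configuration is a flat JSON-serializable mapping
whose hash is logged into output headers for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .spikehmm import SpikeTrainSet
from .synfire import Raster

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_spikes",
    "write_spikes",
    "read_raster",
    "write_raster",
]


@dataclass
class RunConfig:
    """Parameters, seed and paths of one pipeline stage.

    The mapping is flat and JSON-serializable; ``config_hash`` of the
    canonical JSON is logged in every output so a run can be matched to
    the exact configuration that produced it.
    """

    params: dict = field(default_factory=dict)
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params, "seed": self.seed, "inputs": self.inputs,
             "outputs": self.outputs, "log_level": self.log_level},
            sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {"params", "seed", "inputs", "outputs", "log_level"}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def merge_params(self, overrides: dict) -> "RunConfig":
        """New config with non-None override values applied to params."""
        params = dict(self.params)
        params.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(params=params, seed=self.seed, inputs=self.inputs,
                         outputs=self.outputs, log_level=self.log_level)


# ---------------------------------------------------------------------------
# Trajectories: CSV with header t,x,y
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, rtol: float = 1e-6) -> Trajectory:
    """Read a trajectory CSV (columns ``t,x,y``, seconds and mm).

    Rejects missing columns, NaN rows (reporting row numbers) and
    non-uniform sampling beyond ``rtol`` of the median step (reporting
    the offending indices).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[["t", "x", "y"]].isna().any(axis=1)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(f"{path}: NaN values in rows {rows[:20]}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 2:
        dt = np.diff(t)
        step = np.median(dt)
        off = np.flatnonzero(np.abs(dt - step) > rtol * max(abs(step), 1e-12))
        if off.size:
            raise ValueError(
                f"{path}: non-uniform sampling at indices {off[:20].tolist()}")
    return Trajectory(t=t, x=df["x"].to_numpy(dtype=float),
                      y=df["y"].to_numpy(dtype=float))


def write_trajectory(traj: Trajectory, path: str | Path,
                     header_note: str | None = None) -> None:
    """Write a trajectory as CSV ``t,x,y`` (full precision round-trip)."""
    with open(path, "w") as f:
        if header_note:
            f.write(f"# {header_note}\n")
        f.write("t,x,y\n")
        for t, x, y in zip(traj.t, traj.x, traj.y):
            f.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Spike trains: CSV with header unit_id,electrode_id,t
# ---------------------------------------------------------------------------

def read_spikes(path: str | Path, duration: float | None = None,
                refractory: float = 1e-3) -> SpikeTrainSet:
    """Read a spike CSV (columns ``unit_id,electrode_id,t``, seconds).

    Unsorted spike times are sorted with a warning; spikes of one unit
    closer than ``refractory`` are an error.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("unit_id", "electrode_id", "t") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    units = []
    if len(df):
        for (uid, eid), grp in df.groupby(["unit_id", "electrode_id"],
                                          sort=True):
            st = grp["t"].to_numpy(dtype=float)
            if st.size > 1 and np.any(np.diff(st) < 0):
                warnings.warn(f"unit {uid}: spike times were unsorted")
                st = np.sort(st)
            if st.size > 1 and np.diff(st).min() < refractory:
                raise ValueError(
                    f"unit {uid}: spike intervals below the refractory "
                    f"period ({refractory * 1e3:g} ms)")
            units.append({"unit_id": uid, "electrode_id": eid,
                          "spike_times": st})
    if duration is None:
        duration = float(df["t"].max()) if len(df) else 0.0
    return SpikeTrainSet(units=units, duration=duration)


def write_spikes(spikes: SpikeTrainSet, path: str | Path,
                 header_note: str | None = None) -> None:
    """Write spike trains as CSV ``unit_id,electrode_id,t``."""
    with open(path, "w") as f:
        if header_note:
            f.write(f"# {header_note}\n")
        f.write("unit_id,electrode_id,t\n")
        for u in spikes.units:
            for t in u["spike_times"]:
                f.write(f"{u['unit_id']},{u['electrode_id']},{float(t)!r}\n")


# ---------------------------------------------------------------------------
# Rasters: CSV with header neuron_id,t
# ---------------------------------------------------------------------------

def read_raster(path: str | Path, n_neurons: int | None = None,
                duration: float | None = None) -> Raster:
    """Read a simulation raster CSV (columns ``neuron_id,t``)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("neuron_id", "t") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ids = df["neuron_id"].to_numpy(dtype=np.int64)
    ts = df["t"].to_numpy(dtype=float)
    if n_neurons is None:
        n_neurons = int(ids.max()) + 1 if ids.size else 0
    if duration is None:
        duration = float(ts.max()) if ts.size else 0.0
    return Raster(neuron_ids=ids, times=ts, n_neurons=n_neurons,
                  duration=duration)


def write_raster(raster: Raster, path: str | Path,
                 header_note: str | None = None) -> None:
    """Write a raster as CSV ``neuron_id,t``."""
    with open(path, "w") as f:
        if header_note:
            f.write(f"# {header_note}\n")
        f.write("neuron_id,t\n")
        for i, t in zip(raster.neuron_ids, raster.times):
            f.write(f"{i},{float(t)!r}\n")
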