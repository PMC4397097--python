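"""HDF5/CSV persistence for trajectories, connectivity matrices and fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .network import DelayMatrix, Network
from .simulate import SimulationConfig, TrajectorySet
from .synthetic import BrainLikeFixture

__all__ = [
    "save_trajectories",
    "load_trajectories",
    "save_fixture",
    "load_fixture",
    "save_matrix_csv",
    "load_matrix_csv",
]


def _config_to_json(cfg: SimulationConfig) -> str:
    d = asdict(cfg)
    delays = d.pop("delays")
    if delays is not None:
        d["delays_mode"] = delays["mode"]
        d["delays_speed"] = delays["speed"]
    return json.dumps(d, default=lambda o: None)


def save_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("r", data=traj.r, compression="gzip")
        f.create_dataset("theta", data=traj.theta, compression="gzip")
        f.create_dataset("omegas", data=traj.omegas)
        f.attrs["fs"] = traj.fs
        f.attrs["retained_from"] = traj.retained_from
        if traj.config is not None:
            f.attrs["config"] = _config_to_json(traj.config)
            if traj.config.delays is not None:
                f.create_dataset("delays", data=traj.config.delays.values)


def load_trajectories(path: str | Path) -> TrajectorySet:
    with h5py.File(path, "r") as f:
        cfg = None
        if "config" in f.attrs:
            d = json.loads(f.attrs["config"])
            mode = d.pop("delays_mode", None)
            speed = d.pop("delays_speed", None)
            if "delays" in f:
                d["delays"] = DelayMatrix(f["delays"][()], mode=mode or "constant", speed=speed)
            cfg = SimulationConfig(**d)
        return TrajectorySet(
            r=f["r"][()],
            theta=f["theta"][()],
            fs=float(f.attrs["fs"]),
            retained_from=int(f.attrs["retained_from"]),
            omegas=f["omegas"][()],
            config=cfg,
        )


def save_fixture(fix: BrainLikeFixture, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("adjacency", data=fix.network.adjacency)
        if fix.network.coordinates is not None:
            f.create_dataset("coordinates", data=fix.network.coordinates)
        for state, rec in fix.state_recordings.items():
            f.create_dataset(f"recordings/{state}", data=rec, compression="gzip")
        f.attrs["fs"] = fix.fs
        f.create_dataset("truth/degree", data=fix.truth["degree"].to_numpy())
        f.create_dataset(
            "truth/group", data=np.array(fix.truth["group"], dtype=h5py.string_dtype())
        )


def load_fixture(path: str | Path) -> BrainLikeFixture:
    import pandas as pd

    with h5py.File(path, "r") as f:
        coords = f["coordinates"][()] if "coordinates" in f else None
        net = Network(f["adjacency"][()], coordinates=coords)
        recs = {k: f[f"recordings/{k}"][()] for k in f["recordings"]}
        truth = pd.DataFrame(
            {
                "node": np.arange(net.n_nodes),
                "degree": f["truth/degree"][()],
                "group": [s.decode() for s in f["truth/group"][()]],
            }
        )
        return BrainLikeFixture(network=net, state_recordings=recs, fs=float(f.attrs["fs"]), truth=truth)


def save_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=",")


def load_matrix_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")
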