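"""Trajectory container and HDF5 persistence.

Schema of the HDF5 file:
    /times          (T,)      float64, strictly increasing sample times [s]
    /counts         (T, K, S) int32, molecule counts per voxel per species
    attrs: seed, model_name, model_hash, mesh_hash, event_count,
           species (comma-joined names)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Trajectory", "save_trajectory", "load_trajectory"]


@dataclass
class Trajectory:
    times: np.ndarray             # (T,) seconds
    counts: np.ndarray            # (T, K, S)
    species: list                 # S names, ordered as in counts
    seed: int = 0
    model_name: str = ""
    model_hash: str = ""
    mesh_hash: str = ""
    event_count: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(self.times):
            raise ValueError("counts must have shape (T, K, S) matching times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.counts.shape[2] != len(self.species):
            raise ValueError("species list does not match counts shape")

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def S(self) -> int:
        return self.counts.shape[2]

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def state(self, t_index: int) -> np.ndarray:
        """The (K, S) state matrix at one sample index."""
        return self.counts[t_index]

    def totals(self, name: str | None = None) -> np.ndarray:
        """Per-snapshot total copy numbers, for one species or all (T, S)."""
        if name is None:
            return self.counts.sum(axis=1)
        return self.counts[:, :, self.species_index(name)].sum(axis=1)

    def append(self, times: np.ndarray, counts: np.ndarray) -> "Trajectory":
        """Extend with later samples; times must continue increasing."""
        times = np.asarray(times, dtype=float)
        if len(times) and len(self.times) and times[0] <= self.times[-1]:
            raise ValueError("appended samples must start after the last time")
        return Trajectory(
            times=np.concatenate([self.times, times]),
            counts=np.concatenate([self.counts, counts], axis=0),
            species=self.species,
            seed=self.seed,
            model_name=self.model_name,
            model_hash=self.model_hash,
            mesh_hash=self.mesh_hash,
            event_count=self.event_count,
        )


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("counts", data=traj.counts.astype(np.int32),
                         compression="gzip", compression_opts=4)
        f.attrs["seed"] = traj.seed
        f.attrs["model_name"] = traj.model_name
        f.attrs["model_hash"] = traj.model_hash
        f.attrs["mesh_hash"] = traj.mesh_hash
        f.attrs["event_count"] = traj.event_count
        f.attrs["species"] = ",".join(traj.species)


def load_trajectory(path, expect_mesh_hash: str | None = None) -> Trajectory:
    with h5py.File(path, "r") as f:
        traj = Trajectory(
            times=f["times"][:],
            counts=f["counts"][:],
            species=str(f.attrs["species"]).split(","),
            seed=int(f.attrs["seed"]),
            model_name=str(f.attrs["model_name"]),
            model_hash=str(f.attrs["model_hash"]),
            mesh_hash=str(f.attrs["mesh_hash"]),
            event_count=int(f.attrs["event_count"]),
        )
    if expect_mesh_hash is not None and traj.mesh_hash != expect_mesh_hash:
        warnings.warn(
            f"trajectory mesh hash {traj.mesh_hash} does not match the "
            f"expected mesh {expect_mesh_hash}",
            RuntimeWarning,
            stacklevel=2,
        )
    return traj
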