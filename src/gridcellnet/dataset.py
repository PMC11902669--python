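"""Sharded on-disk storage for trajectory datasets.

A dataset is a directory of HDF5 shards (``shard_000.h5`` ...) plus a
``manifest.json``.  Shards store kinematics only — initial pose, per-step
self-motion inputs and per-step target poses — not activation matrices:
labels are rematerialised on read from the ensemble parameters embedded in
the manifest, so the same dataset supports sweeps over ensemble size or
scale.  The first ``train_files`` shard indices form the training split and
the rest the evaluation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

from .arena import Trajectory, egocentric_inputs
from .population import (
    HeadDirectionEnsemble,
    PlaceCellEnsemble,
    hd_activations,
    place_activations,
)

__all__ = [
    "TrajectoryRecord",
    "DatasetManifest",
    "DatasetIntegrityError",
    "write_dataset",
    "read_manifest",
    "read_split",
    "materialize_labels",
]

MANIFEST_NAME = "manifest.json"


class DatasetIntegrityError(RuntimeError):
    """A shard is missing or does not match the manifest."""


@dataclass
class TrajectoryRecord:
    """One episode as stored on disk: initial pose, inputs and target poses."""

    init_position: np.ndarray  # (2,)
    init_heading: float
    inputs: np.ndarray  # (n_steps, 3): v, sin(phi), cos(phi)
    target_positions: np.ndarray  # (n_steps, 2)
    target_headings: np.ndarray  # (n_steps,)

    def __post_init__(self) -> None:
        self.init_position = np.asarray(self.init_position, float)
        self.inputs = np.asarray(self.inputs, float)
        self.target_positions = np.asarray(self.target_positions, float)
        self.target_headings = np.asarray(self.target_headings, float)
        n = self.inputs.shape[0]
        if self.target_positions.shape[0] != n or self.target_headings.shape[0] != n:
            raise ValueError("per-step arrays must have equal length")

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "TrajectoryRecord":
        return cls(
            init_position=traj.positions[0].copy(),
            init_heading=float(traj.headings[0]),
            inputs=egocentric_inputs(traj),
            target_positions=traj.positions[1:].copy(),
            target_headings=traj.headings[1:].copy(),
        )


@dataclass
class DatasetManifest:
    """Dataset layout, ensemble parameters and provenance."""

    n_files: int = 100
    train_files: int = 70
    eval_files: int = 30
    records_per_file: int = 0
    n_steps: int = 100
    master_seed: int = 0
    arena: dict = field(default_factory=dict)
    place_ensemble: dict = field(default_factory=dict)
    hd_ensemble: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_files + self.eval_files != self.n_files:
            raise ValueError("train_files + eval_files must equal n_files")

    def shard_indices(self, split: str) -> range:
        if split == "train":
            return range(self.train_files)
        if split == "eval":
            return range(self.train_files, self.n_files)
        raise ValueError(f"unknown split {split!r}")

    def ensembles(self) -> tuple[PlaceCellEnsemble, HeadDirectionEnsemble]:
        return (
            PlaceCellEnsemble.from_dict(self.place_ensemble),
            HeadDirectionEnsemble.from_dict(self.hd_ensemble),
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        return cls(**json.loads(text))


def _shard_path(out: Path, index: int) -> Path:
    return out / f"shard_{index:03d}.h5"


def write_dataset(
    records: Sequence[TrajectoryRecord],
    out: str | Path,
    manifest: DatasetManifest,
) -> Path:
    """Partition ``records`` into ``manifest.n_files`` HDF5 shards.

    The record count must divide evenly; records keep their order, so shard k
    holds records [k*r, (k+1)*r).  Returns the manifest path.
    """
    out = Path(out)
    if len(records) % manifest.n_files != 0:
        raise ValueError(
            f"{len(records)} records cannot be split into {manifest.n_files} equal files"
        )
    per_file = len(records) // manifest.n_files
    manifest.records_per_file = per_file
    manifest.n_steps = records[0].n_steps
    out.mkdir(parents=True, exist_ok=True)
    for k in range(manifest.n_files):
        chunk = records[k * per_file : (k + 1) * per_file]
        with h5py.File(_shard_path(out, k), "w") as f:
            f.attrs["split"] = "train" if k < manifest.train_files else "eval"
            f.attrs["shard_index"] = k
            f.create_dataset("init_position", data=np.stack([r.init_position for r in chunk]))
            f.create_dataset("init_heading", data=np.array([r.init_heading for r in chunk]))
            f.create_dataset("inputs", data=np.stack([r.inputs for r in chunk]))
            f.create_dataset(
                "target_positions", data=np.stack([r.target_positions for r in chunk])
            )
            f.create_dataset(
                "target_headings", data=np.stack([r.target_headings for r in chunk])
            )
    manifest_path = out / MANIFEST_NAME
    manifest_path.write_text(manifest.to_json())
    return manifest_path


def read_manifest(directory: str | Path) -> DatasetManifest:
    path = Path(directory) / MANIFEST_NAME
    if not path.exists():
        raise DatasetIntegrityError(f"missing manifest: {path}")
    return DatasetManifest.from_json(path.read_text())


def read_split(directory: str | Path, split: str) -> Iterator[TrajectoryRecord]:
    """Yield records of one split in deterministic shard-index order."""
    directory = Path(directory)
    manifest = read_manifest(directory)
    for k in manifest.shard_indices(split):
        path = _shard_path(directory, k)
        if not path.exists():
            raise DatasetIntegrityError(f"missing shard file: {path}")
        with h5py.File(path, "r") as f:
            try:
                init_pos = f["init_position"][:]
                init_head = f["init_heading"][:]
                inputs = f["inputs"][:]
                tpos = f["target_positions"][:]
                thead = f["target_headings"][:]
            except KeyError as exc:
                raise DatasetIntegrityError(f"corrupt shard file: {path}") from exc
        if inputs.shape[0] != manifest.records_per_file:
            raise DatasetIntegrityError(
                f"shard {path} holds {inputs.shape[0]} records, "
                f"manifest says {manifest.records_per_file}"
            )
        for i in range(inputs.shape[0]):
            yield TrajectoryRecord(
                init_pos[i], float(init_head[i]), inputs[i], tpos[i], thead[i]
            )


def materialize_labels(
    rec: TrajectoryRecord,
    pc: PlaceCellEnsemble,
    hd: HeadDirectionEnsemble,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-step supervision targets plus the time-0 activations.

    Returns (place targets (n_steps, N), head-direction targets (n_steps, M),
    (place, head-direction) activations of the initial pose).  The time-0
    pair seeds the recurrent state of the network.
    """
    pc_targets = place_activations(rec.target_positions, pc)
    hd_targets = hd_activations(rec.target_headings, hd)
    pc0 = place_activations(rec.init_position, pc)
    hd0 = hd_activations(np.asarray(rec.init_heading), hd)
    return pc_targets, hd_targets, (pc0, hd0)
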