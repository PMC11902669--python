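"""Three-stage pipeline: generate-data -> train -> analyze.

Every stage is idempotent: it checks for its output artifact and returns
immediately when the artifact already exists, so a run directory can be
resumed after interruption.  All randomness derives from one master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import ArenaConfig, generate_trajectory, trajectory_rng
from .dataset import (
    DatasetManifest,
    TrajectoryRecord,
    read_manifest,
    read_split,
    write_dataset,
)
from .network import (
    NetworkConfig,
    NetworkParams,
    collect_activations,
    train,
)
from .population import init_hd_centers, init_place_centers
from .analysis import plot_unit_grid, rank_units

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "summarize_run",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed while producing {artifact}: {cause}")
        self.stage = stage
        self.artifact = artifact


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs, from one master seed."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_trajectories: int = 500
    n_files: int = 100
    train_files: int = 70
    n_place: int = 256
    n_hd: int = 12
    place_scale: float = 0.35
    hd_concentration: float = 20.0
    bins: int = 32
    thresholds: dict = field(default_factory=dict)
    top_k_plots: int = 16
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.arena, dict):
            self.arena = ArenaConfig(**self.arena)
        if isinstance(self.network, dict):
            self.network = NetworkConfig(**self.network)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage integer seeds below 2**31."""
        state = np.random.SeedSequence(self.master_seed).generate_state(4)
        names = ("place_centers", "hd_centers", "trajectories", "network")
        return {k: int(s % 2**31) for k, s in zip(names, state)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arena"] = self.arena.to_dict()
        d["network"] = self.network.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def stage_generate(cfg: PipelineConfig, run_dir: Path) -> Path:
    """Simulate trajectories and write the sharded dataset (idempotent)."""
    out = run_dir / "dataset"
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        return out
    seeds = cfg.stage_seeds()
    pc = init_place_centers(
        cfg.n_place, cfg.arena, np.random.default_rng(seeds["place_centers"]),
        scale=cfg.place_scale,
    )
    hd = init_hd_centers(
        cfg.n_hd, np.random.default_rng(seeds["hd_centers"]),
        concentration=cfg.hd_concentration,
    )
    records = [
        TrajectoryRecord.from_trajectory(
            generate_trajectory(cfg.arena, trajectory_rng(seeds["trajectories"], i))
        )
        for i in range(cfg.n_trajectories)
    ]
    manifest = DatasetManifest(
        n_files=cfg.n_files,
        train_files=cfg.train_files,
        eval_files=cfg.n_files - cfg.train_files,
        master_seed=cfg.master_seed,
        arena=cfg.arena.to_dict(),
        place_ensemble=pc.to_dict(),
        hd_ensemble=hd.to_dict(),
    )
    write_dataset(records, out, manifest)
    return out


def stage_train(cfg: PipelineConfig, run_dir: Path) -> Path:
    """Train the network on the train split (idempotent)."""
    ckpt_dir = run_dir / "checkpoints"
    ckpt = ckpt_dir / "checkpoint.npz"
    if ckpt.exists():
        return ckpt_dir
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    data_dir = run_dir / "dataset"
    manifest = read_manifest(data_dir)
    pc, hd = manifest.ensembles()
    net_cfg = NetworkConfig(
        **{
            **cfg.network.to_dict(),
            "n_place": pc.n_cells,
            "n_hd": hd.n_cells,
            "seed": cfg.stage_seeds()["network"],
        }
    )
    train_records = list(read_split(data_dir, "train"))
    eval_records = list(read_split(data_dir, "eval"))
    params, log = train(train_records, eval_records, pc, hd, net_cfg, ckpt_dir)
    params.save(ckpt, net_cfg)
    pd.DataFrame(log).to_csv(ckpt_dir / "metrics.csv", index=False)
    return ckpt_dir


def stage_analyze(cfg: PipelineConfig, run_dir: Path) -> Path:
    """Score the spatial tuning of every linear-layer unit (idempotent)."""
    out = run_dir / "analysis"
    report_path = out / "tuning_report.csv"
    if report_path.exists():
        return out
    out.mkdir(parents=True, exist_ok=True)
    data_dir = run_dir / "dataset"
    manifest = read_manifest(data_dir)
    pc, hd = manifest.ensembles()
    params = NetworkParams.load(run_dir / "checkpoints" / "checkpoint.npz")
    eval_records = list(read_split(data_dir, "eval"))
    positions, headings, acts = collect_activations(eval_records, params, pc, hd)
    report, ratemaps, sacs = rank_units(
        positions, headings, acts,
        bins=cfg.bins, extent=cfg.arena.half_width, thresholds=cfg.thresholds,
    )
    report.save(report_path)
    (out / "thresholds.json").write_text(json.dumps(report.thresholds, indent=1))
    top = report.table.head(cfg.top_k_plots)
    units = top["unit"].to_numpy()
    scores = top["gridness"].to_numpy()
    plot_unit_grid(
        [ratemaps[u].values for u in units], list(scores), out / "ratemaps.png"
    )
    sac_maps, sac_scores = [], []
    for u, s in zip(units, scores):
        if sacs[u] is not None:
            sac_maps.append(sacs[u].values)
            sac_scores.append(s)
    if sac_maps:
        plot_unit_grid(sac_maps, sac_scores, out / "autocorrelograms.png")
    return out


_STAGES = (
    ("generate-data", stage_generate, "dataset/manifest.json"),
    ("train", stage_train, "checkpoints/checkpoint.npz"),
    ("analyze", stage_analyze, "analysis/tuning_report.csv"),
)


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> dict[str, Path]:
    """Execute all stages in order inside ``run_dir``; returns artifact paths."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    artifacts: dict[str, Path] = {}
    for name, fn, artifact in _STAGES:
        try:
            artifacts[name] = fn(cfg, run_dir)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineStageError(name, artifact, exc) from exc
    return artifacts


def summarize_run(run_dir: str | Path, top_k: int = 5) -> dict:
    """Headline metrics of a finished (or partial) run."""
    run_dir = Path(run_dir)
    summary: dict = {"run_dir": str(run_dir), "warnings": []}
    config_path = run_dir / "config.json"
    if config_path.exists():
        summary["config"] = json.loads(config_path.read_text())
    metrics_path = run_dir / "checkpoints" / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        evald = metrics.dropna(subset=["eval_pos_error"]) if "eval_pos_error" in metrics else metrics
        if len(evald):
            summary["final_eval_loss"] = float(evald["eval_loss"].iloc[-1])
            summary["final_eval_pos_error_m"] = float(evald["eval_pos_error"].iloc[-1])
    else:
        summary["warnings"].append("train stage incomplete: no metrics.csv")
    report_path = run_dir / "analysis" / "tuning_report.csv"
    if report_path.exists():
        table = pd.read_csv(report_path)
        top = table.head(top_k)
        summary["top_units"] = top[["unit", "gridness", "tag"]].to_dict("records")
        summary["max_gridness"] = float(table["gridness"].max())
        summary["tag_counts"] = table["tag"].value_counts().to_dict()
    else:
        summary["warnings"].append("analyze stage incomplete: no tuning_report.csv")
    for w in summary["warnings"]:
        warnings.warn(w, stacklevel=2)
    return summary
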