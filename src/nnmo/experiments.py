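"""Experiment orchestration, weight-file serialization, and run manifests.

The four scripted computational experiments are:

* ``ensemble``   — train an ensemble of networks on one task and analyse
  its structure-space geometry (distances, cluster count, 3-D projection
  coordinates, distance-histogram modality);
* ``diverge``    — replicate evolutionary trajectories from one shared
  start and tabulate their pairwise divergence per generation;
* ``reduce``     — complexity-reduce trained networks and report
  functional vs potential complexity;
* ``min-size``   — scan network sizes for the smallest trainable one.

Every experiment takes a single master seed; all per-run seeds are
derived as ``SeedSequence([master_seed, run_index])`` (see
:func:`nnmo.evolution.derive_seeds`), so a manifest's config snapshot
reproduces every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .event_stream import StreamConfig, TaskSpec
from .evolution import TrainConfig, train_ensemble, trajectory_divergence
from .net_core import NetworkConfig, WeightMatrix
from .reduction import min_network_search, reduce
from .symmetry import cluster_count, distance_modality, pairwise_distances, project3d

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "save_weights",
    "load_weights",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    experiment: str  # ensemble | diverge | reduce | min-size
    task: str = "A3"
    n_total: int = 6
    master_seed: int = 0
    out_dir: str = "nnmo-out"
    n_runs: int = 8  # ensemble size / replicate count
    sizes: tuple[int, ...] = (5, 6)  # for min-size
    restarts: int = 10  # per size for min-size; per stage for reduce
    steepness_a: float = 1.0
    projection_synapses: tuple[int, int, int] = (25, 26, 31)
    train: TrainConfig = field(default_factory=TrainConfig)
    retrain_budget: int | None = None
    compact: bool = False  # reduce: also emit the minimized configuration

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        train_raw = raw.pop("train", {})
        stream_raw = train_raw.pop("stream_cfg", {}) if isinstance(train_raw, dict) else {}
        train = TrainConfig(stream_cfg=StreamConfig(**stream_raw), **train_raw)
        for key in ("sizes", "projection_synapses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(train=train, **raw)


@dataclass
class RunManifest:
    """Record of one experiment run, sufficient for bit-exact reproduction."""

    experiment: str
    config: dict
    code_version: str
    seeds: list[int]
    files: list[str]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# Weight-file round trip
# ---------------------------------------------------------------------------


def save_weights(w: WeightMatrix, config: NetworkConfig, path: str | Path) -> None:
    """Write a structure as delimited text with a config header.

    Header lines carry the neuron count, role indices, activation
    steepness and the frozen mask (row-major 0/1 string); then one
    tab-separated row of full-precision (hex float) synapse values per
    neuron.  The round trip through :func:`load_weights` is exact.
    """
    lines = [
        f"# n_total: {config.n_total}",
        f"# input_ids: {config.input_ids[0]} {config.input_ids[1]}",
        f"# output_ids: {config.output_ids[0]} {config.output_ids[1]}",
        f"# steepness_a: {config.steepness_a!r}",
        "# frozen: " + "".join("1" if f else "0" for f in w.frozen.ravel()),
    ]
    for row in w.x:
        lines.append("\t".join(float(v).hex() for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_weights(path: str | Path) -> tuple[WeightMatrix, NetworkConfig]:
    """Read a structure written by :func:`save_weights` (lossless)."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed header line") from None
            header[key.strip()] = value.strip()
        else:
            try:
                rows.append([float.fromhex(v) for v in line.split("\t")])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed weight row") from None
    try:
        n = int(header["n_total"])
        input_ids = tuple(int(v) for v in header["input_ids"].split())
        output_ids = tuple(int(v) for v in header["output_ids"].split())
        a = float(header["steepness_a"])
        frozen_bits = header["frozen"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing header field {exc}") from None
    if len(rows) != n or any(len(r) != n for r in rows):
        raise ValueError(f"{path}: expected a {n}x{n} matrix, got {len(rows)} rows")
    if len(frozen_bits) != n * n or set(frozen_bits) - {"0", "1"}:
        raise ValueError(f"{path}: frozen mask must be {n * n} 0/1 characters")
    frozen = np.array([c == "1" for c in frozen_bits]).reshape(n, n)
    config = NetworkConfig(n, input_ids, output_ids, a)  # type: ignore[arg-type]
    return WeightMatrix(np.array(rows), frozen), config


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_experiment(cfg: ExperimentConfig) -> RunManifest:
    """Execute the named experiment and write all outputs plus a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _now()
    task = TaskSpec.from_name(cfg.task)
    net_cfg = NetworkConfig(cfg.n_total, steepness_a=cfg.steepness_a)
    files: list[str] = []
    seeds: list[int] = [cfg.master_seed]

    def emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        files.append(name)
        return p

    if cfg.experiment == "ensemble":
        results = train_ensemble(cfg.n_runs, net_cfg, task, cfg.train, cfg.master_seed)
        trained = [r for r in results if r.success]
        for i, r in enumerate(results):
            name = f"weights_{i:03d}.txt"
            save_weights(r.final_weights, net_cfg, out / name)
            files.append(name)
        summary = pd.DataFrame(
            {
                "run": range(len(results)),
                "success": [r.success for r in results],
                "generations": [r.generations_used for r in results],
                "final_goal": [float(r.trajectory.goals[-1]) for r in results],
            }
        )
        emit("ensemble_summary.csv", summary.to_csv(index=False))
        if len(results) == 1:  # single training run: full per-generation log
            t = results[0].trajectory
            emit(
                "trajectory.csv",
                pd.DataFrame(
                    {"generation": t.generations, "goal": t.goals, "errors": t.errors}
                ).to_csv(index=False),
            )
        if len(trained) >= 2:
            geo = pairwise_distances(
                [r.final_weights for r in trained],
                net_cfg,
                input_swap_allowed=task.input_swap_symmetric,
            )
            n_clusters, labels = cluster_count(geo)
            geo.labels = labels
            emit(
                "distances.csv",
                pd.DataFrame({"distance": geo.distances}).to_csv(index=False),
            )
            emit(
                "clusters.csv",
                pd.DataFrame(
                    {"member": range(geo.n_members), "cluster": labels}
                ).to_csv(index=False),
            )
            proj = project3d([r.final_weights for r in trained], cfg.projection_synapses)
            emit("projection3d.csv", proj.to_csv(index=False))
            if geo.n_members >= 3:
                rep = distance_modality(geo)
                emit(
                    "modality.txt",
                    f"n_modes: {rep.n_modes}\nmultimodal: {rep.multimodal}\n"
                    f"n_clusters: {n_clusters}\n",
                )

    elif cfg.experiment == "diverge":
        rng = np.random.default_rng(cfg.master_seed)
        from .evolution import init_weights

        start = init_weights(net_cfg, cfg.train.init_scale, rng)
        table = trajectory_divergence(
            start, net_cfg, task, cfg.train, cfg.n_runs, base_seed=cfg.master_seed
        )
        emit("divergence.csv", table.to_csv(index=False))

    elif cfg.experiment == "reduce":
        results = train_ensemble(cfg.n_runs, net_cfg, task, cfg.train, cfg.master_seed)
        rows = []
        for i, r in enumerate(results):
            if not r.success:
                rows.append((i, False, -1, -1))
                continue
            w, hist, rep = reduce(
                r.final_weights,
                net_cfg,
                task,
                cfg.train,
                retrain_budget=cfg.retrain_budget,
                restarts=cfg.restarts,
                base_seed=cfg.master_seed * 1000 + i,
            )
            name = f"reduced_{i:03d}.txt"
            save_weights(w, net_cfg, out / name)
            files.append(name)
            if cfg.compact:
                from .reduction import compact as compact_net

                w_small, cfg_small = compact_net(w, net_cfg)
                name = f"reduced_compact_{i:03d}.txt"
                save_weights(w_small, cfg_small, out / name)
                files.append(name)
            rows.append((i, True, rep.functional_complexity, rep.potential_complexity))
        frame = pd.DataFrame(
            rows, columns=["run", "trained", "functional_complexity", "potential_complexity"]
        )
        emit("reduction_summary.csv", frame.to_csv(index=False))

    elif cfg.experiment == "min-size":
        report = min_network_search(
            task,
            list(cfg.sizes),
            cfg.train,
            restarts=cfg.restarts,
            base_seed=cfg.master_seed,
            steepness_a=cfg.steepness_a,
        )
        frame = pd.DataFrame(
            {
                "size": report.sizes,
                "successes": [report.successes[s] for s in report.sizes],
                "restarts": report.restarts,
            }
        )
        emit("size_search.csv", frame.to_csv(index=False))
        emit("min_size.txt", f"min_successful_size: {report.min_successful_size}\n")

    else:
        raise ValueError(f"unknown experiment {cfg.experiment!r}")

    manifest = RunManifest(
        experiment=cfg.experiment,
        config=dataclasses.asdict(cfg),
        code_version=__version__,
        seeds=seeds,
        files=files,
        started=started,
        finished=_now(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
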