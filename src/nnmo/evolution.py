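"""Mirrored random-search evolution of network structures.

The algorithm is a (1+2) evolution strategy with mirrored sampling.  Each
generation: (1) draw one random increment matrix and create two offspring
by adding it to the parent's synapses with opposite signs; (2) run parent
and both offspring through the same freshly generated stream fragment and
score each with the goal function; (3) keep the network with the smallest
goal value.  Training succeeds when the survivor makes zero recognition
errors on its training fragment, its goal value is below a loose bound,
and it then makes zero errors on an independent validation stream.

Heredity is the synapse matrix, variability the mirrored increments, and
selection the survival of the smallest goal value; frozen (pruned)
synapses stay exactly zero throughout, which is what lets complexity
reduction retrain a structure without regrowing removed connections.

Weights and increments are kept on a lattice of multiples of 2**-30 so
that every addition ``w +/- delta`` is exact in double precision: the
mirror identity ``(w_plus + w_minus) / 2 == w`` holds bit for bit and runs
are exactly reproducible.  The lattice spacing (~1e-9) is far below every
other scale in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .event_stream import EventStream, StreamConfig, TaskSpec, generate_stream
from .net_core import DEFAULT_THRESHOLD, NetworkConfig, WeightMatrix, evaluate

__all__ = [
    "QUANTUM",
    "TrainConfig",
    "Trajectory",
    "TrainResult",
    "init_weights",
    "draw_increment",
    "mutate_pair",
    "select_step",
    "evolve",
    "train_ensemble",
    "trajectory_divergence",
    "derive_seeds",
]

#: Weight-lattice spacing; all initial weights and mutation increments are
#: integer multiples of this, making mirrored mutation exact (see module doc).
QUANTUM = 2.0**-30


@dataclass(frozen=True)
class TrainConfig:
    """Parameters of one evolutionary training run.

    Parameters
    ----------
    mutation_scale
        Half-width of the uniform increment distribution per synapse per
        generation (dimensionless weight units).
    init_scale
        Half-width of the uniform distribution of initial weights
        ("modulo close to zero").
    epsilon
        Goal-function level that must be reached in addition to zero
        recognition errors; ``None`` means the loose per-tick bound
        ``(1 - threshold)**2 * n_ticks`` evaluated on the fragment at hand
        (``0.25`` per tick with the default threshold: the squared
        classification margin, summed over ticks).  The level is
        deliberately non-binding at zero errors — the error count is the
        hard criterion; the bound only rejects traces that classify
        correctly while straying far from the 0/1 targets.
    regenerate_stream
        Draw a fresh stream fragment every generation (the default,
        mirroring a non-reproducible environment); if False a single
        fragment is reused, which makes the goal sequence monotone.
    mutation_seed, stream_seed
        Independent seeds for the mutation and environment randomness, so
        the two divergence sources can be isolated.
    snapshot_stride
        Record a full weight snapshot every this many generations
        (0 disables snapshots; generation 0 is always included when on).
    """

    mutation_scale: float = 0.05
    stream_cfg: StreamConfig = field(default_factory=StreamConfig)
    epsilon: float | None = None
    max_generations: int = 50_000
    init_scale: float = 0.01
    regenerate_stream: bool = True
    threshold: float = DEFAULT_THRESHOLD
    mutation_seed: int | None = None
    stream_seed: int | None = None
    snapshot_stride: int = 0

    def __post_init__(self) -> None:
        if self.mutation_scale <= 0:
            raise ValueError("mutation_scale must be positive")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    def epsilon_for(self, n_ticks: int) -> float:
        if self.epsilon is not None:
            return self.epsilon
        return (1.0 - self.threshold) ** 2 * n_ticks


@dataclass
class Trajectory:
    """Per-generation record of an evolutionary run.

    ``goals[k]`` and ``errors[k]`` belong to generation ``k + 1`` (the
    survivor after the k-th selection).  ``snapshots`` maps generation
    number to a flattened weight vector; generation 0 is the start.
    """

    goals: np.ndarray
    errors: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    snapshot_stride: int = 0

    @property
    def generations(self) -> np.ndarray:
        return np.arange(1, len(self.goals) + 1)


@dataclass
class TrainResult:
    """Outcome of :func:`evolve`: the surviving structure and its history."""

    final_weights: WeightMatrix
    generations_used: int
    success: bool
    trajectory: Trajectory
    mutation_seed: int | None = None
    stream_seed: int | None = None
    validation_errors: int | None = None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _lattice_uniform(rng: np.random.Generator, scale: float, shape) -> np.ndarray:
    """I.i.d. uniform draws on [-scale, scale] snapped to the weight lattice."""
    m = int(round(scale / QUANTUM))
    return rng.integers(-m, m + 1, size=shape).astype(np.float64) * QUANTUM


def init_weights(
    config: NetworkConfig, init_scale: float, rng: np.random.Generator
) -> WeightMatrix:
    """Random initial structure: entries i.i.d. uniform on [-init_scale, init_scale]."""
    if init_scale < 0:
        raise ValueError("init_scale must be >= 0")
    n = config.n_total
    if init_scale == 0:
        return WeightMatrix(np.zeros((n, n)))
    return WeightMatrix(_lattice_uniform(rng, init_scale, (n, n)))


def draw_increment(
    w: WeightMatrix, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """One mutation increment matrix: uniform on [-scale, scale], zero on frozen entries.

    The full matrix is always drawn (then masked), so the random stream
    consumed does not depend on the frozen pattern.
    """
    delta = _lattice_uniform(rng, scale, w.x.shape)
    delta[w.frozen] = 0.0
    return delta


def mutate_pair(
    w: WeightMatrix,
    scale: float,
    rng: np.random.Generator,
    delta: np.ndarray | None = None,
) -> tuple[WeightMatrix, WeightMatrix]:
    """The mirrored pair (w + delta, w - delta) from one increment draw.

    Both offspring receive the same-modulus increments with opposite
    signs; ``(w_plus + w_minus) / 2 == w`` exactly, and frozen entries
    remain exactly zero in both.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if delta is None:
        delta = draw_increment(w, scale, rng)
    return (
        WeightMatrix(w.x + delta, w.frozen.copy()),
        WeightMatrix(w.x - delta, w.frozen.copy()),
    )


def _select_on_stream(
    parent: WeightMatrix,
    stream: EventStream,
    config: NetworkConfig,
    cfg: TrainConfig,
    mut_rng: np.random.Generator,
    delta: np.ndarray | None = None,
) -> tuple[WeightMatrix, float, int]:
    """One selection step on a given fragment; returns survivor, goal, errors.

    Ties are broken in favour of the parent, then the "+" offspring.
    """
    plus, minus = mutate_pair(parent, cfg.mutation_scale, mut_rng, delta=delta)
    gp, ep = evaluate(parent, stream, config, cfg.threshold)
    g_plus, e_plus = evaluate(plus, stream, config, cfg.threshold)
    g_minus, e_minus = evaluate(minus, stream, config, cfg.threshold)
    if gp <= g_plus and gp <= g_minus:
        return parent, gp, ep
    if g_plus <= g_minus:
        return plus, g_plus, e_plus
    return minus, g_minus, e_minus


def select_step(
    parent: WeightMatrix,
    task: TaskSpec,
    cfg: TrainConfig,
    config: NetworkConfig,
    mut_rng: np.random.Generator,
    stream_rng: np.random.Generator,
    delta: np.ndarray | None = None,
) -> tuple[WeightMatrix, float]:
    """Generate one common stream fragment and keep the fittest of the three."""
    stream = generate_stream(task, cfg.stream_cfg, rng=stream_rng, annotate=False)
    survivor, goal, _ = _select_on_stream(parent, stream, config, cfg, mut_rng, delta)
    return survivor, goal


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def evolve(
    config: NetworkConfig,
    task: TaskSpec,
    cfg: TrainConfig,
    start: WeightMatrix | None = None,
    stop_on_success: bool = True,
) -> TrainResult:
    """Iterate mirrored selection until trained or the generation budget is spent.

    Success requires zero recognition errors and goal <= epsilon on the
    current training fragment, then zero errors on a freshly generated
    validation stream of the same length.  Non-convergence returns
    ``success=False``, never raises.  ``start`` (with its frozen mask) is
    respected throughout; by default a fresh random initialisation is drawn.
    """
    mut_rng = np.random.default_rng(cfg.mutation_seed)
    stream_rng = np.random.default_rng(cfg.stream_seed)
    w = start.copy() if start is not None else init_weights(config, cfg.init_scale, mut_rng)
    if w.n != config.n_total:
        raise ValueError("start weights do not match the configuration")

    goals = np.empty(cfg.max_generations)
    errors = np.empty(cfg.max_generations, dtype=np.int64)
    snapshots: dict[int, np.ndarray] = {}
    stride = cfg.snapshot_stride
    if stride:
        snapshots[0] = w.flat()

    stream = generate_stream(task, cfg.stream_cfg, rng=stream_rng, annotate=False)
    success = False
    validation_errors: int | None = None
    gen = 0
    for gen in range(1, cfg.max_generations + 1):
        if cfg.regenerate_stream and gen > 1:
            stream = generate_stream(task, cfg.stream_cfg, rng=stream_rng, annotate=False)
        w, g, e = _select_on_stream(w, stream, config, cfg, mut_rng)
        goals[gen - 1] = g
        errors[gen - 1] = e
        if stride and gen % stride == 0:
            snapshots[gen] = w.flat()
        if stop_on_success and e == 0 and g <= cfg.epsilon_for(len(stream)):
            vstream = generate_stream(task, cfg.stream_cfg, rng=stream_rng, annotate=False)
            _, validation_errors = evaluate(w, vstream, config, cfg.threshold)
            if validation_errors == 0:
                success = True
                break
    if stride and gen not in snapshots:
        snapshots[gen] = w.flat()

    trajectory = Trajectory(goals[:gen].copy(), errors[:gen].copy(), snapshots, stride)
    return TrainResult(
        final_weights=w,
        generations_used=gen,
        success=success,
        trajectory=trajectory,
        mutation_seed=cfg.mutation_seed,
        stream_seed=cfg.stream_seed,
        validation_errors=validation_errors,
    )


def derive_seeds(base_seed: int, index: int, n: int = 2) -> list[int]:
    """Deterministic child seeds for run ``index`` of an experiment.

    Uses ``SeedSequence([base_seed, index])`` so every (experiment seed,
    run index) pair maps to an independent, reproducible random stream;
    values are reduced below 2**31.
    """
    state = np.random.SeedSequence([int(base_seed), int(index)]).generate_state(n)
    return [int(s % (2**31)) for s in state]


def train_ensemble(
    n: int,
    config: NetworkConfig,
    task: TaskSpec,
    cfg: TrainConfig,
    base_seed: int = 0,
) -> list[TrainResult]:
    """``n`` independent training runs from distinct random initialisations.

    Run ``i`` uses mutation and stream seeds derived from
    ``(base_seed, i)``; the seeds are recorded on each result.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    results = []
    for i in range(n):
        mseed, sseed = derive_seeds(base_seed, i)
        results.append(
            evolve(config, task, replace(cfg, mutation_seed=mseed, stream_seed=sseed))
        )
    return results


def trajectory_divergence(
    start: WeightMatrix,
    config: NetworkConfig,
    task: TaskSpec,
    cfg: TrainConfig,
    n_replicates: int,
    base_seed: int = 0,
    identical_seeds: bool = False,
) -> pd.DataFrame:
    """Divergence of replicate evolutionary trajectories from one shared start.

    Runs ``n_replicates`` full-length trainings from the same initial
    structure with distinct mutation and stream seeds (or identical ones,
    as a determinism control) and returns all pairwise Euclidean distances
    between replicate weight vectors at every snapshot generation, as a
    tidy frame with columns ``generation, rep_i, rep_j, distance``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    stride = cfg.snapshot_stride or max(1, cfg.max_generations // 50)
    results = []
    for i in range(n_replicates):
        mseed, sseed = derive_seeds(base_seed, 0 if identical_seeds else i)
        run_cfg = replace(
            cfg, mutation_seed=mseed, stream_seed=sseed, snapshot_stride=stride
        )
        results.append(
            evolve(config, task, run_cfg, start=start, stop_on_success=False)
        )
    common = sorted(
        set.intersection(*(set(r.trajectory.snapshots) for r in results))
    )
    rows = []
    for g in common:
        vecs = [r.trajectory.snapshots[g] for r in results]
        for i in range(n_replicates):
            for j in range(i + 1, n_replicates):
                d = float(np.linalg.norm(vecs[i] - vecs[j]))
                rows.append((g, i, j, d))
    return pd.DataFrame(rows, columns=["generation", "rep_i", "rep_j", "distance"])
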