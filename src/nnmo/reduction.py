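"""Complexity reduction: magnitude pruning with evolutionary retraining.

The functional complexity of a task is estimated by whittling a trained
structure down to its minimal working form: repeatedly freeze the
smallest-magnitude free synapse to exactly zero, then retrain the
remaining free synapses with the same evolutionary algorithm until the
network again makes zero recognition errors.  The loop stops at the first
synapse whose removal cannot be retrained away; the non-zero count of the
last successful structure is the functional-complexity estimate, while
the total synapse count of the configuration (n^2) is the potential
complexity.  The gap between the two is the redundancy that makes the
structure evolvable in the first place.

Also here: compaction of reduced networks into smaller configurations
(dropping hidden neurons whose row and column are entirely zero), the
randomized-synapse negative control (keeping the reduced wiring diagram
but replacing surviving values with random numbers, after which training
fails), and the minimal-network-size search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .event_stream import TaskSpec
from .evolution import TrainConfig, derive_seeds, evolve
from .net_core import NetworkConfig, WeightMatrix

__all__ = [
    "ReductionStage",
    "ReductionHistory",
    "ComplexityReport",
    "RandomizeControlReport",
    "SizeSearchReport",
    "prune_smallest",
    "reduce",
    "compact",
    "randomize_control",
    "min_network_search",
]


@dataclass(frozen=True)
class ReductionStage:
    """One pruning stage: which synapse was frozen and how retraining went."""

    removed_index: int  # 0-based row-major flat index
    retrain_success: bool
    generations_used: int
    nonzero_after: int


@dataclass
class ReductionHistory:
    stages: list[ReductionStage]

    @property
    def n_successful(self) -> int:
        return sum(s.retrain_success for s in self.stages)


@dataclass(frozen=True)
class ComplexityReport:
    """Functional vs potential complexity of one reduced structure."""

    functional_complexity: int
    potential_complexity: int

    @property
    def redundancy(self) -> int:
        return self.potential_complexity - self.functional_complexity


def prune_smallest(w: WeightMatrix) -> tuple[WeightMatrix, int]:
    """Freeze the free synapse of smallest non-zero modulus to exactly zero.

    Ties are broken by the lowest row-major flat index.  Returns the new
    matrix and the flat index of the removed synapse.
    """
    mag = np.abs(w.x.ravel())
    mag[w.frozen.ravel()] = np.inf
    mag[mag == 0.0] = np.inf
    idx = int(np.argmin(mag))  # argmin takes the first (lowest flat index) on ties
    if not np.isfinite(mag[idx]):
        raise ValueError("no non-frozen, non-zero synapse left to prune")
    out = w.copy()
    out.x.ravel()[idx] = 0.0
    out.frozen.ravel()[idx] = True
    return out, idx


def reduce(
    w: WeightMatrix,
    config: NetworkConfig,
    task: TaskSpec,
    train_cfg: TrainConfig,
    retrain_budget: int | None = None,
    restarts: int = 5,
    base_seed: int = 0,
) -> tuple[WeightMatrix, ReductionHistory, ComplexityReport]:
    """Iterate prune-smallest-then-retrain until retraining fails.

    Each stage makes up to ``restarts`` retraining attempts of
    ``retrain_budget`` generations (default: twice the training budget),
    each from the pruned structure with fresh mutation/stream seeds
    derived from ``base_seed``; streams are regenerated per attempt.  The
    first stage on which every attempt fails ends the loop; the last
    successful structure is returned together with the stage history and
    the complexity report.
    """
    if retrain_budget is None:
        retrain_budget = 2 * train_cfg.max_generations
    current = w.copy()
    stages: list[ReductionStage] = []
    attempt = 0
    while True:
        try:
            pruned, idx = prune_smallest(current)
        except ValueError:
            break
        success = None
        for _ in range(restarts):
            mseed, sseed = derive_seeds(base_seed, attempt)
            attempt += 1
            cfg = replace(
                train_cfg,
                max_generations=retrain_budget,
                mutation_seed=mseed,
                stream_seed=sseed,
            )
            result = evolve(config, task, cfg, start=pruned)
            if result.success:
                success = result
                break
        if success is None:
            stages.append(ReductionStage(idx, False, restarts * retrain_budget, pruned.n_nonzero()))
            break
        stages.append(
            ReductionStage(idx, True, success.generations_used, success.final_weights.n_nonzero())
        )
        current = success.final_weights
    report = ComplexityReport(current.n_nonzero(), config.n_synapses)
    return current, ReductionHistory(stages), report


def compact(w: WeightMatrix, config: NetworkConfig) -> tuple[WeightMatrix, NetworkConfig]:
    """Drop hidden neurons whose synapse row *and* column are entirely zero.

    Removing such a neuron cannot change any other neuron's weighted sum,
    so the compacted network's output trace on any stream equals the
    original's exactly.  Input and output neurons are never removed; their
    relative order is preserved in the re-indexed configuration.
    """
    dead = [
        i
        for i in config.hidden_ids
        if not np.any(w.x[i, :]) and not np.any(w.x[:, i])
    ]
    if not dead:
        return w.copy(), config
    keep = [i for i in range(config.n_total) if i not in dead]
    remap = {old: new for new, old in enumerate(keep)}
    new_cfg = NetworkConfig(
        n_total=len(keep),
        input_ids=(remap[config.input_ids[0]], remap[config.input_ids[1]]),
        output_ids=(remap[config.output_ids[0]], remap[config.output_ids[1]]),
        steepness_a=config.steepness_a,
    )
    sel = np.ix_(keep, keep)
    return WeightMatrix(w.x[sel].copy(), w.frozen[sel].copy()), new_cfg


@dataclass
class RandomizeControlReport:
    """Outcome of the randomized-synapse negative control."""

    n_attempts: int
    n_successes: int
    final_goals: list[float]
    generations_used: list[int]

    @property
    def success_rate(self) -> float:
        return self.n_successes / self.n_attempts if self.n_attempts else 0.0


def randomize_control(
    w_reduced: WeightMatrix,
    config: NetworkConfig,
    task: TaskSpec,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
    preserve_sign: bool = True,
    n_attempts: int = 10,
    noise: float = 1.0,
) -> RandomizeControlReport:
    """Replace surviving synapse values with random numbers and try to train.

    The wiring diagram (the frozen mask) of the reduced structure is kept;
    each surviving synapse is redrawn with magnitude uniform on the
    [min, max] modulus range of the surviving weights (the sign is kept
    when ``preserve_sign``, otherwise random).  ``noise=0`` is the control
    of the control: values are left unchanged, so training succeeds
    trivially.  Evolutionary training is then run from each randomized
    structure under the frozen mask; with an informative structure-vs-
    values separation the expected success count is ~0.
    """
    live = (~w_reduced.frozen) & (w_reduced.x != 0)
    mags = np.abs(w_reduced.x[live])
    lo, hi = float(mags.min()), float(mags.max())
    goals, gens = [], []
    n_success = 0
    for _ in range(n_attempts):
        x = w_reduced.x.copy()
        if noise > 0:
            new_mag = rng.uniform(lo, hi, size=int(live.sum()))
            sign = np.sign(w_reduced.x[live]) if preserve_sign else rng.choice([-1.0, 1.0], size=new_mag.size)
            x[live] = sign * new_mag
        mseed, sseed = [int(s) for s in rng.integers(0, 2**31, size=2)]
        cfg = replace(train_cfg, mutation_seed=mseed, stream_seed=sseed)
        result = evolve(config, task, cfg, start=WeightMatrix(x, w_reduced.frozen.copy()))
        n_success += result.success
        goals.append(float(result.trajectory.goals[-1]))
        gens.append(result.generations_used)
    return RandomizeControlReport(n_attempts, n_success, goals, gens)


@dataclass
class SizeSearchReport:
    """Per-size training success counts and the smallest size that worked."""

    sizes: list[int]
    successes: dict[int, int]
    restarts: int
    min_successful_size: int | None


def min_network_search(
    task: TaskSpec,
    sizes: list[int],
    train_cfg: TrainConfig,
    restarts: int = 10,
    base_seed: int = 0,
    steepness_a: float = 1.0,
) -> SizeSearchReport:
    """Smallest network size trainable to error-free performance.

    For each total neuron count (2 input + 2 output + the rest hidden)
    runs ``restarts`` independent trainings under the same budget and
    counts successes; reports the smallest size with at least one.
    """
    if any(s < 4 for s in sizes):
        raise ValueError("sizes must be >= 4 (2 input + 2 output neurons)")
    successes: dict[int, int] = {}
    for size in sorted(sizes):
        config = NetworkConfig(size, steepness_a=steepness_a)
        count = 0
        for i in range(restarts):
            mseed, sseed = derive_seeds(base_seed, size * 10_000 + i)
            cfg = replace(train_cfg, mutation_seed=mseed, stream_seed=sseed)
            count += evolve(config, task, cfg).success
        successes[size] = count
    ok = [s for s in sorted(sizes) if successes[s] > 0]
    return SizeSearchReport(sorted(sizes), successes, restarts, ok[0] if ok else None)
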