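# nnmo — evolving neural network model objects

`nnmo` is a heuristic simulator of biological evolution for studying
whether evolutionary outcomes are reproducible or merely *equifinal* —
different structures, same function.  The evolving agents are small
fully connected recurrent neural networks ("neural network model
objects", NNMOs): the synapse matrix is the heritable structure, a
quasi-random stimulus stream is the environment, a summed-squared-error
goal function is (inverse) fitness, and a mirrored random search plays
mutation and selection.  The library is aimed at computational/
theoretical biologists who want a transparent, fully seeded testbed for
questions about fitness landscapes, neutral structure space, and
functional complexity.

## The model in brief

Dynamics (synchronous, discrete time, odd activation):

    alpha_i[k] = tanh( a * ( sum_j x[i][j] * alpha_j[k-1] + A_i[k] ) )

Two neurons receive the external two-bit signal, two are read out as the
response, and the remaining K are associative (hidden).  A task such as
**A3** demands the output (1,1) on the 3 ticks after stimulus A = (1,0)
and (0,0) otherwise; **C4** the same for C = (1,1) with a 4-tick window.

Evolution is a (1+2) strategy with mirrored sampling: one random
increment matrix Δ per generation, offspring w+Δ and w−Δ, survival of
the smallest goal value on a fresh 100-symbol stream fragment, repeated
until the survivor makes zero recognition errors (plus a validation
stream).  Three analyses are built on top:

* **Functional symmetry** — permuting hidden neurons and flipping the
  signs of all their synapses leaves the network function exactly
  invariant (the activation is odd), so independently evolved structures
  fall into `N = 2^K · K!` clusters in the `n²`-dimensional structure
  space (doubled to `2^{K+1} · K!` for C-tasks, which are symmetric
  under swapping the input lines).
* **Trajectory divergence** — replicate runs from one start with
  different mutation/stream randomness, with pairwise distances per
  generation.
* **Complexity reduction** — repeatedly zero the smallest-modulus
  synapse and retrain; the final non-zero count estimates the task's
  *functional complexity*, against the configuration's *potential
  complexity* (all n² synapses); the excess is the redundancy that makes
  the structure evolvable.

## Worked example

```python
from nnmo import (NetworkConfig, TaskSpec, TrainConfig, evolve, reduce,
                  predicted_cluster_count, enumerate_group)

config = NetworkConfig(6)                     # 2 input + 2 output + 2 hidden
task = TaskSpec.from_name("A3")               # respond (1,1) for 3 ticks after A
cfg = TrainConfig(mutation_seed=7, stream_seed=11, max_generations=50_000)

result = evolve(config, task, cfg)
print(f"trained: {result.success} after {result.generations_used} generations, "
      f"final goal {result.trajectory.goals[-1]:.1f}")

reduced, history, report = reduce(result.final_weights, config, task, cfg,
                                  retrain_budget=10_000, restarts=5, base_seed=3)
print(f"functional complexity: {report.functional_complexity} of "
      f"{report.potential_complexity} synapses "
      f"(redundancy {report.redundancy})")

k = len(config.hidden_ids)
print(f"predicted structural clusters: {predicted_cluster_count(k)} "
      f"(= size of the enumerated symmetry group: {len(enumerate_group(k))})")
```

prints

```
trained: True after 413 generations, final goal 79.3
functional complexity: 7 of 36 synapses (redundancy 29)
predicted structural clusters: 8 (= size of the enumerated symmetry group: 8)
```

The 6-neuron network learned error-free A3 recognition in 413
generations; pruning-with-retraining kept it working with 7 of its 36
synapses (reduction outcomes are stochastic — across replicates most
runs end between 8 and 17); and its two hidden neurons give an
8-element symmetry group, i.e. up to 8 structural clusters of
functionally identical solutions.

## Command line

```
nnmo ensemble --task A3 --n 20 --seed 1 --out runs/ens-a3
nnmo diverge  --task A3 --replicates 5 --seed 2 --out runs/div-a3
nnmo reduce   --task C4 --n 10 --seed 3 --out runs/red-c4
nnmo min-size --task A3 --sizes 5,6 --seed 4 --out runs/minsize
nnmo symmetry-analyze runs/ens-a3/weights_*.txt --out runs/sym-a3
```

Each command writes CSV tables (pairwise distances, cluster labels, 3-D
projection coordinates, divergence or reduction summaries) plus a
`manifest.json` recording config and seeds for bit-exact reruns.  A YAML
config can replace the flags (`--config experiment.yaml`).

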