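# Methods

`nnmo` is a heuristic model of biological evolution built from recurrent
neural networks.  A *neural network model object* (NNMO) is one evolved
network instance: its synapse matrix is the heritable structure, the
stimulus stream is the environment, the goal function is (inverse)
fitness, and a mirrored random search plays the role of mutation and
selection.  The package exists to make three kinds of statements
quantitative and repeatable: (i) the functional symmetry of weight space
— how many distinct structural clusters can implement one function;
(ii) the reproducibility of evolutionary trajectories from a shared
start; and (iii) the functional complexity of a task — the minimal
number of synapses that still supports error-free performance, versus
the potential complexity (all synapses) whose excess is the redundancy
that makes evolution possible at all.

## Network model

A fully connected recurrent network of `n` formal neurons, including
self-connections.  Two neurons receive the external two-bit signal, two
are read out as the response, and the remaining `K = n - 4` are
associative (hidden).  The synchronous update is

    alpha_i[k] = tanh( a * ( sum_j x[i][j] * alpha_j[k-1] + A_i[k] ) )

with `x[i][j]` the synapse from neuron `j` to neuron `i`, `A_i[k]` the
external input (non-zero only on the two input neurons), and `a > 0` the
activation steepness (default 1.0).  The activation must be odd: oddness
is what makes per-hidden-neuron sign flips exact symmetries of the
network function, and hence what produces the `2^K * K!` cluster count.
The initial state is all zeros.  Output activations live in (-1, 1);
targets are encoded 0/1 and an output counts as "on" above the
classification threshold 0.5.

## Environment and tasks

The environment is a discrete stream over four symbols: pause = (0,0),
A = (1,0), B = (0,1), C = (1,1).  A task names the correct stimulus and
a processing window: `A3` requires the response (1,1) on exactly the 3
ticks following an occurrence of A, and (0,0) on every other tick; `C4`
the same with stimulus C and a 4-tick window.  C-tasks are symmetric
under swapping the two input lines (the correct code (1,1) drives both
inputs identically), which doubles the symmetry group.

Streams hold 100 single-tick stimuli drawn uniformly from {A, B, C},
separated by pauses drawn uniformly from [1, 4] ticks; a drawn pause is
extended to the window length when shorter, so a response window always
closes before the next stimulus arrives.  These are declared modelling
conventions: the per-tick response timing of the original task family is
not recoverable, and the quantitative minima below are sensitive to it
(see *Limitations*).

The goal (loss) function of a network on a fragment is the sum over
ticks and over the two output neurons of the squared difference between
output activation and required response.  Recognition errors are counted
per tick: a tick is erroneous if either thresholded output disagrees
with its target.

## Evolutionary algorithm

A (1+2) evolution strategy with mirrored sampling.  Per generation:

1. draw one increment matrix with entries i.i.d. uniform on
   [-mutation_scale, +mutation_scale] (default scale 0.05) and form the
   two offspring `w + delta` and `w - delta` (same-modulus increments,
   opposite signs); pruned (frozen) synapses receive no increment;
2. evaluate parent and both offspring on one freshly generated
   100-symbol fragment (a new fragment every generation by default — the
   environment does not repeat);
3. keep the network with the smallest goal value (ties resolved to the
   parent, then the "+" offspring).

Initial weights are i.i.d. uniform on [-0.01, 0.01].  Training succeeds
when the survivor makes zero recognition errors on its training
fragment, its goal value is below `(1 - threshold)^2 * n_ticks`
(~0.25 per tick — deliberately non-binding at zero errors; the error
count is the hard criterion), and it then makes zero errors on an
independently generated validation stream of the same length.  With the
default budget of 50,000 generations, 6-neuron networks train on A3 in
roughly 0.2–6 k generations (median ~1 k) and on C4 in roughly 3–30 k;
a small fraction of runs stall and are counted as failures.

Numerical choice: initial weights and increments are snapped to a
lattice of multiples of 2^-30 (~1e-9, far below every model scale), so
that `w ± delta` is exact in double precision.  This makes the mirror
identity `(w+ + w-)/2 = w` hold bit for bit and runs exactly
reproducible from their two seeds (mutation and environment randomness
are separate streams so the two divergence sources can be isolated).

## Functional symmetry and ensemble geometry

For K hidden neurons the invariant transforms are all compositions of a
hidden-neuron permutation with per-hidden-neuron sign flips of incoming
and outgoing synapses — a group of `2^K * K!` elements, doubled by the
input swap for C-tasks.  `apply_transform` realises an element as
`S P x P^T S`; output neurons are never moved or flipped.  Sign-flip
invariance is exact to the last bit (the flips cancel through the odd
activation without reordering any floating-point sum); permutations
reorder sums, so traces agree to rounding (tested at 1e-9).

Ensembles are compared as points in the `n^2`-dimensional structure
space under Euclidean distance.  `canonicalize` labels orbits by the
lexicographically minimal matrix over the enumerated group (exhaustive;
practical for K <= 3).  Cluster counting uses single-linkage
agglomeration cut at the largest ratio between consecutive merge
heights (minimum ratio 3 by default, below which the ensemble counts as
one cluster): orbit clusters are compact and far apart, which is
exactly the regime where the largest-gap cut is unambiguous.  The
distance-histogram modality check (fixed-width moving-average smoothing,
count of local maxima) mirrors the visual bi-/polymodality criterion
for cluster structure.

## Complexity reduction

Starting from a trained structure: freeze the smallest-modulus free
synapse to exactly zero (ties to the lowest row-major flat index), then
retrain the remaining free synapses with the same algorithm; repeat
until a stage's retraining fails in all of 5 restart attempts of 10,000
generations each (streams regenerated per attempt).  One synapse is
removed per stage, so the non-zero count falls by exactly one per
successful stage; the count of the last successful structure is the
functional-complexity estimate.  Retraining restarts and budget are
protocol choices (the retrain budget was checked for saturation:
doubling it does not deepen the result).  `compact` afterwards deletes
hidden neurons whose synapse row and column are entirely zero — this
provably cannot change any weighted sum, and trace equality is asserted.

The randomized-synapse control keeps the reduced wiring (the frozen
mask) but replaces each surviving value with a fresh draw of magnitude
uniform on the [min, max] modulus range of the survivors (sign kept by
default), then attempts training under the mask.  `noise=0` degenerates
to restarting from the solved values and must succeed — the control of
the control.

## Standard protocol sizes

Used by the acceptance recomputation (`scripts/acceptance.py`) and the
acceptance test suite, and chosen as the package's standard experiment
sizes: training budget 50,000 generations; 10 replicate reductions per
task (training additional seeds until 10 trained networks exist);
5 restarts x 10,000 generations per reduction stage; size scan over
{5, 6} with 10 restarts each; divergence over 5 replicates of 2,000
generations with snapshots every 100.

## What the generator does and does not emulate

The synthetic environment reproduces the *structure* of the modelled
world: a quasi-random symbol stream with random pause lengths, uniform
stimulus marginals, and a deterministic required-response rule.  It does
not emulate graded stimulus intensities, noise on the input lines,
correlated symbol sequences, or any physical time scale; and the exact
per-tick placement of the required response within the processing
window is a declared convention, not a recovered fact.  Tests passing
under this generator therefore demonstrate properties of the model
class — exact symmetry, equifinality, redundancy-dependent
evolvability — not of any particular biological system.

## Design choices where the design was open

* **Activation:** `tanh(a*rho)` — the canonical odd sigmoid; any odd,
  strictly increasing, bounded activation preserves every symmetry
  result.
* **Response placement:** the window opens one tick after stimulus
  onset, the earliest tick at which the input can causally reach an
  output neuron (input -> input-neuron activation -> output summation).
* **Non-overlap rule:** pauses are extended so response windows close
  before the next stimulus.  The alternative (windows running into
  subsequent stimuli) was examined and makes the tasks dramatically
  harder — see Limitations.
* **Increment distribution:** uniform; no adaptive step-size control
  (none is part of the modelled algorithm).
* **Cluster cut:** single linkage with a largest-gap criterion rather
  than a parametric mixture: orbit clusters have no model family, and
  the gap statistic needs no cluster-count prior.

## Limitations

* The quantitative minima (smallest trainable network, minimal synapse
  counts) are properties of the *task conventions*, not only of the
  algorithm.  Under the conventions above, A3 is learnable by 5-neuron
  (one-hidden) networks, and best-of-ensemble reductions reach ~8–10
  synapses for A3 and ~11–14 for C4; under a harsher reading in which response windows
  overlap subsequent stimuli, 5-neuron networks reliably fail on A3 and
  the minima rise by ~50%, while C4 training slows by two orders of
  magnitude.  The relative statements — C4 needs more synapses than A3,
  minima independent of the starting network size, redundancy required
  for evolvability — are stable across conventions; the absolute counts
  are not.
* The randomized-synapse control is convention-sensitive for the same
  reason: where the reduced task remains easy, a reduced wiring diagram
  with random values can still be trained.
* Cluster counting assumes well-separated orbit clusters; ensembles
  trained with large mutation scales or stopped early produce diffuse
  clouds where the largest-gap cut degrades to a single cluster.
* The trainer is the modelled (1+2) mirrored random search by
  construction; it is not intended to be an efficient optimiser, and no
  gradient information is used anywhere.
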