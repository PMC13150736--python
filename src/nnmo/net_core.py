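"""Discrete-time dynamics of fully connected recurrent networks in an event stream.

The model object is a fully connected recurrent network of ``n`` formal
neurons (self-connections included).  Two neurons receive the external
two-bit signal, two neurons are read out as the response, and the rest are
associative (hidden).  At every tick the whole state is updated
synchronously from the previous state:

    alpha_i[k] = f( sum_j x[i][j] * alpha_j[k-1] + A_i[k] )

where ``x[i][j]`` is the synapse from neuron ``j`` to neuron ``i``,
``A_i[k]`` is the external input (non-zero only on input neurons) and
``f(rho) = tanh(a * rho)`` is an odd sigmoid with steepness ``a``.  The odd
activation is essential: it is what makes per-neuron sign flips a
functional symmetry of the weight space (see :mod:`nnmo.symmetry`).

Fitness of a network on a stream fragment is the goal (loss) function: the
sum over ticks and over the two output neurons of the squared difference
between the output activation and the required response.  Recognition
errors are counted per tick by thresholding the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "NetworkConfig",
    "WeightMatrix",
    "NetworkState",
    "OutputTrace",
    "activation",
    "step",
    "run_stream",
    "goal_function",
    "recognition_errors",
    "evaluate",
    "DEFAULT_THRESHOLD",
]

#: Classification threshold on output activations: an output counts as
#: "on" when its activation exceeds this value.  Targets are encoded 0/1.
DEFAULT_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Neuron count and role assignment of a network.

    Indices are 0-based internally.  The default layout puts the two input
    neurons first, then the two output neurons, then the associative
    (hidden) neurons; ``flat`` synapse numbering used for reporting and 3-D
    projections is row-major and 1-based (synapse 1 = x[0][0]).

    Parameters
    ----------
    n_total
        Total neuron count (>= 4: two inputs and two outputs are always
        present).
    input_ids, output_ids
        Ordered index pairs of the neurons receiving the external signal
        and of the neurons read as the response.
    steepness_a
        Positive steepness coefficient of the activation ``tanh(a * rho)``.
    """

    n_total: int
    input_ids: tuple[int, int] = (0, 1)
    output_ids: tuple[int, int] = (2, 3)
    steepness_a: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total < 4:
            raise ValueError("n_total must be >= 4 (2 input + 2 output neurons)")
        if self.steepness_a <= 0:
            raise ValueError("steepness_a must be positive")
        ids = (*self.input_ids, *self.output_ids)
        if len(set(ids)) != 4 or not all(0 <= i < self.n_total for i in ids):
            raise ValueError("input/output ids must be 4 distinct indices in range")

    @property
    def hidden_ids(self) -> tuple[int, ...]:
        """Associative neuron indices (all neurons that are neither input nor output)."""
        taken = set(self.input_ids) | set(self.output_ids)
        return tuple(i for i in range(self.n_total) if i not in taken)

    @property
    def n_hidden(self) -> int:
        return self.n_total - 4

    @property
    def n_synapses(self) -> int:
        """Total synapse count (the dimension of structure space)."""
        return self.n_total * self.n_total


@dataclass
class WeightMatrix:
    """An ``n x n`` synapse matrix with a frozen-zero mask.

    ``x[i, j]`` is the synapse from neuron ``j`` to neuron ``i``.  Entries
    with ``frozen[i, j]`` set are pinned to exactly zero: mutation and
    retraining never touch them.  The frozen mask is how complexity
    reduction removes synapses permanently.
    """

    x: np.ndarray
    frozen: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 2 or self.x.shape[0] != self.x.shape[1]:
            raise ValueError("weight matrix must be square")
        if self.frozen is None:
            self.frozen = np.zeros(self.x.shape, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
            if self.frozen.shape != self.x.shape:
                raise ValueError("frozen mask shape must match weight matrix")
        if np.any(self.x[self.frozen] != 0.0):
            raise ValueError("frozen synapses must be exactly zero")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.x.copy(), self.frozen.copy())

    def flat(self) -> np.ndarray:
        """Row-major flattened weight vector (the point in structure space)."""
        return self.x.ravel().copy()

    def n_nonzero(self) -> int:
        """Number of non-zero synapses (the current functional complexity)."""
        return int(np.count_nonzero(self.x))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        return bool(
            np.array_equal(self.x, other.x) and np.array_equal(self.frozen, other.frozen)
        )


@dataclass
class NetworkState:
    """Activation vector ``alpha`` of all neurons at one tick; all in (-1, 1)."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls(np.zeros(n))


@dataclass
class OutputTrace:
    """Per-tick activations of the two output neurons over a stream run."""

    outputs: np.ndarray  # shape (T, 2)

    def __post_init__(self) -> None:
        self.outputs = np.asarray(self.outputs, dtype=np.float64)

    def __len__(self) -> int:
        return self.outputs.shape[0]


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def activation(rho: float, steepness_a: float = 1.0):
    """Odd activation ``f(rho) = tanh(a * rho)``; strictly increasing, range (-1, 1)."""
    if steepness_a <= 0:
        raise ValueError("steepness_a must be positive")
    return np.tanh(steepness_a * np.asarray(rho, dtype=np.float64))


def step(
    weights: WeightMatrix,
    state: NetworkState,
    external: tuple[float, float] | np.ndarray,
    config: NetworkConfig,
) -> NetworkState:
    """One synchronous update: all weighted sums use the previous state."""
    if weights.n != config.n_total or state.alpha.shape[0] != config.n_total:
        raise ValueError("weights/state dimensions do not match the configuration")
    rho = weights.x @ state.alpha
    rho[config.input_ids[0]] += external[0]
    rho[config.input_ids[1]] += external[1]
    return NetworkState(np.tanh(config.steepness_a * rho))


@njit(cache=True)
def _simulate_outputs(x, a, inputs, out0, out1, in0, in1):  # pragma: no cover - jitted
    n = x.shape[0]
    T = inputs.shape[0]
    alpha = np.zeros(n)
    new = np.zeros(n)
    out = np.empty((T, 2))
    for t in range(T):
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += x[i, j] * alpha[j]
            new[i] = s
        new[in0] += inputs[t, 0]
        new[in1] += inputs[t, 1]
        for i in range(n):
            alpha[i] = np.tanh(a * new[i])
        out[t, 0] = alpha[out0]
        out[t, 1] = alpha[out1]
    return out


@njit(cache=True)
def _simulate_goal(x, a, inputs, targets, out0, out1, in0, in1, threshold):  # pragma: no cover
    n = x.shape[0]
    T = inputs.shape[0]
    alpha = np.zeros(n)
    new = np.zeros(n)
    goal = 0.0
    errors = 0
    for t in range(T):
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += x[i, j] * alpha[j]
            new[i] = s
        new[in0] += inputs[t, 0]
        new[in1] += inputs[t, 1]
        for i in range(n):
            alpha[i] = np.tanh(a * new[i])
        d0 = alpha[out0] - targets[t, 0]
        d1 = alpha[out1] - targets[t, 1]
        goal += d0 * d0 + d1 * d1
        if ((alpha[out0] > threshold) != (targets[t, 0] > 0.5)) or (
            (alpha[out1] > threshold) != (targets[t, 1] > 0.5)
        ):
            errors += 1
    return goal, errors


def run_stream(
    weights: WeightMatrix,
    stream,
    config: NetworkConfig,
    initial: NetworkState | None = None,
) -> OutputTrace:
    """Drive the network through a stream from a given (default zero) state.

    Returns the per-tick activations of the two output neurons; the weight
    matrix is never mutated.  A non-zero initial state falls back to the
    pure-Python stepper; the default zero start uses the compiled kernel.
    """
    if weights.n != config.n_total:
        raise ValueError("weights do not match the configuration")
    inputs = stream.inputs
    if initial is None or not np.any(initial.alpha):
        out = _simulate_outputs(
            weights.x,
            config.steepness_a,
            np.asarray(inputs, dtype=np.float64),
            config.output_ids[0],
            config.output_ids[1],
            config.input_ids[0],
            config.input_ids[1],
        )
        return OutputTrace(out)
    state = initial
    out = np.empty((inputs.shape[0], 2))
    for t in range(inputs.shape[0]):
        state = step(weights, state, inputs[t], config)
        out[t, 0] = state.alpha[config.output_ids[0]]
        out[t, 1] = state.alpha[config.output_ids[1]]
    return OutputTrace(out)


def goal_function(trace: OutputTrace, stream) -> float:
    """Summed squared deviation between outputs and the required response.

    This is the evolutionary fitness surrogate: non-negative, zero only for
    a trace that matches the target exactly (unreachable with a saturating
    activation, so trained networks settle at a small positive value).
    """
    targets = np.asarray(stream.targets, dtype=np.float64)
    if trace.outputs.shape != targets.shape:
        raise ValueError("trace and target lengths differ")
    return float(np.sum((trace.outputs - targets) ** 2))


def recognition_errors(trace: OutputTrace, stream, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Number of ticks on which the thresholded outputs disagree with the target.

    A tick is erroneous when, for either output neuron, ``activation >
    threshold`` disagrees with ``target == 1``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    targets = np.asarray(stream.targets)
    if trace.outputs.shape != targets.shape:
        raise ValueError("trace and target lengths differ")
    wrong = (trace.outputs > threshold) != (targets == 1)
    return int(np.count_nonzero(wrong.any(axis=1)))


def evaluate(
    weights: WeightMatrix,
    stream,
    config: NetworkConfig,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, int]:
    """Goal value and recognition-error count in one compiled pass from a zero state."""
    goal, errors = _simulate_goal(
        weights.x,
        config.steepness_a,
        np.asarray(stream.inputs, dtype=np.float64),
        np.asarray(stream.targets, dtype=np.float64),
        config.output_ids[0],
        config.output_ids[1],
        config.input_ids[0],
        config.input_ids[1],
        threshold,
    )
    return float(goal), int(errors)
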