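"""Functional symmetry of the weight space and ensemble geometry.

Because the activation is odd, a trained network's input-output function
is exactly preserved under two kinds of discrete structure transforms:

* relabelling (permuting) the associative neurons, and
* flipping the sign of all incoming and outgoing synapses of any subset
  of associative neurons (the sign flip cancels through the odd
  activation: the neuron's activation trace negates, but every product
  ``x[i][j] * alpha[j]`` it feeds is unchanged).

With K associative neurons this gives a group of ``2**K * K!`` transforms
— the predicted number of structural clusters an ensemble of
independently evolved networks can occupy.  Tasks that are symmetric
under swapping the two input lines (the C tasks, whose correct stimulus
(1,1) drives both inputs identically) additionally admit the input-neuron
swap, doubling the count.

The module also provides the geometry side: pairwise Euclidean distances
between flattened weight matrices, orbit canonicalization, single-linkage
cluster counting with a largest-gap cut, 3-D coordinate projections, and
the distance-histogram modality check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .net_core import NetworkConfig, WeightMatrix

__all__ = [
    "InvariantTransform",
    "EnsembleGeometry",
    "ModalityReport",
    "apply_transform",
    "enumerate_group",
    "predicted_cluster_count",
    "canonicalize",
    "pairwise_distances",
    "cluster_count",
    "project3d",
    "distance_modality",
]


@dataclass(frozen=True)
class InvariantTransform:
    """One element of the functional-symmetry group.

    ``hidden_perm[k]`` is the position (within the ordered hidden-neuron
    list) whose neuron moves to hidden slot ``k``; ``hidden_signs[k]`` is
    the sign applied to the neuron now in slot ``k``.  ``input_swap``
    exchanges the two input neurons (a symmetry of the network function
    only for tasks with a symmetric stimulus code).
    """

    hidden_perm: tuple[int, ...]
    hidden_signs: tuple[int, ...]
    input_swap: bool = False

    def __post_init__(self) -> None:
        k = len(self.hidden_perm)
        if sorted(self.hidden_perm) != list(range(k)):
            raise ValueError("hidden_perm must be a permutation of 0..K-1")
        if len(self.hidden_signs) != k or any(s not in (-1, 1) for s in self.hidden_signs):
            raise ValueError("hidden_signs must be +/-1 of length K")

    @property
    def k(self) -> int:
        return len(self.hidden_perm)

    @property
    def is_identity(self) -> bool:
        return (
            self.hidden_perm == tuple(range(self.k))
            and all(s == 1 for s in self.hidden_signs)
            and not self.input_swap
        )

    def compose(self, other: "InvariantTransform") -> "InvariantTransform":
        """The transform 'apply ``other`` first, then ``self``'."""
        if self.k != other.k:
            raise ValueError("transforms act on different hidden counts")
        perm = tuple(other.hidden_perm[p] for p in self.hidden_perm)
        signs = tuple(
            self.hidden_signs[k] * other.hidden_signs[self.hidden_perm[k]]
            for k in range(self.k)
        )
        return InvariantTransform(perm, signs, self.input_swap != other.input_swap)


def _permutation_and_signs(
    t: InvariantTransform, config: NetworkConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-network permutation vector and sign vector realising ``t``.

    ``perm[i]`` = old index of the neuron placed at new index ``i``;
    ``signs[i]`` applies to new index ``i`` (always +1 on inputs/outputs).
    """
    hidden = config.hidden_ids
    if t.k != len(hidden):
        raise ValueError("transform does not match the configuration's hidden count")
    n = config.n_total
    perm = np.arange(n)
    signs = np.ones(n)
    if t.input_swap:
        a, b = config.input_ids
        perm[a], perm[b] = b, a
    for slot, src in enumerate(t.hidden_perm):
        perm[hidden[slot]] = hidden[src]
        signs[hidden[slot]] = t.hidden_signs[slot]
    return perm, signs


def apply_transform(
    w: WeightMatrix, t: InvariantTransform, config: NetworkConfig
) -> WeightMatrix:
    """Transform a structure: permute hidden (and optionally input) neurons
    and sign-flip the rows and columns of the flipped hidden neurons.

    Output neurons are never moved or sign-flipped.  The frozen mask is
    transported along with the entries.  With ``input_swap=False`` the
    transformed network's output trace equals the original's on every
    stream; with ``input_swap=True`` equality holds against the
    input-swapped stream (exact at task level for C tasks).
    """
    perm, signs = _permutation_and_signs(t, config)
    x = w.x[np.ix_(perm, perm)] * np.outer(signs, signs)
    frozen = w.frozen[np.ix_(perm, perm)]
    x[frozen] = 0.0  # sign flip of -0.0 guards: frozen entries stay exactly 0
    return WeightMatrix(x, frozen)


def enumerate_group(k: int, input_swap_allowed: bool = False) -> list[InvariantTransform]:
    """All distinct functionally invariant transforms for K hidden neurons.

    The list has ``2**k * k!`` elements, doubled when the input swap is
    allowed; it is closed under composition.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    swaps = (False, True) if input_swap_allowed else (False,)
    return [
        InvariantTransform(perm, signs, swap)
        for swap in swaps
        for perm in itertools.permutations(range(k))
        for signs in itertools.product((1, -1), repeat=k)
    ]


def predicted_cluster_count(k: int, input_swap_allowed: bool = False) -> int:
    """The cluster-count formula ``N = 2**K * K!`` (doubled with input swap)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    n = 2**k * math.factorial(k)
    return 2 * n if input_swap_allowed else n


def canonicalize(
    w: WeightMatrix, config: NetworkConfig, input_swap_allowed: bool = False
) -> tuple[WeightMatrix, InvariantTransform]:
    """The orbit representative minimising lexicographic order of the
    flattened matrix, with the transform that achieves it.

    Exhaustive over the enumerated group (practical for K <= 3, i.e. up to
    96 elements); constant on orbits, hence usable as an orbit label, and
    idempotent.
    """
    best: WeightMatrix | None = None
    best_key: tuple | None = None
    best_t: InvariantTransform | None = None
    for t in enumerate_group(len(config.hidden_ids), input_swap_allowed):
        cand = apply_transform(w, t, config)
        key = tuple(cand.x.ravel())
        if best_key is None or key < best_key:
            best, best_key, best_t = cand, key, t
    assert best is not None and best_t is not None
    return best, best_t


# ---------------------------------------------------------------------------
# Ensemble geometry
# ---------------------------------------------------------------------------


@dataclass
class EnsembleGeometry:
    """Flattened ensemble members, their condensed distance matrix, labels."""

    points: np.ndarray  # (n_members, n_synapses)
    distances: np.ndarray  # condensed, length n*(n-1)/2
    canonical_distances: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return self.points.shape[0]

    def distance_matrix(self) -> np.ndarray:
        return squareform(self.distances)


def _as_points(ensemble) -> np.ndarray:
    rows = [
        (m.flat() if isinstance(m, WeightMatrix) else np.asarray(m, dtype=float).ravel())
        for m in ensemble
    ]
    if len(rows) < 2:
        raise ValueError("need at least 2 ensemble members")
    if len({r.shape for r in rows}) != 1:
        raise ValueError("ensemble members have mismatched dimensions")
    return np.vstack(rows)


def pairwise_distances(
    ensemble,
    config: NetworkConfig | None = None,
    input_swap_allowed: bool = False,
) -> EnsembleGeometry:
    """Euclidean distances between flattened structures.

    When a configuration is given, members are additionally canonicalized
    and the post-canonicalization distances recorded: members of one orbit
    collapse onto a single point (up to training noise).
    """
    points = _as_points(ensemble)
    geo = EnsembleGeometry(points=points, distances=pdist(points))
    if config is not None:
        canon = [
            canonicalize(WeightMatrix(p.reshape(config.n_total, -1)), config, input_swap_allowed)[0].flat()
            for p in points
        ]
        geo.canonical_distances = pdist(np.vstack(canon))
    return geo


def cluster_count(
    geometry: EnsembleGeometry,
    min_gap_ratio: float = 3.0,
    atol: float = 1e-12,
) -> tuple[int, np.ndarray]:
    """Number of clusters by single-linkage agglomeration with a largest-gap cut.

    The dendrogram's merge heights are scanned for the largest ratio
    between consecutive heights; the tree is cut inside that gap.  If no
    gap reaches ``min_gap_ratio`` (or all members coincide) the ensemble
    counts as a single cluster.  Returns the count and per-member labels;
    cluster sizes are ``np.bincount`` of the labels.
    """
    n = geometry.n_members
    if np.all(geometry.distances <= atol):
        return 1, np.ones(n, dtype=int)
    z = linkage(geometry.distances, method="single")
    heights = z[:, 2]
    pos = heights > atol
    ratios = np.where(
        pos[:-1], heights[1:] / np.maximum(heights[:-1], atol), np.inf
    )
    # a merge at ~0 followed by a real merge is always a valid gap
    ratios[~pos[:-1] & pos[1:]] = np.inf
    ratios[~pos[1:]] = 1.0
    if not np.any(ratios >= min_gap_ratio):
        return 1, np.ones(n, dtype=int)
    i = int(np.argmax(ratios))
    cut = 0.5 * (heights[i] + heights[i + 1])
    labels = fcluster(z, t=cut, criterion="distance")
    return int(labels.max()), labels


def project3d(ensemble, synapse_numbers: tuple[int, int, int]) -> pd.DataFrame:
    """Three selected flat coordinates per member, for external 3-D plotting.

    Synapse numbers are 1-based row-major flat indices into the weight
    matrix (synapse 1 = first row, first column), the numbering used
    throughout reports.
    """
    points = _as_points(ensemble)
    d = points.shape[1]
    idx = []
    for s in synapse_numbers:
        if not (1 <= s <= d):
            raise IndexError(f"synapse number {s} outside 1..{d}")
        idx.append(s - 1)
    return pd.DataFrame(
        points[:, idx], columns=[f"synapse_{s}" for s in synapse_numbers]
    )


@dataclass
class ModalityReport:
    """Histogram of pairwise distances and its smoothed mode count."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    n_modes: int
    multimodal: bool


def distance_modality(
    geometry: EnsembleGeometry, bins: int = 40, smooth_window: int = 3
) -> ModalityReport:
    """Bi-/polymodality of the pairwise-distance distribution.

    A multimodal distance histogram (separated within- and between-cluster
    distance scales) is an indicator of cluster structure.  The histogram
    is smoothed with a fixed-width moving average and local maxima of the
    smoothed curve are counted; ``multimodal`` is true for >= 2 maxima.
    """
    if geometry.n_members < 3:
        raise ValueError("need at least 3 members")
    counts, edges = np.histogram(geometry.distances, bins=bins)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # local maxima with plateau handling: strictly above the previous
    # distinct value and not below the next distinct value
    n_modes = 0
    i = 0
    m = len(smoothed)
    while i < m:
        j = i
        while j + 1 < m and smoothed[j + 1] == smoothed[i]:
            j += 1
        left_ok = i == 0 or smoothed[i - 1] < smoothed[i]
        right_ok = j == m - 1 or smoothed[j + 1] < smoothed[i]
        if left_ok and right_ok and smoothed[i] > 0:
            n_modes += 1
        i = j + 1
    return ModalityReport(edges, counts, smoothed, n_modes, n_modes >= 2)
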