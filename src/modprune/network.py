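"""Graph/partition data model and (multilayer) modularity with its linear decomposition.

Modularity of a partition ``g`` of an undirected graph at resolution ``gamma`` is

    Q(gamma) = (1/2m) * sum_{ij} [A_ij - gamma * k_i k_j / 2m] delta(g_i, g_j)

with the sum over *ordered* node pairs including i = j.  A self-loop of weight w
contributes A_ii = 2w (so that k_i = sum_j A_ij and 2m = sum_i k_i hold exactly).

Because Q is affine in gamma (and, for multilayer networks, in the interlayer
coupling omega), each partition is summarized by three coefficients

    Q_tilde(gamma, omega) = A_hat - gamma * P_hat + omega * C_hat

where A_hat is the within-community adjacency weight over ordered pairs, P_hat the
within-community null-model mass, and C_hat the number (weight) of ordered
interlayer couplings whose endpoints share a label.  These coefficients are what
the convex-hull pruning compares across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Graph",
    "MultilayerNetwork",
    "Partition",
    "MultilayerPartition",
    "QualityCoefficients",
    "modularity",
    "multilayer_modularity",
    "partition_coefficients",
    "multilayer_partition_coefficients",
    "TEMPORAL_CHAIN",
    "MULTIPLEX_ALL_PAIRS",
]

TEMPORAL_CHAIN = "temporal_chain"
MULTIPLEX_ALL_PAIRS = "multiplex_all_pairs"
_COUPLINGS = (TEMPORAL_CHAIN, MULTIPLEX_ALL_PAIRS)


class EmptyGraphError(ValueError):
    """Raised when a quality function is evaluated on a graph with no edge weight."""


def _canonicalize(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel to 0..K-1 in order of first appearance."""
    _, first, inv = np.unique(labels, return_index=True, return_inverse=True)
    rank = np.argsort(np.argsort(first, kind="stable"), kind="stable")
    canon = rank[inv].astype(np.int64)
    return canon, int(rank.size)


class Partition:
    """Community labels for the nodes of a single-layer graph.

    Labels are canonicalized to 0..K-1 in order of first appearance, so two
    partitions are equal iff they induce the same grouping.
    """

    __slots__ = ("labels", "K", "_key")

    def __init__(self, labels: Sequence[int] | np.ndarray):
        arr = np.asarray(labels)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        self.labels, self.K = _canonicalize(arr)
        self.labels.flags.writeable = False
        self._key = self.labels.tobytes()

    @property
    def n(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"Partition(n={self.n}, K={self.K})"


class MultilayerPartition:
    """Community labels per node-layer, stored as a (T, n) array.

    Canonicalization runs over the flattened layer-major label sequence, so
    equality is again grouping equality on node-layers.
    """

    __slots__ = ("labels", "K", "_key")

    def __init__(self, labels: np.ndarray | Sequence[Sequence[int]]):
        arr = np.asarray(labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a non-empty (T, n) array")
        flat, self.K = _canonicalize(arr.ravel())
        self.labels = flat.reshape(arr.shape)
        self.labels.flags.writeable = False
        self._key = self.labels.tobytes() + bytes(str(arr.shape), "ascii")

    @property
    def T(self) -> int:
        return self.labels.shape[0]

    @property
    def n(self) -> int:
        return self.labels.shape[1]

    def layer(self, s: int) -> np.ndarray:
        return self.labels[s]

    def __eq__(self, other) -> bool:
        return isinstance(other, MultilayerPartition) and self._key == other._key

    def __hash__(self) -> int:
        return hash(self._key)

    def __repr__(self) -> str:
        return f"MultilayerPartition(T={self.T}, n={self.n}, K={self.K})"


class Graph:
    """Undirected weighted graph as an edge list over nodes 0..n-1.

    Parallel edges are allowed (their weights add in every quality sum) and a
    self-loop of weight w contributes 2w to its endpoint's degree.
    """

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] | Iterable[tuple[int, int, float]]):
        edges = list(edges)
        if n <= 0:
            raise ValueError("n must be positive")
        if edges and len(edges[0]) == 3:
            u, v, w = (np.asarray(x) for x in zip(*edges))
        elif edges:
            u, v = (np.asarray(x) for x in zip(*edges))
            w = np.ones(len(edges))
        else:
            u = v = np.empty(0, dtype=np.int64)
            w = np.empty(0)
        self.n = int(n)
        self.u = u.astype(np.int64)
        self.v = v.astype(np.int64)
        self.w = w.astype(np.float64)
        if self.u.size and (self.u.min() < 0 or max(self.u.max(), self.v.max()) >= n):
            raise ValueError("edge endpoint out of range")
        if np.any(self.w < 0):
            raise ValueError("edge weights must be non-negative")
        # self-loops land in both bincounts, giving the required k_i += 2w
        self.k = np.bincount(self.u, self.w, minlength=n) + np.bincount(self.v, self.w, minlength=n)
        self.two_m = float(self.k.sum())

    @property
    def m_edges(self) -> int:
        return self.u.size

    @property
    def is_weighted(self) -> bool:
        return bool(self.w.size) and not np.all(self.w == 1.0)

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph(n=self.n, edges=list(zip(self.u.tolist(), self.v.tolist())))
        g.es["weight"] = self.w.tolist()
        return g

    @classmethod
    def from_networkx(cls, G, weight: str = "weight") -> "Graph":
        nodes = list(G.nodes())
        idx = {node: i for i, node in enumerate(nodes)}
        edges = [(idx[a], idx[b], float(d.get(weight, 1.0))) for a, b, d in G.edges(data=True)]
        return cls(len(nodes), edges)

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, edges={self.m_edges}, 2m={self.two_m:g})"


class MultilayerNetwork:
    """A sequence of layers over a shared node set with uniform interlayer coupling.

    Node identity across layers is positional.  The coupling topology is either a
    temporal chain (node i in layer t coupled to itself in layers t-1 and t+1) or
    multiplex all-pairs (every distinct layer pair coupled); present couplings all
    carry the same weight omega, supplied at evaluation time.
    """

    def __init__(self, layers: Sequence[Graph], coupling: str = TEMPORAL_CHAIN):
        layers = list(layers)
        if not layers:
            raise ValueError("need at least one layer")
        n = layers[0].n
        if any(g.n != n for g in layers):
            raise ValueError("all layers must share the node count")
        if coupling not in _COUPLINGS:
            raise ValueError(f"coupling must be one of {_COUPLINGS}")
        self.layers = layers
        self.coupling = coupling
        self.n = n
        self.T = len(layers)

    def coupled_layer_pairs(self) -> list[tuple[int, int]]:
        """Ordered (s, r) layer pairs carrying interlayer links."""
        if self.coupling == TEMPORAL_CHAIN:
            pairs = [(t, t + 1) for t in range(self.T - 1)]
        else:
            pairs = [(s, r) for s in range(self.T) for r in range(s + 1, self.T)]
        return [p for s, r in pairs for p in ((s, r), (r, s))]

    @property
    def n_ordered_couplings(self) -> int:
        return self.n * len(self.coupled_layer_pairs())

    @property
    def total_two_m(self) -> float:
        return float(sum(g.two_m for g in self.layers))

    def two_mu(self, omega: float) -> float:
        """2*mu = sum of all intralayer degrees plus ordered interlayer couplings."""
        return self.total_two_m + omega * self.n_ordered_couplings

    def __repr__(self) -> str:
        return f"MultilayerNetwork(T={self.T}, n={self.n}, coupling={self.coupling!r})"


@dataclass(frozen=True)
class QualityCoefficients:
    """Linear decomposition Q_tilde(gamma, omega) = A_hat - gamma*P_hat + omega*C_hat."""

    A_hat: float
    P_hat: float
    C_hat: float = 0.0

    def value(self, gamma: float, omega: float = 0.0) -> float:
        return self.A_hat - gamma * self.P_hat + omega * self.C_hat

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A_hat, self.P_hat, self.C_hat)


def _layer_coefficients(graph: Graph, labels: np.ndarray) -> tuple[float, float]:
    """(A_hat, P_hat) of one layer; ordered-pair convention throughout."""
    within = labels[graph.u] == labels[graph.v]
    A_hat = 2.0 * float(graph.w[within].sum())
    if graph.two_m == 0:
        return A_hat, 0.0
    kappa = np.bincount(labels, graph.k)
    P_hat = float((kappa**2).sum() / graph.two_m)
    return A_hat, P_hat


def partition_coefficients(graph: Graph, partition: Partition) -> QualityCoefficients:
    """Coefficients (A_hat, P_hat, 0) with 2m * Q(gamma) = A_hat - gamma * P_hat."""
    if partition.n != graph.n:
        raise ValueError("partition must label every node")
    A_hat, P_hat = _layer_coefficients(graph, partition.labels)
    return QualityCoefficients(A_hat, P_hat, 0.0)


def modularity(graph: Graph, partition: Partition, gamma: float) -> float:
    """Resolution-parametrized modularity Q(gamma)."""
    if graph.two_m == 0:
        raise EmptyGraphError("modularity undefined for a graph with no edge weight")
    c = partition_coefficients(graph, partition)
    return c.value(gamma) / graph.two_m


def interlayer_agreement_count(ml: MultilayerNetwork, partition: MultilayerPartition) -> float:
    """C_hat: ordered coupled node-layer pairs whose endpoints share a label."""
    labels = partition.labels
    total = 0
    seen = set()
    for s, r in ml.coupled_layer_pairs():
        key = (min(s, r), max(s, r))
        if key in seen:
            continue
        seen.add(key)
        total += 2 * int((labels[s] == labels[r]).sum())
    return float(total)


def multilayer_partition_coefficients(
    ml: MultilayerNetwork, partition: MultilayerPartition
) -> QualityCoefficients:
    """Coefficients with 2mu(omega) * Q(gamma, omega) = A_hat - gamma*P_hat + omega*C_hat."""
    if partition.T != ml.T or partition.n != ml.n:
        raise ValueError("partition shape must match the network's (T, n)")
    A = P = 0.0
    for s, g in enumerate(ml.layers):
        a, p = _layer_coefficients(g, partition.layer(s))
        A += a
        P += p
    C = interlayer_agreement_count(ml, partition)
    return QualityCoefficients(A, P, C)


def multilayer_modularity(
    ml: MultilayerNetwork, partition: MultilayerPartition, gamma: float, omega: float
) -> float:
    """Multilayer modularity with uniform resolution gamma and coupling weight omega."""
    if ml.total_two_m == 0:
        raise EmptyGraphError("multilayer modularity undefined: all layers are empty")
    c = multilayer_partition_coefficients(ml, partition)
    return c.value(gamma, omega) / ml.two_mu(omega)
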