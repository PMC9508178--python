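"""Synthetic benchmark generators: hierarchical blocks, temporal label-copying, equal blocks.

Two study designs are emulated.  The hierarchical block model places 450 nodes
in 9 equal blocks grouped into 3 communities of 3 subcommunities each; node
pairs connect independently with probability 0.12 within a subcommunity, 0.03
within the same community but across subcommunities, and 1/600 across
communities, so that both a 3-community and a 9-subcommunity description of the
same network are meaningful.

The temporal model assigns first-layer labels evenly among K communities and
then copies each node's label from the previous layer with probability eta,
otherwise resampling uniformly from all K labels (so consecutive labels agree
with probability eta + (1 - eta)/K).  Within each layer, edges are placed
independently with probability p_in inside communities and p_out between them;
epsilon = p_out/p_in sets the strength of the planted structure.  Layers are
coupled as a temporal chain.  When p_in is not given it is chosen to hit a
target mean degree (default 20 at the canonical n = 150, T = 15 sizes); the
planted-partition parameter estimates depend on the edge probabilities only
through epsilon, so this choice does not move the ground-truth estimates.

All generators draw labels before edges from a single seeded generator, so the
label stream is unchanged when only edge probabilities vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import TEMPORAL_CHAIN, Graph, MultilayerNetwork, MultilayerPartition, Partition

__all__ = [
    "HierarchicalSpec",
    "TemporalSpec",
    "generate_hierarchical",
    "generate_temporal",
    "generate_equal_blocks",
]


@dataclass(frozen=True)
class HierarchicalSpec:
    """Parameters of the two-scale hierarchical block model."""

    n: int = 450
    blocks: int = 9
    groups: int = 3
    p_sub: float = 0.12
    p_group: float = 0.03
    p_between: float = 1.0 / 600.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_sub, self.p_group, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n % self.blocks or self.blocks % self.groups:
            raise ValueError("n must divide into equal blocks, blocks into equal groups")


@dataclass(frozen=True)
class TemporalSpec:
    """Parameters of the temporal label-copying planted-partition model."""

    n: int = 150
    T: int = 15
    K: int = 2
    eta: float = 0.7
    epsilon: float = 0.4
    p_in: Optional[float] = None
    mean_degree: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.n % self.K:
            raise ValueError("n must be divisible by K for an even first-layer split")

    @property
    def edge_p_in(self) -> float:
        if self.p_in is not None:
            return self.p_in
        # mean degree ~= (n/K - 1) p_in + (n - n/K) p_out
        within = self.n / self.K - 1
        between = self.n - self.n / self.K
        return self.mean_degree / (within + between * self.epsilon)

    @property
    def edge_p_out(self) -> float:
        return self.edge_p_in * self.epsilon


def _bernoulli_block_edges(rng, rows: np.ndarray, cols: np.ndarray, p: float) -> list:
    """Edges among the cross product rows x cols (or upper triangle if identical)."""
    if rows is cols:
        iu, ju = np.triu_indices(len(rows), k=1)
        pick = rng.random(iu.size) < p
        return list(zip(rows[iu[pick]].tolist(), cols[ju[pick]].tolist()))
    mask = rng.random((len(rows), len(cols))) < p
    ii, jj = np.nonzero(mask)
    return list(zip(rows[ii].tolist(), cols[jj].tolist()))


def generate_hierarchical(spec: HierarchicalSpec) -> tuple[Graph, Partition, Partition]:
    """One realization of the hierarchical model with its planted 3- and 9-partitions."""
    rng = np.random.default_rng(spec.seed)
    size = spec.n // spec.blocks
    per_group = spec.blocks // spec.groups
    block_of = np.repeat(np.arange(spec.blocks), size)
    group_of_block = np.arange(spec.blocks) // per_group
    node_ids = [np.arange(b * size, (b + 1) * size) for b in range(spec.blocks)]
    edges: list = []
    for b in range(spec.blocks):
        edges += _bernoulli_block_edges(rng, node_ids[b], node_ids[b], spec.p_sub)
        for b2 in range(b + 1, spec.blocks):
            p = spec.p_group if group_of_block[b] == group_of_block[b2] else spec.p_between
            edges += _bernoulli_block_edges(rng, node_ids[b], node_ids[b2], p)
    graph = Graph(spec.n, edges)
    return graph, Partition(group_of_block[block_of]), Partition(block_of)


def _temporal_labels(rng, n: int, T: int, K: int, eta: float) -> np.ndarray:
    labels = np.empty((T, n), dtype=np.int64)
    labels[0] = np.repeat(np.arange(K), n // K)
    for t in range(1, T):
        copied = rng.random(n) < eta
        fresh = rng.integers(K, size=n)
        labels[t] = np.where(copied, labels[t - 1], fresh)
    return labels


def _planted_layer(rng, labels: np.ndarray, p_in: float, p_out: float) -> Graph:
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    pick = rng.random(iu.size) < p
    return Graph(n, list(zip(iu[pick].tolist(), ju[pick].tolist())))


def generate_temporal(spec: TemporalSpec) -> tuple[MultilayerNetwork, MultilayerPartition]:
    """One realization of the temporal model with its planted node-layer labels."""
    rng = np.random.default_rng(spec.seed)
    labels = _temporal_labels(rng, spec.n, spec.T, spec.K, spec.eta)
    layers = [
        _planted_layer(rng, labels[t], spec.edge_p_in, spec.edge_p_out) for t in range(spec.T)
    ]
    return MultilayerNetwork(layers, TEMPORAL_CHAIN), MultilayerPartition(labels)


def generate_equal_blocks(
    n: int, K: int, p_in: float, p_out: float, seed: int = 0
) -> tuple[Graph, Partition]:
    """Single-layer planted partition with K equal blocks (test fixture workhorse)."""
    if n % K:
        raise ValueError("n must be divisible by K")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(K), n // K)
    return _planted_layer(rng, labels, p_in, p_out), Partition(labels)
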