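"""Pluggable modularity-maximization backends that produce input partition pools.

The pruning framework post-processes partitions however they were obtained; this
module supplies the common ways to obtain them:

* ``leiden`` (default): the Leiden algorithm via leidenalg.  Single-layer
  maximization uses the configuration null model at resolution gamma;
  multilayer maximization optimizes the supra quality
  A_hat - gamma*P_hat + omega*C_hat by combining one per-layer
  RBConfiguration partition per layer with an omega-weighted interlayer
  coupling partition (GenLouvain-style supra formulation).
* ``spinglass``: igraph's spin-glass heuristic, the natural backend for
  fixed-K single-layer searches (connected graphs only).
* ``exhaustive``: brute-force argmax over all set partitions, feasible for
  roughly <= 12 items; the testing oracle.
* ``greedy``: dependency-free agglomerative merging on the supra quality
  matrix; a fallback, not competitive with Leiden.

Fixed-K requests on backends without native support are satisfied by rejection
filtering of unconstrained runs (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import (
    Graph,
    MultilayerNetwork,
    MultilayerPartition,
    Partition,
)

__all__ = ["MaximizerSpec", "maximize", "sweep", "enumerate_set_partitions", "brute_force_maximum"]

_REJECTION_ATTEMPTS = 50


@dataclass(frozen=True)
class MaximizerSpec:
    """One maximization request: backend, quality parameters, seed, optional fixed K."""

    backend: str = "leiden"
    gamma: float = 1.0
    omega: float = 1.0
    K: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.K is not None and self.K < 1:
            raise ValueError("K constraint must be >= 1")


# ---------------------------------------------------------------------------
# supra quality matrix (shared by greedy and exhaustive backends)


def _supra_matrix(network, gamma: float, omega: float) -> np.ndarray:
    """Dense symmetric M with Q_tilde(partition) = sum of M over same-label ordered pairs."""
    if isinstance(network, Graph):
        layers, coupling_pairs, n, T = [network], [], network.n, 1
    else:
        layers, coupling_pairs, n, T = (
            network.layers,
            network.coupled_layer_pairs(),
            network.n,
            network.T,
        )
    N = n * T
    M = np.zeros((N, N))
    for s, g in enumerate(layers):
        off = s * n
        np.add.at(M, (g.u + off, g.v + off), g.w)
        np.add.at(M, (g.v + off, g.u + off), g.w)
        if g.two_m > 0:
            M[off : off + n, off : off + n] -= gamma * np.outer(g.k, g.k) / g.two_m
    for s, r in coupling_pairs:
        idx = np.arange(n)
        M[s * n + idx, r * n + idx] += omega
    return M


def _labels_to_partition(network, labels: np.ndarray):
    if isinstance(network, Graph):
        return Partition(labels)
    return MultilayerPartition(np.asarray(labels).reshape(network.T, network.n))


# ---------------------------------------------------------------------------
# exhaustive backend


def enumerate_set_partitions(n: int):
    """Yield every set partition of range(n) as a label array (restricted growth)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def brute_force_maximum(network, gamma: float, omega: float = 0.0, K: Optional[int] = None):
    """Exact argmax of the supra quality over all set partitions (small inputs only)."""
    n_items = network.n if isinstance(network, Graph) else network.n * network.T
    if n_items > 13:
        raise ValueError("exhaustive search is limited to <= 13 items")
    M = _supra_matrix(network, gamma, omega)
    best_val, best_labels = -np.inf, None
    for labels in enumerate_set_partitions(n_items):
        if K is not None and labels.max() + 1 != K:
            continue
        val = 0.0
        for c in range(labels.max() + 1):
            idx = np.nonzero(labels == c)[0]
            val += M[np.ix_(idx, idx)].sum()
        if val > best_val:
            best_val, best_labels = val, labels
    if best_labels is None:
        raise ValueError(f"no partition with K={K} communities exists for n={n_items}")
    return _labels_to_partition(network, best_labels)


# ---------------------------------------------------------------------------
# greedy agglomeration


def _greedy_maximum(network, gamma: float, omega: float = 0.0):
    M = _supra_matrix(network, gamma, omega)
    N = len(M)
    S = M.copy()  # community-aggregated quality matrix
    alive = list(range(N))
    members: dict[int, list[int]] = {i: [i] for i in range(N)}
    while len(alive) > 1:
        sub = S[np.ix_(alive, alive)]
        np.fill_diagonal(sub, -np.inf)
        flat = int(np.argmax(sub))
        gain = sub.flat[flat]
        if gain <= 0:
            break
        a, b = alive[flat // len(alive)], alive[flat % len(alive)]
        S[a, :] += S[b, :]
        S[:, a] += S[:, b]
        members[a] += members.pop(b)
        alive.remove(b)
    labels = np.empty(N, dtype=np.int64)
    for c, (root, mem) in enumerate(members.items()):
        labels[mem] = c
    return _labels_to_partition(network, labels)


# ---------------------------------------------------------------------------
# leidenalg / igraph backends


def _single_layer_igraph(graph: Graph):
    if not hasattr(graph, "_ig_cache"):
        graph._ig_cache = graph.to_igraph()
    return graph._ig_cache


def _supra_igraphs(ml: MultilayerNetwork):
    """Cached per-layer igraph graphs on the n*T supra vertex set plus the coupling graph."""
    if hasattr(ml, "_supra_cache"):
        return ml._supra_cache
    import igraph as ig

    n, T = ml.n, ml.T
    layer_graphs = []
    for s, g in enumerate(ml.layers):
        G = ig.Graph(n=n * T)
        G.add_edges(list(zip((g.u + s * n).tolist(), (g.v + s * n).tolist())))
        G.es["weight"] = g.w.tolist()
        layer_graphs.append(G)
    coupling = ig.Graph(n=n * T)
    seen = set()
    c_edges = []
    for s, r in ml.coupled_layer_pairs():
        key = (min(s, r), max(s, r))
        if key in seen:
            continue
        seen.add(key)
        c_edges += [(key[0] * n + i, key[1] * n + i) for i in range(n)]
    coupling.add_edges(c_edges)
    ml._supra_cache = (layer_graphs, coupling)
    return ml._supra_cache


def _leiden_single(graph: Graph, gamma: float, seed: int) -> Partition:
    import leidenalg as la

    g = _single_layer_igraph(graph)
    part = la.find_partition(
        g,
        la.RBConfigurationVertexPartition,
        weights=g.es["weight"] if graph.is_weighted else None,
        resolution_parameter=gamma,
        seed=int(seed),
    )
    return Partition(np.asarray(part.membership))


def _leiden_multilayer(ml: MultilayerNetwork, gamma: float, omega: float, seed: int) -> MultilayerPartition:
    import leidenalg as la

    layer_graphs, coupling = _supra_igraphs(ml)
    parts = [
        la.RBConfigurationVertexPartition(
            G, weights=G.es["weight"] if g.is_weighted else None, resolution_parameter=gamma
        )
        for G, g in zip(layer_graphs, ml.layers)
    ]
    cpart = la.CPMVertexPartition(coupling, resolution_parameter=0.0)
    opt = la.Optimiser()
    opt.set_rng_seed(int(seed))
    opt.optimise_partition_multiplex(parts + [cpart], layer_weights=[1.0] * ml.T + [float(omega)])
    labels = np.asarray(parts[0].membership).reshape(ml.T, ml.n)
    return MultilayerPartition(labels)


def _spinglass(graph: Graph, gamma: float, K: int, seed: int) -> Partition:
    import igraph  # noqa: F401  (random module seeding below drives spinglass)
    import random

    random.seed(int(seed))
    g = _single_layer_igraph(graph)
    cl = g.community_spinglass(
        weights="weight" if graph.is_weighted else None, spins=K, gamma=gamma
    )
    return Partition(np.asarray(cl.membership))


def maximize(network, spec: MaximizerSpec):
    """Run one maximization; deterministic for a fixed backend and seed."""
    single = isinstance(network, Graph)
    gamma, omega = spec.gamma, spec.omega
    if spec.backend == "exhaustive":
        return brute_force_maximum(network, gamma, omega, K=spec.K)
    if spec.backend == "greedy":
        part = _greedy_maximum(network, gamma, omega)
        if spec.K is not None and part.K != spec.K:
            raise ValueError("greedy backend cannot satisfy a K constraint")
        return part
    if spec.backend == "spinglass":
        if not single:
            raise ValueError("spinglass backend is single-layer only")
        if spec.K is None:
            raise ValueError("spinglass backend requires a K constraint")
        return _spinglass(network, gamma, spec.K, spec.seed)
    if spec.backend != "leiden":
        raise ValueError(f"unknown backend {spec.backend!r}")

    rng = np.random.default_rng(spec.seed)
    for _ in range(_REJECTION_ATTEMPTS if spec.K is not None else 1):
        run_seed = int(rng.integers(2**31 - 1))
        part = (
            _leiden_single(network, gamma, run_seed)
            if single
            else _leiden_multilayer(network, gamma, omega, run_seed)
        )
        if spec.K is None or part.K == spec.K:
            return part
    raise ValueError(f"leiden backend failed to produce K={spec.K} in {_REJECTION_ATTEMPTS} runs")


def sweep(
    network,
    gamma_grid: Sequence[float],
    omega_grid: Optional[Sequence[float]] = None,
    runs_per_point: int = 1,
    seed: int = 0,
    backend: str = "leiden",
    K: Optional[int] = None,
):
    """Maximize at every grid point, canonicalize and deduplicate the results.

    Returns (partitions, manifest): the unique partitions in first-found order
    and a manifest describing the grid and seeds.  Reproducible from ``seed``.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid or (omega_grid is not None and not len(omega_grid)):
        raise ValueError("grids must be non-empty")
    omega_points = list(omega_grid) if omega_grid is not None else [0.0]
    rng = np.random.default_rng(seed)
    total = len(gamma_grid) * len(omega_points) * runs_per_point
    run_seeds = rng.integers(2**31 - 1, size=total)
    pool: dict = {}
    idx = 0
    for gamma in gamma_grid:
        for omega in omega_points:
            for _ in range(runs_per_point):
                spec = MaximizerSpec(
                    backend=backend, gamma=float(gamma), omega=float(omega), K=K,
                    seed=int(run_seeds[idx]),
                )
                idx += 1
                try:
                    part = maximize(network, spec)
                except ValueError:
                    continue  # unsatisfiable K at this grid point
                pool.setdefault(part, None)
    manifest = {
        "backend": backend,
        "gamma_grid": [float(g) for g in gamma_grid],
        "omega_grid": [float(w) for w in omega_points] if omega_grid is not None else None,
        "runs_per_point": runs_per_point,
        "seed": seed,
        "K": K,
        "total_runs": total,
        "unique_partitions": len(pool),
    }
    return list(pool.keys()), manifest
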