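"""Readers and writers for the package's plain-text exchange formats.

Single-layer networks: GML (via igraph) or 2-3 column whitespace edge lists
``u v [w]``.  Multilayer networks: 4-column edge lists ``layer u v [w]`` with
layers numbered 0..T-1; the coupling topology is not stored in the file and is
supplied by the caller.  Partitions: CSV ``node[,layer],label``.  Node ids are
mapped to 0..n-1 and the mapping is returned (and can be persisted as JSON).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .network import Graph, MultilayerNetwork, MultilayerPartition, Partition

__all__ = [
    "read_edgelist",
    "read_gml",
    "read_multilayer_edgelist",
    "read_partition_csv",
    "write_partition_csv",
    "write_edgelist",
    "write_multilayer_edgelist",
]


def _tokenize(path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.replace(",", " ").split())
    return rows


def read_edgelist(path, n: Optional[int] = None) -> tuple[Graph, dict]:
    """Read ``u v [w]`` lines; returns (graph, node-id -> index mapping)."""
    rows = _tokenize(path)
    mapping: dict[str, int] = {}

    def idx(tok: str) -> int:
        return mapping.setdefault(tok, len(mapping))

    edges = []
    for row in rows:
        if len(row) not in (2, 3):
            raise ValueError(f"edge list rows need 2 or 3 columns, got {row}")
        w = float(row[2]) if len(row) == 3 else 1.0
        edges.append((idx(row[0]), idx(row[1]), w))
    count = n if n is not None else len(mapping)
    return Graph(count, edges), mapping


def read_gml(path) -> tuple[Graph, dict]:
    import igraph as ig

    g = ig.Graph.Read_GML(str(path))
    w = g.es["weight"] if "weight" in g.es.attributes() else [1.0] * g.ecount()
    edges = [(e.source, e.target, float(wt)) for e, wt in zip(g.es, w)]
    names = g.vs["label"] if "label" in g.vs.attributes() else list(range(g.vcount()))
    return Graph(g.vcount(), edges), {name: i for i, name in enumerate(names)}


def read_multilayer_edgelist(path, coupling: str, T: Optional[int] = None) -> tuple[MultilayerNetwork, dict]:
    """Read ``layer u v [w]`` lines into a multilayer network with the given coupling."""
    rows = _tokenize(path)
    mapping: dict[str, int] = {}

    def idx(tok: str) -> int:
        return mapping.setdefault(tok, len(mapping))

    by_layer: dict[int, list] = {}
    for row in rows:
        if len(row) not in (3, 4):
            raise ValueError(f"multilayer rows need 3 or 4 columns, got {row}")
        layer = int(row[0])
        w = float(row[3]) if len(row) == 4 else 1.0
        by_layer.setdefault(layer, []).append((idx(row[1]), idx(row[2]), w))
    n = len(mapping)
    n_layers = T if T is not None else (max(by_layer) + 1 if by_layer else 1)
    layers = [Graph(n, by_layer.get(t, [])) for t in range(n_layers)]
    return MultilayerNetwork(layers, coupling), mapping


def read_partition_csv(path, n: int, T: Optional[int] = None):
    """Read ``node[,layer],label`` rows into a Partition or MultilayerPartition."""
    rows = _tokenize(path)
    rows = [r for r in rows if not r[0].lower().startswith("node")]
    if T is None:
        labels = np.full(n, -1, dtype=np.int64)
        for r in rows:
            labels[int(r[0])] = int(r[-1])
        if (labels < 0).any():
            raise ValueError("partition file does not label every node")
        return Partition(labels)
    labels = np.full((T, n), -1, dtype=np.int64)
    for r in rows:
        if len(r) != 3:
            raise ValueError("multilayer partition rows need node,layer,label")
        labels[int(r[1]), int(r[0])] = int(r[2])
    if (labels < 0).any():
        raise ValueError("partition file does not label every node-layer")
    return MultilayerPartition(labels)


def write_partition_csv(path, partition) -> None:
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh)
        if isinstance(partition, MultilayerPartition):
            out.writerow(["node", "layer", "label"])
            for t in range(partition.T):
                for i in range(partition.n):
                    out.writerow([i, t, int(partition.labels[t, i])])
        else:
            out.writerow(["node", "label"])
            for i, lab in enumerate(partition.labels):
                out.writerow([i, int(lab)])


def write_edgelist(path, graph: Graph) -> None:
    with open(path, "w") as fh:
        for u, v, w in zip(graph.u, graph.v, graph.w):
            fh.write(f"{u}\t{v}\t{w:g}\n")


def write_multilayer_edgelist(path, ml: MultilayerNetwork) -> None:
    with open(path, "w") as fh:
        for t, g in enumerate(ml.layers):
            for u, v, w in zip(g.u, g.v, g.w):
                fh.write(f"{t}\t{u}\t{v}\t{w:g}\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
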