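"""Sparse undirected LD graphs and random-walk community detection.

The neighborhood-selection stage emits an undirected, unweighted graph over
SNPs (or, genome-wide, over chromosome-wise clusters). LD blocks are the
communities found by the walktrap algorithm (short random walks +
agglomerative merging, cut at maximum modularity), as implemented in igraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import igraph as ig


@dataclass
class LDGraph:
    """Undirected, unweighted graph stored as a set of index pairs.

    Invariants: no self-loops; each edge stored once as (min, max).
    """

    n_nodes: int
    edges: set = field(default_factory=set)
    node_labels: list | None = None

    def __post_init__(self):
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed")
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError(f"edge ({a},{b}) outside node range")
            norm.add((min(a, b), max(a, b)))
        self.edges = norm
        if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length != n_nodes")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        possible = self.n_nodes * (self.n_nodes - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def adjacency(self):
        """Dense symmetric hollow 0/1 adjacency matrix (small graphs only)."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for a, b in self.edges:
            A[a, b] = A[b, a] = 1
        return A

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=sorted(self.edges))
        if self.node_labels is not None:
            g.vs["name"] = [str(x) for x in self.node_labels]
        return g

    def write_graphml(self, path):
        self.to_igraph().write_graphml(str(path))

    def write_edgelist(self, path):
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


@dataclass
class Clustering:
    """A partition of node indices into clusters with ids dense from 1."""

    assignment: np.ndarray
    level: str = "chromosome"  # or "genome"

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(self.assignment):
            ids = np.unique(self.assignment)
            if ids[0] != 1 or not np.array_equal(ids, np.arange(1, len(ids) + 1)):
                self.assignment = relabel_dense(self.assignment)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) if len(self.assignment) else 0

    def members(self, cid) -> np.ndarray:
        return np.flatnonzero(self.assignment == cid)

    def sizes(self) -> dict:
        ids, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def relabel_dense(assignment) -> np.ndarray:
    """Relabel cluster ids to 1..K in order of first occurrence (deterministic)."""
    assignment = np.asarray(assignment)
    out = np.empty_like(assignment, dtype=int)
    mapping = {}
    for i, a in enumerate(assignment):
        if a not in mapping:
            mapping[a] = len(mapping) + 1
        out[i] = mapping[a]
    return out


def walktrap_cluster(g: LDGraph, steps: int = 4, level: str = "chromosome") -> Clustering:
    """Partition a graph into communities with walktrap at the max-modularity cut.

    Isolated nodes become singleton clusters; walktrap runs on the subgraph
    of non-isolated nodes (random walks are undefined on degree-0 vertices).
    Deterministic for a fixed graph.
    """
    assignment = np.zeros(g.n_nodes, dtype=int)
    deg = g.degree()
    active = np.flatnonzero(deg > 0)
    if len(active):
        remap = {int(v): i for i, v in enumerate(active)}
        sub = ig.Graph(
            n=len(active),
            edges=[(remap[a], remap[b]) for a, b in sorted(g.edges)],
        )
        dendro = sub.community_walktrap(steps=steps)
        membership = dendro.as_clustering().membership
        for v, m in zip(active, membership):
            assignment[v] = m + 1
    offset = int(assignment.max())
    k = 0
    for v in np.flatnonzero(deg == 0):
        k += 1
        assignment[v] = offset + k
    return Clustering(assignment=assignment, level=level)
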