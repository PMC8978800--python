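"""Protein interaction graph and balanced positive/negative pair construction.

The interaction network is an undirected graph G = (X, Y) over protein IDs.
Positives for classification are the observed edges; negatives are sampled
uniformly from unordered, distinct-vertex non-edges, one per positive, so the
labeled set is exactly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from .data_io import EdgeRecord
from .errors import GraphError, SamplingError


class ProteinGraph:
    """Undirected PPI network with a canonical (sorted) vertex order.

    Thin wrapper over a :class:`networkx.Graph`; vertex order and neighbor
    lists are sorted so that downstream seeded computation is reproducible
    from files alone.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise GraphError("graph has no vertices")
        self._g = graph
        self.vertices: list[str] = sorted(graph.nodes)
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.vertices)}
        self.adjacency: dict[str, list[str]] = {
            v: sorted(graph.neighbors(v)) for v in self.vertices
        }

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        """Unordered edge keys (a <= b)."""
        return {tuple(sorted(e)) for e in self._g.edges}

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def neighbors(self, v: str) -> list[str]:
        return self.adjacency[v]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def subgraph_from_edges(self, edges: Iterable[tuple[str, str]]) -> "ProteinGraph":
        """Graph over the same vertex set restricted to the given edges."""
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return ProteinGraph(g)

    def csr_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(neighbors_flat, offsets) in canonical vertex-index space,
        for vectorised random walks."""
        offsets = np.zeros(self.n_vertices + 1, dtype=np.int64)
        flat: list[int] = []
        for i, v in enumerate(self.vertices):
            nbrs = [self.index[u] for u in self.adjacency[v]]
            flat.extend(nbrs)
            offsets[i + 1] = offsets[i] + len(nbrs)
        return np.asarray(flat, dtype=np.int64), offsets


@dataclass
class LabeledPairSet:
    """Protein pairs with binary interaction labels."""

    pairs: list[tuple[str, str]]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels):
            raise GraphError("pairs and labels differ in length")

    def __len__(self) -> int:
        return len(self.pairs)


def build_graph(edges: Iterable[EdgeRecord | tuple[str, str]]) -> ProteinGraph:
    """Build the PPI graph from an edge collection.

    The vertex set is every ID appearing in an edge; orientation duplicates
    collapse and self-loops are ignored. Raises :class:`GraphError` if no
    edges remain.
    """
    g = nx.Graph()
    for e in edges:
        a, b = (e.protein_a, e.protein_b) if isinstance(e, EdgeRecord) else e
        if a == b:
            continue
        g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise GraphError("no edges supplied")
    return ProteinGraph(g)


def count_candidate_negatives(n_vertices: int, n_edges: int) -> int:
    """Candidate non-interaction count by the n² − m reporting convention.

    With 7,437 proteins and 28,110 interactions this gives 55,280,859 —
    the count over ordered pairs including self-pairs. The actual sampler
    (:func:`sample_negatives`) draws from unordered distinct-vertex
    non-edges instead; the two conventions are deliberately distinct.
    """
    if n_vertices < 1 or n_edges < 0:
        raise GraphError("need n_vertices >= 1 and n_edges >= 0")
    count = n_vertices * n_vertices - n_edges
    if count < 0:
        raise GraphError(f"negative candidate count: {count}")
    return count


def _max_non_edges(graph: ProteinGraph) -> int:
    n = graph.n_vertices
    return n * (n - 1) // 2 - graph.n_edges


def sample_negatives(graph: ProteinGraph, n_neg: int, seed: int) -> list[tuple[str, str]]:
    """Uniformly sample ``n_neg`` distinct unordered non-edges.

    Rejection sampling with a visited set: the candidate space is huge and
    sparse relative to the edge set, so expected time is O(n_neg). For
    near-complete graphs it falls back to enumerating all non-edges.
    Deterministic for fixed (graph, n_neg, seed).
    """
    available = _max_non_edges(graph)
    if n_neg > available:
        raise SamplingError(f"requested {n_neg} negatives but only {available} non-edges exist")
    rng = np.random.default_rng(seed)
    n = graph.n_vertices
    verts = graph.vertices
    edge_set = graph.edge_set
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    # dense graphs: rejection would thrash; enumerate instead
    if available < 4 * n_neg:
        non_edges = sorted(
            (verts[i], verts[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (verts[i], verts[j]) not in edge_set and (verts[j], verts[i]) not in edge_set
        )
        idx = rng.choice(len(non_edges), size=n_neg, replace=False)
        return [non_edges[i] for i in sorted(idx)]
    while len(out) < n_neg:
        draw = rng.integers(0, n, size=2 * (n_neg - len(out)) + 8)
        for i in range(0, len(draw) - 1, 2):
            a, b = verts[draw[i]], verts[draw[i + 1]]
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in edge_set or key in chosen:
                continue
            chosen.add(key)
            out.append(key)
            if len(out) == n_neg:
                break
    return out


def build_labeled_set(graph: ProteinGraph, seed: int) -> LabeledPairSet:
    """All edges labeled 1 plus an equal number of sampled non-edges labeled 0.

    Mirrors the balanced construction used for the plant datasets
    (e.g. 28,110 positives + 28,110 random negatives). Total size 2 |Y|.
    """
    positives = sorted(graph.edge_set)
    if not positives:
        raise GraphError("graph has no edges")
    negatives = sample_negatives(graph, len(positives), seed)
    pairs = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)
    return LabeledPairSet(pairs, labels)
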