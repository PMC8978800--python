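"""Behavior embeddings: DeepWalk over the PPI graph.

Truncated random walks are treated as sentences and node vectors are
learned with skip-gram under Huffman-tree hierarchical softmax. The cosine
node-similarity matrix over the learned vectors is available as a library
feature (it is not consumed downstream; the classifier takes the raw
embeddings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import VocabularyError, WalkError
from .hsoftmax import HuffmanTree, build_huffman_tree, hs_probability, train_hs_embeddings
from .network import ProteinGraph

__all__ = [
    "WalkCorpus",
    "EmbeddingMatrix",
    "generate_walks",
    "build_huffman_tree",
    "hs_probability",
    "HuffmanTree",
    "train_skipgram",
    "cosine_similarity_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    """Ordered vocabulary with one sigma-dimensional vector per item."""

    vocabulary: list[str]
    vectors: np.ndarray  # (|vocab|, sigma)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise VocabularyError("vocabulary size does not match matrix rows")
        if not np.all(np.isfinite(self.vectors)):
            raise VocabularyError("non-finite embedding entries")
        self.index = {v: i for i, v in enumerate(self.vocabulary)}

    @property
    def sigma(self) -> int:
        return self.vectors.shape[1]

    def vector(self, item: str) -> np.ndarray:
        try:
            return self.vectors[self.index[item]]
        except KeyError:
            raise VocabularyError(f"unknown item {item!r}") from None

    def to_tsv(self, path: str | Path) -> None:
        """Headered TSV: id column + sigma value columns, full precision."""
        with open(path, "w") as handle:
            handle.write("id\t" + "\t".join(f"d{i}" for i in range(self.sigma)) + "\n")
            for item, row in zip(self.vocabulary, self.vectors):
                handle.write(item + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingMatrix":
        vocab: list[str] = []
        rows: list[list[float]] = []
        with open(path) as handle:
            next(handle)  # header
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                vocab.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(vocab, np.asarray(rows, dtype=np.float64))


@dataclass
class WalkCorpus:
    """Truncated random walks; each walk is a vertex-ID sequence."""

    walks: list[list[str]]
    walk_length: int
    walks_per_node: int

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for w in self.walks:
                handle.write(" ".join(w) + "\n")


def generate_walks(
    graph: ProteinGraph, walks_per_node: int, walk_length: int, seed: int
) -> WalkCorpus:
    """Uniform random walks of (at most) ``walk_length`` vertices.

    Each vertex roots exactly ``walks_per_node`` walks; at every step the
    next vertex is chosen uniformly among the current vertex's neighbors.
    Isolated vertices yield singleton walks. Vertex order is shuffled per
    pass (the usual DeepWalk schedule); deterministic for a fixed seed.
    """
    if walk_length < 1:
        raise WalkError(f"walk_length must be >= 1, got {walk_length}")
    if walks_per_node < 1:
        raise WalkError(f"walks_per_node must be >= 1, got {walks_per_node}")
    rng = np.random.default_rng(seed)
    n = graph.n_vertices
    nbrs, offsets = graph.csr_arrays()
    deg = np.diff(offsets)
    verts = graph.vertices
    walks: list[list[str]] = []
    for _ in range(walks_per_node):
        for start in rng.permutation(n):
            cur = int(start)
            walk = [cur]
            for _ in range(walk_length - 1):
                d = deg[cur]
                if d == 0:
                    break
                cur = int(nbrs[offsets[cur] + rng.integers(0, d)])
                walk.append(cur)
            walks.append([verts[i] for i in walk])
    return WalkCorpus(walks, walk_length, walks_per_node)


def _corpus_frequencies(corpus: WalkCorpus) -> dict[str, int]:
    freq: dict[str, int] = {}
    for walk in corpus.walks:
        for v in walk:
            freq[v] = freq.get(v, 0) + 1
    return freq


def train_skipgram(
    corpus: WalkCorpus,
    window: int,
    sigma: int,
    epochs: int,
    learning_rate: float,
    seed: int,
    vocabulary: list[str] | None = None,
) -> EmbeddingMatrix:
    """Skip-gram with hierarchical softmax over the walk corpus.

    For every walk position j, each vertex within ``window`` positions on
    either side is a context target predicted from the center's vector;
    vertex frequencies for the Huffman tree are occurrence counts in the
    corpus. If ``vocabulary`` is given, every corpus vertex must belong to
    it and vertices never visited still receive (initialisation-valued)
    rows. Deterministic for a fixed seed.
    """
    if not corpus.walks:
        raise VocabularyError("empty walk corpus")
    if window < 1:
        raise WalkError("window must be >= 1")
    freq = _corpus_frequencies(corpus)
    if vocabulary is None:
        vocabulary = sorted(freq)
    else:
        missing = set(freq) - set(vocabulary)
        if missing:
            raise VocabularyError(f"corpus vertices missing from vocabulary: {sorted(missing)[:5]}")
    vindex = {v: i for i, v in enumerate(vocabulary)}
    # Huffman leaves only for vertices that occur; map leaf ids to tree order
    tree = build_huffman_tree(freq)
    leaf_of = {it: i for i, it in enumerate(tree.items)}

    targets: list[int] = []
    inputs: list[int] = []
    for walk in corpus.walks:
        idx = [vindex[v] for v in walk]
        leaves = [leaf_of[v] for v in walk]
        L = len(walk)
        for j in range(L):
            lo, hi = max(0, j - window), min(L, j + window + 1)
            for i in range(lo, hi):
                if i == j:
                    continue
                targets.append(leaves[i])
                inputs.append(idx[j])
    targets_arr = np.asarray(targets, dtype=np.int64)
    inputs_arr = np.asarray(inputs, dtype=np.int64)
    offsets = np.arange(len(inputs_arr) + 1, dtype=np.int64)

    # remap: embedding rows are over the full vocabulary; tree leaves over
    # observed vertices only
    emb = train_hs_embeddings(
        n_vocab=len(vocabulary), tree=tree, targets=targets_arr,
        inputs_flat=inputs_arr, input_offsets=offsets,
        sigma=sigma, epochs=epochs, learning_rate=learning_rate, seed=seed,
    )
    return EmbeddingMatrix(list(vocabulary), emb)


def cosine_similarity_matrix(embedding: EmbeddingMatrix) -> np.ndarray:
    """Pairwise cosine similarity Sim[i, j] between embedding rows.

    Symmetric with unit diagonal for nonzero rows; any all-zero row is
    assigned similarity 0 everywhere (logged) since its angle is undefined.
    """
    X = embedding.vectors
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d all-zero embedding row(s); their similarities set to 0", zero.sum())
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    sim = Xn @ Xn.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    return sim
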