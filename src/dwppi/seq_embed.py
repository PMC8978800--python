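"""Attribute embeddings: k-mer tokenization and CBOW word2vec over sequences.

A protein sequence is read as a sentence of overlapping k-mers (stride 1);
CBOW predicts each k-mer from the mean of its context k-mers through the
same Huffman-tree hierarchical softmax used for the graph channel. A
protein's attribute vector pools its k-mer vectors (mean by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import SequenceRecord
from .errors import ConfigError, VocabularyError
from .graph_embed import EmbeddingMatrix
from .hsoftmax import build_huffman_tree, train_hs_embeddings

logger = logging.getLogger(__name__)


def tokenize_kmers(sequence: str, k: int) -> list[str]:
    """Sliding-window k-mers, stride 1: sequence[i:i+k] for i = 0..L-k.

    A length-L sequence yields max(L - k + 1, 0) tokens; shorter-than-k
    sequences yield an empty list (logged). Example with k = 4:
    "MNLLLFFL" -> [MNLL, NLLL, LLLF, LLFF, LFFL].
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        logger.info("sequence of length %d shorter than k=%d: no tokens", len(sequence), k)
        return []
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class KmerCorpus:
    """One k-mer sentence per protein, with the observed vocabulary."""

    protein_ids: list[str]
    sentences: list[list[str]]
    k: int
    vocabulary: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        vocab: dict[str, int] = {}
        for sent in self.sentences:
            for tok in sent:
                vocab[tok] = vocab.get(tok, 0) + 1
        self.vocabulary = vocab

    @classmethod
    def from_records(cls, records: list[SequenceRecord], k: int) -> "KmerCorpus":
        ids = [r.id for r in records]
        sentences = [tokenize_kmers(r.sequence, k) for r in records]
        return cls(ids, sentences, k)


def train_cbow(
    corpus: KmerCorpus,
    window: int,
    sigma: int,
    epochs: int,
    learning_rate: float,
    seed: int,
) -> EmbeddingMatrix:
    """CBOW with hierarchical softmax over the k-mer corpus.

    For each sentence position, the mean of the input vectors of up to
    ``window`` tokens on either side predicts the center token through its
    Huffman path. Returns sigma-dimensional vectors for every observed
    k-mer; deterministic for a fixed seed.
    """
    if not corpus.vocabulary:
        raise VocabularyError("k-mer corpus has an empty vocabulary")
    vocab = sorted(corpus.vocabulary)
    vindex = {t: i for i, t in enumerate(vocab)}
    tree = build_huffman_tree(corpus.vocabulary)
    leaf_of = {it: i for i, it in enumerate(tree.items)}

    targets: list[int] = []
    inputs_flat: list[int] = []
    offsets: list[int] = [0]
    for sent in corpus.sentences:
        idx = [vindex[t] for t in sent]
        L = len(sent)
        for j in range(L):
            lo, hi = max(0, j - window), min(L, j + window + 1)
            ctx = [idx[i] for i in range(lo, hi) if i != j]
            if not ctx:
                continue
            targets.append(leaf_of[sent[j]])
            inputs_flat.extend(ctx)
            offsets.append(offsets[-1] + len(ctx))
    if not targets:
        raise VocabularyError("no CBOW training examples (all sentences too short)")

    emb = train_hs_embeddings(
        n_vocab=len(vocab), tree=tree,
        targets=np.asarray(targets, dtype=np.int64),
        inputs_flat=np.asarray(inputs_flat, dtype=np.int64),
        input_offsets=np.asarray(offsets, dtype=np.int64),
        sigma=sigma, epochs=epochs, learning_rate=learning_rate, seed=seed,
    )
    return EmbeddingMatrix(vocab, emb)


def protein_vector(
    sequence: str, kmer_embeddings: EmbeddingMatrix, k: int, pooling: str = "mean"
) -> np.ndarray:
    """Pool a protein's k-mer vectors into one fixed-length attribute vector.

    Mean pooling by default (sum and max available); out-of-vocabulary
    k-mers are skipped with a log message, and a protein with no in-
    vocabulary k-mers (or a sequence shorter than k) gets the zero vector.
    """
    tokens = tokenize_kmers(sequence, k)
    rows = []
    n_oov = 0
    for t in tokens:
        i = kmer_embeddings.index.get(t)
        if i is None:
            n_oov += 1
        else:
            rows.append(kmer_embeddings.vectors[i])
    if n_oov:
        logger.info("skipped %d out-of-vocabulary k-mer(s)", n_oov)
    if not rows:
        logger.info("no in-vocabulary k-mers; returning zero vector")
        return np.zeros(kmer_embeddings.sigma)
    mat = np.asarray(rows)
    if pooling == "mean":
        return mat.mean(axis=0)
    if pooling == "sum":
        return mat.sum(axis=0)
    if pooling == "max":
        return mat.max(axis=0)
    raise ConfigError(f"unknown pooling {pooling!r}")


def protein_vectors(
    records: list[SequenceRecord],
    kmer_embeddings: EmbeddingMatrix,
    k: int,
    pooling: str = "mean",
) -> EmbeddingMatrix:
    """Attribute vectors for a collection of proteins, as an EmbeddingMatrix."""
    ids = [r.id for r in records]
    mat = np.stack([
        protein_vector(r.sequence, kmer_embeddings, k, pooling) for r in records
    ])
    return EmbeddingMatrix(ids, mat)
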