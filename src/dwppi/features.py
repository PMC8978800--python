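"""Per-protein feature construction and behavior/attribute fusion.

The "behavior" channel embeds each protein by its position in the
interaction network (DeepWalk); the "attribute" channel embeds it by its
sequence (k-mer CBOW). The "multiple" feature concatenates the two, giving
a 2-sigma vector (128-dimensional at the default sigma = 64).
"""

from __future__ import annotations

import numpy as np

from .data_io import RunConfig, SequenceRecord
from .errors import VocabularyError
from .graph_embed import EmbeddingMatrix, generate_walks, train_skipgram
from .network import ProteinGraph
from .seq_embed import KmerCorpus, protein_vectors, train_cbow

MODES = ("behavior", "attribute", "multiple")


def behavior_features(
    graph: ProteinGraph,
    config: RunConfig,
    seed: int,
    train_edges: list[tuple[str, str]] | None = None,
) -> EmbeddingMatrix:
    """DeepWalk node embeddings for every vertex of ``graph``.

    If ``train_edges`` is given, walks run on the subgraph restricted to
    those edges (the leakage-avoiding mode: test-fold positives never shape
    the embedding); vertices isolated in the subgraph keep their
    initialisation-scale rows. Otherwise the full graph is used
    (transductive mode).
    """
    walk_graph = graph if train_edges is None else graph.subgraph_from_edges(train_edges)
    corpus = generate_walks(walk_graph, config.walks_per_node, config.walk_length, seed)
    return train_skipgram(
        corpus,
        window=config.window,
        sigma=config.sigma,
        epochs=config.sg_epochs,
        learning_rate=config.sg_learning_rate,
        seed=seed,
        vocabulary=graph.vertices,
    )


def attribute_features(
    records: list[SequenceRecord], config: RunConfig, seed: int
) -> EmbeddingMatrix:
    """k-mer CBOW embeddings pooled to one vector per protein.

    Uses only the sequences (no interaction labels), so one training per
    dataset suffices regardless of fold structure.
    """
    corpus = KmerCorpus.from_records(records, config.k)
    kmer_emb = train_cbow(
        corpus,
        window=config.cbow_window,
        sigma=config.sigma,
        epochs=config.cbow_epochs,
        learning_rate=config.cbow_learning_rate,
        seed=seed,
    )
    return protein_vectors(records, kmer_emb, config.k, config.pooling)


def fuse_features(
    mode: str,
    behavior: EmbeddingMatrix | None,
    attribute: EmbeddingMatrix | None,
) -> dict[str, np.ndarray]:
    """Per-protein feature table for a given mode.

    behavior / attribute: the single sigma-dimensional channel;
    multiple: behavior ‖ attribute concatenation (2 sigma).
    """
    if mode not in MODES:
        raise VocabularyError(f"unknown feature mode {mode!r}")
    if mode == "behavior":
        assert behavior is not None
        return {p: behavior.vector(p) for p in behavior.vocabulary}
    if mode == "attribute":
        assert attribute is not None
        return {p: attribute.vector(p) for p in attribute.vocabulary}
    assert behavior is not None and attribute is not None
    common = [p for p in behavior.vocabulary if p in attribute.index]
    missing = set(behavior.vocabulary) - set(common)
    if missing:
        raise VocabularyError(
            f"{len(missing)} protein(s) lack sequence features, e.g. {sorted(missing)[:3]}"
        )
    return {p: np.concatenate([behavior.vector(p), attribute.vector(p)]) for p in common}
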