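"""Huffman-tree hierarchical softmax and the shared word2vec-style trainer.

Both embedding channels — skip-gram over random-walk "sentences" of graph
vertices, and CBOW over k-mer "sentences" of protein sequences — maximise
log-likelihoods of the form

    log P(target | h) = sum over the target's Huffman path of
                        log sigmoid(sign_k * <h, psi(b_k)>)

where h is the input projection (a single center vector for skip-gram, the
mean of context vectors for CBOW), psi(b_k) are parameter vectors on the
tree's internal nodes, and sign_k is +1/-1 for a left/right branch. The
per-branch sign makes sibling probabilities complementary, so the leaf
probabilities sum to one — the property that lets a Huffman tree factorise
a softmax over the vocabulary.

The SGD inner loop is JIT-compiled with numba; it is single-threaded and
therefore bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import VocabularyError


@dataclass
class HuffmanTree:
    """Optimal binary prefix tree over a frequency-weighted vocabulary.

    ``paths[i]`` lists the internal-node indices from the root to leaf
    ``i`` and ``signs[i]`` the corresponding branch signs (+1 left child,
    -1 right child). A one-item vocabulary yields an empty path whose
    product is 1 (all probability mass on the single leaf).
    """

    items: list[str]
    frequencies: list[int]
    paths: list[np.ndarray]  # int64 internal-node indices, root first
    signs: list[np.ndarray]  # float64 +1/-1 per branch
    n_inner: int

    def path_length(self, item: str) -> int:
        return len(self.paths[self.items.index(item)])

    def weighted_path_length(self) -> int:
        return int(sum(f * len(p) for f, p in zip(self.frequencies, self.paths)))

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(nodes_flat, signs_flat, offsets) for the numba kernel."""
        offsets = np.zeros(len(self.items) + 1, dtype=np.int64)
        for i, p in enumerate(self.paths):
            offsets[i + 1] = offsets[i] + len(p)
        nodes = np.concatenate(self.paths) if self.items else np.empty(0, np.int64)
        signs = np.concatenate(self.signs) if self.items else np.empty(0, np.float64)
        return nodes.astype(np.int64), signs.astype(np.float64), offsets


def build_huffman_tree(frequencies: dict[str, int]) -> HuffmanTree:
    """Build the Huffman tree for the given item frequencies.

    Ties in the merge queue are broken by (frequency, insertion order),
    with leaves inserted in sorted-ID order before any merged node, so the
    tree is a deterministic function of the frequency table. Raises
    :class:`VocabularyError` on an empty vocabulary or non-positive counts.
    """
    if not frequencies:
        raise VocabularyError("empty vocabulary")
    if any(f <= 0 for f in frequencies.values()):
        raise VocabularyError("all frequencies must be > 0")
    items = sorted(frequencies)
    n = len(items)
    if n == 1:
        return HuffmanTree(items, [frequencies[items[0]]],
                           [np.empty(0, np.int64)], [np.empty(0, np.float64)], 0)

    # heap entries: (freq, tiebreak, node_id); node ids: 0..n-1 leaves,
    # n..2n-2 internal
    heap = [(frequencies[it], i, i) for i, it in enumerate(items)]
    heapq.heapify(heap)
    counter = n
    left = np.full(2 * n - 1, -1, dtype=np.int64)
    right = np.full(2 * n - 1, -1, dtype=np.int64)
    while len(heap) > 1:
        f1, _, a = heapq.heappop(heap)
        f2, _, b = heapq.heappop(heap)
        node = counter
        left[node], right[node] = a, b
        heapq.heappush(heap, (f1 + f2, counter, node))
        counter += 1
    root = heap[0][2]

    # internal nodes renumbered 0..n-2 for the parameter matrix
    inner_index = {node: k for k, node in enumerate(range(n, 2 * n - 1))}
    paths: list[np.ndarray] = [np.empty(0, np.int64)] * n
    signs: list[np.ndarray] = [np.empty(0, np.float64)] * n
    stack: list[tuple[int, list[int], list[float]]] = [(root, [], [])]
    while stack:
        node, p, s = stack.pop()
        if node < n:  # leaf
            paths[node] = np.asarray(p, dtype=np.int64)
            signs[node] = np.asarray(s, dtype=np.float64)
        else:
            k = inner_index[node]
            stack.append((left[node], p + [k], s + [1.0]))
            stack.append((right[node], p + [k], s + [-1.0]))
    return HuffmanTree(items, [frequencies[it] for it in items], paths, signs, n - 1)


def hs_probability(center_vector: np.ndarray, target_item: str, tree: HuffmanTree,
                   inner_vectors: np.ndarray) -> float:
    """P(target | center) under hierarchical softmax.

    Product over the target's root-to-leaf path of
    sigmoid(sign * <center_vector, psi(node)>). ``inner_vectors`` is the
    (n_inner, sigma) parameter matrix psi. Raises
    :class:`VocabularyError` for an unknown target.
    """
    try:
        idx = tree.items.index(target_item)
    except ValueError:
        raise VocabularyError(f"unknown item {target_item!r}") from None
    p = 1.0
    for node, sign in zip(tree.paths[idx], tree.signs[idx]):
        x = sign * float(center_vector @ inner_vectors[node])
        p *= 1.0 / (1.0 + np.exp(-x))
    return float(p)


@njit(cache=True)
def _train_hs_epoch(emb, psi, nodes_flat, signs_flat, path_off,
                    targets, inputs_flat, input_off, order,
                    lr_start, lr_end, step0, total_steps):
    """One epoch of hierarchical-softmax SGD.

    For each example (in ``order``): h = mean of input vectors; walk the
    target's Huffman path accumulating the gradient on h while updating
    psi; then add the accumulated gradient to every input vector (the
    word2vec convention: mean on the forward pass, full gradient to each
    contributor). Learning rate decays linearly over all updates.
    """
    dim = emb.shape[1]
    h = np.empty(dim, dtype=np.float64)
    gh = np.empty(dim, dtype=np.float64)
    for t in range(order.shape[0]):
        ex = order[t]
        step = step0 + t
        alpha = lr_start + (lr_end - lr_start) * (step / max(total_steps - 1, 1))
        i0, i1 = input_off[ex], input_off[ex + 1]
        n_in = i1 - i0
        if n_in == 0:
            continue
        for d in range(dim):
            h[d] = 0.0
            gh[d] = 0.0
        for ii in range(i0, i1):
            w = inputs_flat[ii]
            for d in range(dim):
                h[d] += emb[w, d]
        inv = 1.0 / n_in
        for d in range(dim):
            h[d] *= inv
        tgt = targets[ex]
        p0, p1 = path_off[tgt], path_off[tgt + 1]
        for pp in range(p0, p1):
            node = nodes_flat[pp]
            sign = signs_flat[pp]
            x = 0.0
            for d in range(dim):
                x += h[d] * psi[node, d]
            x *= sign
            f = 1.0 / (1.0 + np.exp(-x))
            g = alpha * sign * (1.0 - f)
            for d in range(dim):
                gh[d] += g * psi[node, d]
                psi[node, d] += g * h[d]
        for ii in range(i0, i1):
            w = inputs_flat[ii]
            for d in range(dim):
                emb[w, d] += gh[d]


def train_hs_embeddings(
    n_vocab: int,
    tree: HuffmanTree,
    targets: np.ndarray,
    inputs_flat: np.ndarray,
    input_offsets: np.ndarray,
    sigma: int,
    epochs: int,
    learning_rate: float,
    seed: int,
) -> np.ndarray:
    """Train input vectors by SGD on the hierarchical-softmax likelihood.

    ``targets[e]`` is the leaf index predicted by example ``e``;
    ``inputs_flat[input_offsets[e]:input_offsets[e+1]]`` are the input-row
    indices averaged to form the projection. Example order is reshuffled
    each epoch with the seeded generator; initialisation follows the
    word2vec convention (uniform in ±0.5/sigma, psi at zero). Returns the
    (n_vocab, sigma) input-embedding matrix. Bit-reproducible for a fixed
    seed.
    """
    if len(targets) == 0:
        raise VocabularyError("no training examples")
    rng = np.random.default_rng(seed)
    emb = (rng.random((n_vocab, sigma)) - 0.5) / sigma
    psi = np.zeros((max(tree.n_inner, 1), sigma), dtype=np.float64)
    nodes_flat, signs_flat, path_off = tree.flat_arrays()
    n_ex = len(targets)
    total = epochs * n_ex
    lr_end = learning_rate * 1e-4
    for ep in range(epochs):
        order = rng.permutation(n_ex).astype(np.int64)
        _train_hs_epoch(
            emb, psi, nodes_flat, signs_flat, path_off,
            targets.astype(np.int64), inputs_flat.astype(np.int64),
            input_offsets.astype(np.int64), order,
            learning_rate, lr_end, ep * n_ex, total,
        )
    return emb
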