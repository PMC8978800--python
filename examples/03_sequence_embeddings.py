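"""Attribute embeddings: k-mer CBOW word2vec over protein sequences.

Each sequence becomes a sentence of overlapping 4-mers; CBOW learns
64-dimensional k-mer vectors, and a protein's attribute vector is the
mean of its k-mer vectors. Proteins sharing implanted motifs (here: same
synthetic block) end up closer than proteins from different blocks.
"""

import numpy as np

from dwppi import RunConfig, SyntheticSpec, tokenize_kmers
from dwppi.features import attribute_features
from dwppi.synthetic import generate_network, generate_sequences

print("4-mers of MNLLLFFL:", tokenize_kmers("MNLLLFFL", 4))

spec = SyntheticSpec(n_proteins=120, seed=7)
_, block = generate_network(spec)
records = generate_sequences(block, spec)
cfg = RunConfig(sigma=32, cbow_epochs=3)

emb = attribute_features(records, cfg, seed=1)
V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
sim = V @ V.T
same, diff = [], []
for i in range(len(V)):
    for j in range(i + 1, len(V)):
        (same if block[emb.vocabulary[i]] == block[emb.vocabulary[j]] else diff).append(sim[i, j])
print(f"{len(records)} proteins -> {emb.sigma}-dim attribute vectors")
print(f"mean cosine, same motif block      : {np.mean(same):+.3f}")
print(f"mean cosine, different motif block : {np.mean(diff):+.3f}")
# Shared k-mer content (the implanted motifs) pulls same-block proteins
# together: the sequence channel carries interaction-relevant signal even
# with the network hidden.
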