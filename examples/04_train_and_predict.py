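"""Train the twin-tower classifier and rank candidate pairs.

Fuses behavior and attribute embeddings into one 2-sigma feature per
protein, trains the pair classifier on the balanced labeled set, then
scores a few held-back candidate pairs (symmetrized, so score(a,b) ==
score(b,a)).
"""

import numpy as np

from dwppi import RunConfig, SyntheticSpec
from dwppi import pair_classifier
from dwppi.features import attribute_features, behavior_features, fuse_features
from dwppi.synthetic import generate_in_memory

spec = SyntheticSpec(n_proteins=120, seed=7)
graph, block, records, labeled = generate_in_memory(spec)
cfg = RunConfig(sigma=32, epochs=40)

feats = fuse_features(
    "multiple",
    behavior_features(graph, cfg, seed=1),
    attribute_features(records, cfg, seed=1),
)
print(f"fused feature dimension: {len(next(iter(feats.values())))}")

# hold back a random 10 pairs of each class for demonstration
rng = np.random.default_rng(3)
pos_idx = [i for i, l in enumerate(labeled.labels) if l == 1]
neg_idx = [i for i, l in enumerate(labeled.labels) if l == 0]
held = set(rng.choice(pos_idx, 10, replace=False)) | set(rng.choice(neg_idx, 10, replace=False))
train_pairs = [p for i, p in enumerate(labeled.pairs) if i not in held]
train_labels = [l for i, l in enumerate(labeled.labels) if i not in held]
demo_pairs = [labeled.pairs[i] for i in sorted(held)]
demo_labels = [labeled.labels[i] for i in sorted(held)]

Xa = np.stack([feats[a] for a, _ in train_pairs])
Xb = np.stack([feats[b] for _, b in train_pairs])
model = pair_classifier.train(Xa, Xb, np.array(train_labels), cfg, seed=2)
print(f"trained {len(model.loss_trace)} epochs; "
      f"loss {model.loss_trace[0]:.3f} -> {model.loss_trace[-1]:.3f}")

scores = pair_classifier.predict_pairs(model, demo_pairs, feats, symmetrize=True)
for (a, b), s, y in zip(demo_pairs[:5], scores[:5], demo_labels[:5]):
    print(f"  {a}-{b}: score {s:.3f} (true label {y})")
mean_pos = scores[np.array(demo_labels) == 1].mean()
mean_neg = scores[np.array(demo_labels) == 0].mean()
print(f"mean score: interacting {mean_pos:.3f} vs non-interacting {mean_neg:.3f}")
# A well-trained model separates the two groups; the score is the
# predicted probability that the pair interacts.
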