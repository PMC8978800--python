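"""Twin-tower deep neural network for scoring protein pairs.

Each protein of a pair enters its own tower of fully connected layers
(batch-norm before a ReLU, dropout after); the tower outputs are
concatenated and passed through further fused ReLU layers; a final affine
map and sigmoid give the interaction probability. Training minimises the
binary cross-entropy with Adam. Everything — forward, backward, batch
normalisation, dropout, Adam — is implemented here in numpy so gradients
are analytic and checkable against finite differences.

Pair order: the two towers have distinct parameters, so score(a, b) and
score(b, a) need not agree. Training randomly swaps pair order per epoch
as augmentation, and prediction can symmetrise by averaging both orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import RunConfig
from .errors import ModelError

logger = logging.getLogger(__name__)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_CLAMP = 1e-12


def build_pair_input(
    protein_a_feature: np.ndarray, protein_b_feature: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the two tower channels for one pair (or a batch).

    Tower 1 receives protein_a's feature, tower 2 protein_b's; both must
    have the same dimension.
    """
    a = np.atleast_2d(np.asarray(protein_a_feature, dtype=np.float64))
    b = np.atleast_2d(np.asarray(protein_b_feature, dtype=np.float64))
    if a.shape != b.shape:
        raise ModelError(f"feature shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy -(1/n) sum [y ln p + (1-y) ln(1-p)].

    Probabilities exactly at 0 or 1 are clamped to [1e-12, 1 - 1e-12]
    (logged) so the loss stays finite; training itself evaluates the loss
    from pre-sigmoid values and never needs the clamp.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ModelError("probabilities and labels differ in length")
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("clamping %d probability value(s) at {0,1}", int(((p <= 0) | (p >= 1)).sum()))
        p = np.clip(p, _CLAMP, 1 - _CLAMP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stage_specs(input_dim: int, cfg: RunConfig) -> dict[str, list[tuple[int, int]]]:
    """Layer (fan_in, fan_out) shapes for towers, fused stage and output."""
    towers = []
    d = input_dim
    for w in cfg.tower_widths:
        towers.append((d, w))
        d = w
    fused = []
    d = 2 * cfg.tower_widths[-1]
    for w in cfg.fused_widths:
        fused.append((d, w))
        d = w
    return {"tower": towers, "fused": fused, "out": [(d, 1)]}


@dataclass
class DNNModel:
    """Parameters and running batch-norm statistics of the pair classifier."""

    input_dim: int
    config: RunConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)
    running: dict[str, np.ndarray] = field(default_factory=dict)
    loss_trace: list[float] = field(default_factory=list)

    @property
    def dtype(self):
        return np.float32 if self.config.precision == "float32" else np.float64

    @classmethod
    def initialize(cls, input_dim: int, config: RunConfig, seed: int) -> "DNNModel":
        """He-initialised weights, zero biases, unit batch-norm scale."""
        rng = np.random.default_rng(seed)
        model = cls(input_dim, config)
        specs = _stage_specs(input_dim, config)
        tower_prefixes = ["t0"] if config.share_towers else ["t0", "t1"]
        for pref in tower_prefixes:
            for l, (fi, fo) in enumerate(specs["tower"]):
                model._init_block(rng, f"{pref}_{l}", fi, fo, batchnorm=True)
        for l, (fi, fo) in enumerate(specs["fused"]):
            model._init_block(rng, f"fu_{l}", fi, fo, batchnorm=True)
        (fi, fo), = specs["out"]
        model._init_block(rng, "out", fi, fo, batchnorm=False)
        return model

    def _init_block(self, rng, name: str, fan_in: int, fan_out: int, batchnorm: bool) -> None:
        dt = self.dtype
        self.params[f"{name}_W"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)).astype(dt)
        self.params[f"{name}_b"] = np.zeros(fan_out, dtype=dt)
        if batchnorm:
            self.params[f"{name}_g"] = np.ones(fan_out, dtype=dt)
            self.params[f"{name}_B"] = np.zeros(fan_out, dtype=dt)
            self.running[f"{name}_mu"] = np.zeros(fan_out, dtype=dt)
            self.running[f"{name}_var"] = np.ones(fan_out, dtype=dt)

    def tower_prefix(self, m: int) -> str:
        return "t0" if self.config.share_towers else f"t{m}"

    # ------------------------------------------------------------------ forward

    def _block_forward(self, name, X, training, update_running, mask):
        """Linear -> batch-norm -> ReLU -> dropout. Returns output + cache."""
        W, b = self.params[f"{name}_W"], self.params[f"{name}_b"]
        Z = X @ W + b
        g, B = self.params[f"{name}_g"], self.params[f"{name}_B"]
        if training:
            mu = Z.mean(axis=0)
            var = Z.var(axis=0)
            if update_running:
                self.running[f"{name}_mu"] = (
                    _BN_MOMENTUM * self.running[f"{name}_mu"] + (1 - _BN_MOMENTUM) * mu
                )
                self.running[f"{name}_var"] = (
                    _BN_MOMENTUM * self.running[f"{name}_var"] + (1 - _BN_MOMENTUM) * var
                )
        else:
            mu = self.running[f"{name}_mu"]
            var = self.running[f"{name}_var"]
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        Zh = (Z - mu) * inv
        Y = g * Zh + B
        A = np.maximum(Y, 0.0)
        if mask is not None:
            A = A * mask
        if not np.all(np.isfinite(A)):
            raise ModelError(f"non-finite activations in layer {name}")
        cache = (X, W, Z, Zh, inv, g, Y, mask, training)
        return A, cache

    def forward(
        self,
        Xa: np.ndarray,
        Xb: np.ndarray,
        training: bool = False,
        masks: dict[str, np.ndarray] | None = None,
        update_running: bool = False,
    ) -> tuple[np.ndarray, dict]:
        """Batch forward pass; returns probabilities in (0, 1) and caches.

        ``masks`` are inverted-dropout masks keyed by block name; omit them
        (or run with ``training=False``) for the deterministic network.
        """
        Xa, Xb = build_pair_input(Xa, Xb)
        if Xa.shape[1] != self.input_dim:
            raise ModelError(f"expected input dim {self.input_dim}, got {Xa.shape[1]}")
        Xa = Xa.astype(self.dtype, copy=False)
        Xb = Xb.astype(self.dtype, copy=False)
        masks = masks or {}
        caches: dict = {"blocks": {}}
        outs = []
        for m, X in enumerate((Xa, Xb)):
            pref = self.tower_prefix(m)
            H = X
            for l in range(len(self.config.tower_widths)):
                name = f"{pref}_{l}"
                H, c = self._block_forward(
                    name, H, training, update_running, masks.get(f"m{m}_{name}")
                )
                caches["blocks"][f"m{m}_{name}"] = c
            outs.append(H)
        H = np.concatenate(outs, axis=1)
        for l in range(len(self.config.fused_widths)):
            name = f"fu_{l}"
            H, c = self._block_forward(name, H, training, update_running, masks.get(name))
            caches["blocks"][name] = c
        W, b = self.params["out_W"], self.params["out_b"]
        logits = (H @ W + b).ravel()
        caches["out"] = (H, W)
        caches["logits"] = logits
        p = 1.0 / (1.0 + np.exp(-logits))
        return p, caches

    # ----------------------------------------------------------------- backward

    @staticmethod
    def _block_backward(cache, dA, grads, name):
        X, W, Z, Zh, inv, g, Y, mask, training = cache
        if mask is not None:
            dA = dA * mask
        dY = dA * (Y > 0)
        grads[f"{name}_g"] = (dY * Zh).sum(axis=0)
        grads[f"{name}_B"] = dY.sum(axis=0)
        dZh = dY * g
        if training:
            n = Z.shape[0]
            # batch statistics depend on Z: full batch-norm backward
            dZ = (inv / n) * (n * dZh - dZh.sum(axis=0) - Zh * (dZh * Zh).sum(axis=0))
        else:
            dZ = dZh * inv
        grads[f"{name}_W"] = X.T @ dZ
        grads[f"{name}_b"] = dZ.sum(axis=0)
        return dZ @ W.T

    def loss_and_grads(
        self,
        Xa: np.ndarray,
        Xb: np.ndarray,
        labels: np.ndarray,
        masks: dict[str, np.ndarray] | None = None,
        training: bool = True,
        update_running: bool = False,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy loss and analytic parameter gradients.

        The loss is evaluated from logits (log1p of the exponential) so no
        probability clamping is ever needed during optimisation.
        """
        y = np.asarray(labels, dtype=self.dtype).ravel()
        p, caches = self.forward(Xa, Xb, training=training, masks=masks,
                                 update_running=update_running)
        z = caches["logits"]
        n = len(y)
        # log-space BCE: max(z,0) - z*y + log(1+exp(-|z|))
        loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        grads: dict[str, np.ndarray] = {}
        dlogits = (p - y) / n
        H, W = caches["out"]
        grads["out_W"] = H.T @ dlogits[:, None]
        grads["out_b"] = np.array([dlogits.sum()])
        dH = dlogits[:, None] @ W.T
        for l in reversed(range(len(self.config.fused_widths))):
            name = f"fu_{l}"
            dH = self._block_backward(caches["blocks"][name], dH, grads, name)
        half = self.config.tower_widths[-1]
        dTow = [dH[:, :half], dH[:, half:]]
        if self.config.share_towers:
            # both channels contribute to the same parameters: sum their grads
            grads = self._shared_tower_grads(caches, dTow, grads)
        else:
            for m in (0, 1):
                pref = self.tower_prefix(m)
                d = dTow[m]
                for l in reversed(range(len(self.config.tower_widths))):
                    name = f"{pref}_{l}"
                    d = self._block_backward(caches["blocks"][f"m{m}_{name}"], d, grads, name)
        return loss, grads

    def _shared_tower_grads(self, caches, dTow, grads):
        """Accumulate per-channel gradients onto the shared tower weights."""
        n_layers = len(self.config.tower_widths)
        acc: dict[str, np.ndarray] = {}
        for m in (0, 1):
            d = dTow[m]
            for l in reversed(range(n_layers)):
                name = f"t0_{l}"
                tmp: dict[str, np.ndarray] = {}
                d = self._block_backward(caches["blocks"][f"m{m}_{name}"], d, tmp, name)
                for k, v in tmp.items():
                    acc[k] = acc.get(k, 0) + v
        grads.update(acc)
        return grads

    # ---------------------------------------------------------------- inference

    def predict(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities (no dropout, running BN stats)."""
        p, _ = self.forward(Xa, Xb, training=False)
        return p

    # -------------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Self-describing checkpoint: parameters + BN stats + config."""
        import json
        from pathlib import Path

        arrays = {f"p_{k}": v for k, v in self.params.items()}
        arrays |= {f"r_{k}": v for k, v in self.running.items()}
        np.savez(Path(path), **arrays)
        meta = {"input_dim": self.input_dim, "config": self.config.to_dict(),
                "loss_trace": self.loss_trace}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "DNNModel":
        import json
        from pathlib import Path

        meta = json.loads(Path(str(path) + ".json").read_text())
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        model = cls(meta["input_dim"], RunConfig.from_dict(meta["config"]))
        model.loss_trace = list(meta.get("loss_trace", []))
        for k in data.files:
            if k.startswith("p_"):
                model.params[k[2:]] = data[k]
            elif k.startswith("r_"):
                model.running[k[2:]] = data[k]
        return model


def _make_masks(model: DNNModel, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    r = model.config.dropout
    if r == 0:
        return {}
    masks = {}
    dt = model.dtype
    keep = np.float32(1 / (1 - r)) if dt == np.float32 else 1 / (1 - r)
    draw = (lambda s: rng.random(s, dtype=np.float32)) if dt == np.float32 else rng.random
    for m in (0, 1):
        pref = model.tower_prefix(m)
        for l, w in enumerate(model.config.tower_widths):
            masks[f"m{m}_{pref}_{l}"] = (draw((n, w)) >= r) * keep
    for l, w in enumerate(model.config.fused_widths):
        masks[f"fu_{l}"] = (draw((n, w)) >= r) * keep
    return masks


def train(
    Xa: np.ndarray,
    Xb: np.ndarray,
    labels: np.ndarray,
    config: RunConfig,
    seed: int,
) -> DNNModel:
    """Train the twin-tower classifier with Adam, dropout and batch-norm.

    A ``val_fraction`` split is held out for early stopping (patience in
    epochs, best parameters restored). Pair order is randomly swapped per
    sample per epoch as augmentation. Initialisation, shuffling, dropout
    masks and the swap are all driven by one seeded generator, so two runs
    with the same seed produce identical loss traces and parameters.
    Raises :class:`ModelError` if only one class is present.
    """
    dt = np.float32 if config.precision == "float32" else np.float64
    y = np.asarray(labels, dtype=dt).ravel()
    Xa = np.asarray(Xa, dtype=dt)
    Xb = np.asarray(Xb, dtype=dt)
    if len(np.unique(y)) < 2:
        raise ModelError("training set contains a single class")
    rng = np.random.default_rng(seed)
    model = DNNModel.initialize(Xa.shape[1], config, seed=int(rng.integers(2**31)))

    n = len(y)
    n_val = max(1, int(round(config.val_fraction * n))) if config.patience else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if n_val and (len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[val_idx])) < 2):
        # tiny or skewed data: fall back to training on everything
        tr_idx, val_idx = perm, perm[:0]
        n_val = 0

    # Adam state
    m_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = None
    best_running = None
    patience_left = config.patience

    for epoch in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        swap = rng.random(len(tr_idx)) < 0.5
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            sel = tr_idx[order[start : start + config.batch_size]]
            sw = swap[order[start : start + config.batch_size]]
            A = np.where(sw[:, None], Xb[sel], Xa[sel])
            B = np.where(sw[:, None], Xa[sel], Xb[sel])
            if len(sel) < 2:
                continue  # batch-norm needs >= 2 samples
            masks = _make_masks(model, len(sel), rng)
            loss, grads = model.loss_and_grads(A, B, y[sel], masks=masks,
                                               training=True, update_running=True)
            epoch_losses.append(loss)
            step += 1
            for k, g in grads.items():
                m_t[k] = b1 * m_t[k] + (1 - b1) * g
                v_t[k] = b2 * v_t[k] + (1 - b2) * g * g
                mhat = m_t[k] / (1 - b1**step)
                vhat = v_t[k] / (1 - b2**step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.loss_trace.append(float(np.mean(epoch_losses)))
        if n_val:
            p_val = model.predict(Xa[val_idx], Xb[val_idx])
            val_loss = cross_entropy_loss(p_val, y[val_idx])
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                best_running = {k: v.copy() for k, v in model.running.items()}
                patience_left = config.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_params is not None:
        model.params = best_params
        model.running = best_running
    return model


def predict_pairs(
    model: DNNModel,
    pairs: list[tuple[str, str]],
    features: dict[str, np.ndarray],
    symmetrize: bool = True,
) -> np.ndarray:
    """Score pairs by protein ID using a per-protein feature table.

    With ``symmetrize`` the score is the mean of forward(a, b) and
    forward(b, a), making the prediction order-invariant. Raises
    :class:`ModelError` naming any protein without a feature vector.
    """
    for a, b in pairs:
        for pid in (a, b):
            if pid not in features:
                raise ModelError(f"no feature vector for protein {pid!r}")
    Xa = np.stack([features[a] for a, _ in pairs])
    Xb = np.stack([features[b] for _, b in pairs])
    scores = model.predict(Xa, Xb)
    if symmetrize:
        scores = 0.5 * (scores + model.predict(Xb, Xa))
    return scores
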