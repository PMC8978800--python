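import numpy as np
import pytest

from dwppi import pair_classifier as pc
from dwppi.data_io import RunConfig
from dwppi.errors import ModelError


def grad_check_config(**kw):
    base = dict(tower_widths=(8, 8), fused_widths=(4,), dropout=0.5,
                precision="float64")
    base.update(kw)
    return RunConfig(**base)


def fixed_masks(model, n, rng):
    r = model.config.dropout
    if r == 0:
        return {}
    masks = {}
    for m in (0, 1):
        pref = model.tower_prefix(m)
        for l, w in enumerate(model.config.tower_widths):
            masks[f"m{m}_{pref}_{l}"] = (rng.random((n, w)) >= r) / (1 - r)
    for l, w in enumerate(model.config.fused_widths):
        masks[f"fu_{l}"] = (rng.random((n, w)) >= r) / (1 - r)
    return masks


def max_gradient_error(model, Xa, Xb, y, masks, eps=1e-6):
    """Worst relative error of analytic vs central-difference gradients.

    Parameters whose analytic gradient is ~0 (e.g. a linear bias ahead of
    batch-norm, which cancels exactly in the normalisation) are compared
    absolutely, since a relative error on rounding noise is meaningless.
    """
    _, grads = model.loss_and_grads(Xa, Xb, y, masks=masks, training=True)
    worst = 0.0
    for k, P in model.params.items():
        G = grads[k]
        it = np.nditer(P, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            old = P[idx]
            P[idx] = old + eps
            lp, _ = model.loss_and_grads(Xa, Xb, y, masks=masks, training=True)
            P[idx] = old - eps
            lm, _ = model.loss_and_grads(Xa, Xb, y, masks=masks, training=True)
            P[idx] = old
            fd = (lp - lm) / (2 * eps)
            # 1e-9 absolute floor: FD itself is only accurate to ~1e-10
            err = max(abs(fd - G[idx]) - 1e-9, 0.0)
            worst = max(worst, err / (abs(fd) + abs(G[idx]) + 1e-30))
            it.iternext()
    return worst


class TestBuildPairInput:
    def test_channels(self, rng):
        a, b = rng.normal(size=(3, 16)), rng.normal(size=(3, 16))
        A, B = pc.build_pair_input(a, b)
        assert np.array_equal(A, a) and np.array_equal(B, b)
        A2, B2 = pc.build_pair_input(b, a)
        assert np.array_equal(A2, b) and np.array_equal(B2, a)

    def test_mismatch_raises(self, rng):
        with pytest.raises(ModelError):
            pc.build_pair_input(rng.normal(size=(3, 16)), rng.normal(size=(3, 8)))


class TestForward:
    def test_zero_model_outputs_half(self, rng):
        cfg = grad_check_config(dropout=0.0)
        model = pc.DNNModel.initialize(8, cfg, seed=0)
        for k in model.params:
            model.params[k][:] = 0.0
        p = model.predict(rng.normal(size=(5, 8)), rng.normal(size=(5, 8)))
        assert np.allclose(p, 0.5)

    def test_output_strictly_in_unit_interval(self, rng):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.0), seed=1)
        p = model.predict(rng.normal(size=(20, 8)), rng.normal(size=(20, 8)))
        assert np.all((p > 0) & (p < 1))

    def test_eval_mode_deterministic_despite_dropout(self, rng):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.5), seed=1)
        Xa, Xb = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        assert np.array_equal(model.predict(Xa, Xb), model.predict(Xa, Xb))


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Backprop through linear, batch-norm (training mode), ReLU and
        dropout layers agrees with central differences."""
        cfg = grad_check_config()
        model = pc.DNNModel.initialize(8, cfg, seed=3)
        Xa, Xb = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        y = rng.integers(0, 2, size=6).astype(float)
        masks = fixed_masks(model, 6, rng)
        assert max_gradient_error(model, Xa, Xb, y, masks) < 1e-5

    def test_shared_tower_gradients(self, rng):
        cfg = grad_check_config(share_towers=True, dropout=0.0)
        model = pc.DNNModel.initialize(8, cfg, seed=3)
        Xa, Xb = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        y = rng.integers(0, 2, size=6).astype(float)
        assert max_gradient_error(model, Xa, Xb, y, {}) < 1e-5

    def test_loss_order_invariance(self, rng):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.0), seed=2)
        Xa, Xb = rng.normal(size=(10, 8)), rng.normal(size=(10, 8))
        y = rng.integers(0, 2, size=10).astype(float)
        l1, _ = model.loss_and_grads(Xa, Xb, y, training=False)
        perm = rng.permutation(10)
        l2, _ = model.loss_and_grads(Xa[perm], Xb[perm], y[perm], training=False)
        assert l1 == pytest.approx(l2, rel=1e-12)


class TestCrossEntropy:
    def test_half_probability(self):
        assert pc.cross_entropy_loss(np.array([0.5]), np.array([1])) == pytest.approx(
            0.69314718, abs=1e-8
        )

    def test_symmetric_average(self):
        loss = pc.cross_entropy_loss(np.array([0.5, 0.5]), np.array([1, 0]))
        assert loss == pytest.approx(0.69314718, abs=1e-8)

    def test_direct_evaluation(self):
        loss = pc.cross_entropy_loss(np.array([0.9, 0.2]), np.array([1, 0]))
        assert loss == pytest.approx(0.16425203, abs=1e-7)

    def test_clamping_keeps_finite(self):
        loss = pc.cross_entropy_loss(np.array([1.0, 0.0]), np.array([1, 0]))
        assert np.isfinite(loss)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(10)
    n, d = 400, 16
    y = rng.integers(0, 2, size=n).astype(float)
    mu = np.where(y[:, None] == 1, 1.0, -1.0)
    Xa = rng.normal(size=(n, d)) * 0.5 + mu
    Xb = rng.normal(size=(n, d)) * 0.5 + mu
    return Xa, Xb, y


class TestTrain:
    def test_separable_data_high_accuracy(self, separable):
        Xa, Xb, y = separable
        cfg = RunConfig(tower_widths=(16, 8), fused_widths=(8,), epochs=50,
                        batch_size=64, patience=0)
        model = pc.train(Xa, Xb, y, cfg, seed=2)
        acc = ((model.predict(Xa, Xb) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_loss_decreases(self, separable):
        Xa, Xb, y = separable
        cfg = RunConfig(tower_widths=(16, 8), fused_widths=(8,), epochs=50,
                        batch_size=64, patience=0)
        model = pc.train(Xa, Xb, y, cfg, seed=2)
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_seed_determinism(self, separable):
        Xa, Xb, y = separable
        cfg = RunConfig(tower_widths=(16,), fused_widths=(8,), epochs=5,
                        batch_size=64, patience=0)
        m1 = pc.train(Xa, Xb, y, cfg, seed=4)
        m2 = pc.train(Xa, Xb, y, cfg, seed=4)
        assert m1.loss_trace == m2.loss_trace
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ModelError):
            pc.train(X, X, np.ones(10), RunConfig(tower_widths=(4,), fused_widths=(4,)), 0)


class TestPredictPairs:
    def test_symmetrize_order_invariant(self, rng):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.0), seed=5)
        feats = {f"p{i}": rng.normal(size=8) for i in range(6)}
        s1 = pc.predict_pairs(model, [("p0", "p1"), ("p2", "p3")], feats, symmetrize=True)
        s2 = pc.predict_pairs(model, [("p1", "p0"), ("p3", "p2")], feats, symmetrize=True)
        assert np.allclose(s1, s2)

    def test_unknown_protein_named(self, rng):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.0), seed=5)
        with pytest.raises(ModelError, match="ghost"):
            pc.predict_pairs(model, [("p0", "ghost")], {"p0": np.zeros(8)}, True)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = pc.DNNModel.initialize(8, grad_check_config(dropout=0.0), seed=5)
        model.save(tmp_path / "m")
        back = pc.DNNModel.load(tmp_path / "m")
        Xa, Xb = rng.normal(size=(4, 8)), rng.normal(size=(4, 8))
        assert np.array_equal(model.predict(Xa, Xb), back.predict(Xa, Xb))
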