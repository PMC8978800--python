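import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from dwppi import evaluation as ev
from dwppi.errors import EvaluationError


def brute_force_auc(labels, scores):
    """Exhaustive positive-negative pair counting, ties as 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_basic(self):
        t = ev.confusion([1, 0], [0.9, 0.1], 0.5)
        assert (t.TP, t.TN, t.FP, t.FN) == (1, 1, 0, 0)

    def test_all_positive_predictions(self):
        labels = [1, 1, 0, 0]
        t = ev.confusion(labels, [0.7] * 4, 0.5)
        assert t.FP == 2 and t.FN == 0

    def test_threshold_boundary_counts_positive(self):
        t = ev.confusion([1], [0.5], 0.5)
        assert t.TP == 1

    def test_empty_raises(self):
        with pytest.raises(EvaluationError):
            ev.confusion([], [], 0.5)


class TestMetrics:
    def test_perfect_classifier(self):
        m = ev.metrics(ev.ConfusionTable(50, 50, 0, 0))
        assert all(m[k] == 1 for k in ("ACC", "Sen", "Spec", "PR", "MCC"))

    def test_degenerate_all_positive_predictions(self):
        m = ev.metrics(ev.ConfusionTable(TP=50, TN=0, FP=50, FN=0))
        assert m["ACC"] == 0.5 and m["Sen"] == 1 and m["Spec"] == 0
        assert m["MCC"] == 0.0  # zero denominator convention

    def test_hand_computed_contingency(self):
        m = ev.metrics(ev.ConfusionTable(TP=40, TN=35, FP=15, FN=10))
        assert m["ACC"] == pytest.approx(0.75)
        assert m["Sen"] == pytest.approx(0.8)
        assert m["Spec"] == pytest.approx(0.7)
        assert m["PR"] == pytest.approx(0.727273, abs=1e-6)
        assert m["MCC"] == pytest.approx(0.502519, abs=1e-6)

    def test_balanced_identity_acc_is_mean_of_sen_spec(self, rng):
        for _ in range(20):
            n = 40
            labels = np.array([1] * n + [0] * n)
            scores = rng.random(2 * n)
            m = ev.metrics(ev.confusion(labels, scores, 0.5))
            assert m["ACC"] == pytest.approx((m["Sen"] + m["Spec"]) / 2, abs=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_worked_example(self):
        assert ev.auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert ev.auc([1, 0, 1, 0], [0.5] * 4) == pytest.approx(0.5)

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            ours = ev.auc(labels, scores)
            assert ours == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            ev.auc([1, 1], [0.2, 0.3])

    def test_permutation_null_centers_at_half(self, rng):
        aucs = []
        for _ in range(100):
            labels = rng.permutation([1] * 25 + [0] * 25)
            aucs.append(ev.auc(labels, rng.random(50)))
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestKfold:
    def test_even_split(self):
        a = ev.kfold_split(10, 5, seed=0, labels=[0, 1] * 5)
        assert sorted(np.bincount(a)) == [2, 2, 2, 2, 2]

    def test_uneven_split(self):
        a = ev.kfold_split(11, 5, seed=0, labels=[0, 1] * 5 + [0])
        assert sorted(np.bincount(a)) == [2, 2, 2, 2, 3]

    def test_deterministic(self):
        labels = [0, 1] * 20
        assert np.array_equal(
            ev.kfold_split(40, 5, 3, labels), ev.kfold_split(40, 5, 3, labels)
        )

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, size=53)
        a = ev.kfold_split(53, 5, 1, labels)
        assert set(a) == set(range(5))
        assert len(a) == 53  # exhaustive and disjoint by construction

    def test_stratified_keeps_both_classes(self):
        labels = [1] * 6 + [0] * 6
        a = ev.kfold_split(12, 3, 0, labels, stratified=True)
        for fold in range(3):
            fold_labels = [labels[i] for i in np.flatnonzero(a == fold)]
            assert 0 in fold_labels and 1 in fold_labels

    def test_too_few_pairs_raises(self):
        with pytest.raises(EvaluationError):
            ev.kfold_split(3, 5, 0)


@pytest.fixture(scope="module")
def reports(small_dataset, fast_config):
    graph, _, records, labeled = small_dataset
    cache = {}
    out = {}
    for clf in ("dnn", "lr"):
        out[clf] = ev.cross_validate(
            graph, records, labeled.pairs, labeled.labels, fast_config,
            seed=3, mode="multiple", classifier=clf, transductive=True,
            _cache=cache,
        )
    return out


class TestCrossValidateSmall:
    """End-to-end harness behaviour on the miniature dataset."""

    def test_fold_count_and_summary_consistency(self, reports):
        rep = reports["dnn"]
        assert len(rep.per_fold) == 3
        aucs = [f["AUC"] for f in rep.per_fold]
        assert rep.mean["AUC"] == pytest.approx(np.mean(aucs))
        assert rep.sd["AUC"] == pytest.approx(np.std(aucs, ddof=1))

    def test_report_metadata(self, reports):
        assert reports["dnn"].classifier == "dnn"
        assert reports["lr"].classifier == "lr"
        assert reports["dnn"].mode == "multiple"

    def test_shared_cache_gives_identical_folds(self, small_dataset, fast_config):
        graph, _, records, labeled = small_dataset
        c1, c2 = {}, {}
        ev.cross_validate(graph, records, labeled.pairs, labeled.labels,
                          fast_config, seed=9, mode="attribute", classifier="lr",
                          _cache=c1)
        ev.cross_validate(graph, records, labeled.pairs, labeled.labels,
                          fast_config, seed=9, mode="attribute", classifier="dt",
                          _cache=c2)
        assert np.array_equal(c1["folds"], c2["folds"])

    def test_multiple_mode_dimension_is_sum_of_channels(self, small_dataset, fast_config):
        from dwppi.features import attribute_features, behavior_features, fuse_features

        graph, _, records, _ = small_dataset
        b = behavior_features(graph, fast_config, 1)
        a = attribute_features(records, fast_config, 1)
        fused = fuse_features("multiple", b, a)
        some = next(iter(fused.values()))
        assert some.shape[0] == b.sigma + a.sigma

    def test_lr_beats_chance_on_separable_features(self, rng):
        # sanity oracle: LR on linearly separable pair features
        n, d = 300, 8
        y = rng.integers(0, 2, size=n)
        feats = {}
        pairs = []
        for i in range(n):
            feats[f"a{i}"] = rng.normal(size=d) + (2.0 if y[i] else -2.0)
            feats[f"b{i}"] = rng.normal(size=d) + (2.0 if y[i] else -2.0)
            pairs.append((f"a{i}", f"b{i}"))
        from sklearn.linear_model import LogisticRegression

        X = np.array([np.concatenate([feats[a], feats[b]]) for a, b in pairs])
        clf = LogisticRegression(max_iter=1000).fit(X[:200], y[:200])
        assert ev.auc(y[200:], clf.predict_proba(X[200:])[:, 1]) > 0.9
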