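"""Classification metrics, ROC/AUC, and the 5-fold cross-validation harness.

Reported metrics follow the usual confusion-matrix definitions:

    ACC  = (TP + TN) / N            Sen = TP / (TP + FN)
    Spec = TN / (TN + FP)           PR  = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is computed in the rank (Mann-Whitney) formulation — the probability
that a random positive outscores a random negative, ties counted 1/2 —
which equals trapezoidal integration of the ROC curve.

The harness runs the full pipeline per fold: DeepWalk behavior embeddings
are retrained on the training fold's positive edges (avoiding test-edge
leakage; a transductive option embeds the whole network once, which is how
such pipelines are often run in practice), attribute embeddings are
sequence-only and trained once, and the chosen classifier (twin-tower DNN,
logistic regression, or decision tree) is trained and scored per fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import pair_classifier
from .data_io import RunConfig, SequenceRecord
from .errors import EvaluationError
from .features import MODES, attribute_features, behavior_features, fuse_features
from .network import ProteinGraph

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "Sen", "Spec", "PR", "MCC", "AUC")
CLASSIFIERS = ("dnn", "lr", "dt")


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionTable:
    """Tally the confusion table at a decision threshold.

    A score exactly at the threshold counts as a positive prediction.
    """
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size == 0:
        raise EvaluationError("empty input")
    if y.size != s.size:
        raise EvaluationError("labels and scores differ in length")
    pred = s >= threshold
    pos = y == 1
    return ConfusionTable(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(table: ConfusionTable) -> dict[str, float | None]:
    """ACC, Sen, Spec, PR and MCC from a confusion table.

    A metric whose denominator is zero is reported as None (missing) and
    logged; MCC with a zero denominator is reported as 0 by the usual
    convention (also logged).
    """
    tp, tn, fp, fn = table.TP, table.TN, table.FP, table.FN
    n = table.total
    if n == 0:
        raise EvaluationError("empty confusion table")

    def ratio(num, den, name):
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as missing", name)
            return None
        return num / den

    out: dict[str, float | None] = {
        "ACC": (tp + tn) / n,
        "Sen": ratio(tp, tp + fn, "Sen"),
        "Spec": ratio(tn, tn + fp, "Spec"),
        "PR": ratio(tp, tp + fp, "PR"),
    }
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        logger.warning("MCC denominator zero; reported as 0 by convention")
        out["MCC"] = 0.0
    else:
        out["MCC"] = (tp * tn - fp * fn) / float(np.sqrt(denom2))
    return out


def auc(labels, scores) -> float:
    """Rank-based AUC (Mann-Whitney U / (n_pos * n_neg), ties as 1/2)."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve_points(labels, scores) -> pd.DataFrame:
    """FPR/TPR coordinates at every distinct threshold (for plotting)."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    n_pos, n_neg = tps[-1], fps[-1]
    tpr = np.concatenate([[0], tps / max(n_pos, 1)])
    fpr = np.concatenate([[0], fps / max(n_neg, 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def precision_recall_points(labels, scores) -> pd.DataFrame:
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tps = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    return pd.DataFrame({"recall": tps / max(tps[-1], 1), "precision": tps / k})


def kfold_split(
    n_pairs: int, k: int, seed: int, labels=None, stratified: bool = True
) -> np.ndarray:
    """Assign each pair a fold index in 0..k-1 (sizes differ by <= 1).

    Stratified by label when labels are given (the default protocol, so
    every fold holds both classes even at small n); plain randomised
    K-fold otherwise. Deterministic for a fixed seed.
    """
    if n_pairs < k:
        raise EvaluationError(f"cannot split {n_pairs} pairs into {k} folds")
    assignment = np.empty(n_pairs, dtype=int)
    if stratified and labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        idx = splitter.split(np.zeros(n_pairs), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        idx = splitter.split(np.zeros(n_pairs))
    for fold, (_, test_idx) in enumerate(idx):
        assignment[test_idx] = fold
    return assignment


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and sample standard deviation."""

    mode: str
    classifier: str
    per_fold: list[dict[str, float | None]]
    metadata: dict = field(default_factory=dict)

    def _values(self, name: str) -> list[float]:
        return [f[name] for f in self.per_fold if f.get(name) is not None]

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(np.mean(self._values(m))) for m in METRIC_NAMES if self._values(m)}

    @property
    def sd(self) -> dict[str, float]:
        return {
            m: float(np.std(self._values(m), ddof=1)) if len(self._values(m)) > 1 else 0.0
            for m in METRIC_NAMES
            if self._values(m)
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-fold rows plus a mean ± SD summary row."""
        rows = []
        for i, f in enumerate(self.per_fold, start=1):
            rows.append({"testing_set": str(i), **{m: f.get(m) for m in METRIC_NAMES}})
        mean, sd = self.mean, self.sd
        rows.append(
            {
                "testing_set": "Average",
                **{m: f"{mean[m]:.4f} ± {sd[m]:.4f}" for m in mean},
            }
        )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "classifier": self.classifier,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _fold_seed(seed: int, tag: int) -> int:
    return int((seed * 1_000_003 + tag) % (2**31 - 1))


def _pair_matrix(pairs, features) -> tuple[np.ndarray, np.ndarray]:
    Xa = np.stack([features[a] for a, _ in pairs])
    Xb = np.stack([features[b] for _, b in pairs])
    return Xa, Xb


def _fit_and_score(classifier, config, seed, train_pairs, train_labels,
                   test_pairs, features) -> np.ndarray:
    if classifier == "dnn":
        Xa, Xb = _pair_matrix(train_pairs, features)
        model = pair_classifier.train(Xa, Xb, np.asarray(train_labels), config, seed)
        return pair_classifier.predict_pairs(model, test_pairs, features, config.symmetrize)
    Xtr = np.hstack(_pair_matrix(train_pairs, features))
    Xte = np.hstack(_pair_matrix(test_pairs, features))
    if classifier == "lr":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif classifier == "dt":
        clf = DecisionTreeClassifier(random_state=seed)
    else:
        raise EvaluationError(f"unknown classifier {classifier!r}")
    clf.fit(Xtr, np.asarray(train_labels))
    return clf.predict_proba(Xte)[:, 1]


def cross_validate(
    graph: ProteinGraph,
    records: list[SequenceRecord] | None,
    pairs: list[tuple[str, str]],
    labels: list[int],
    config: RunConfig,
    seed: int,
    mode: str = "multiple",
    classifier: str = "dnn",
    transductive: bool | None = None,
    _cache: dict | None = None,
) -> MetricsReport:
    """K-fold cross-validated evaluation of the full pipeline.

    Folds are stratified by label (configurable); for each fold, behavior
    embeddings are trained on the training fold's positive edges (or once
    on the full network when ``transductive``), attribute embeddings once
    on the sequences, features fused per ``mode``, the ``classifier``
    trained on the training pairs and scored on the held-out pairs. The
    report mirrors the per-fold-rows-plus-average layout used for such
    experiments. Passing the same ``_cache`` dict across calls with the
    same graph/seed reuses fold splits and embeddings (the fold split is
    shared across classifiers for a given seed by construction).
    """
    if mode not in MODES:
        raise EvaluationError(f"unknown mode {mode!r}")
    if classifier not in CLASSIFIERS:
        raise EvaluationError(f"unknown classifier {classifier!r}")
    if transductive is None:
        transductive = config.transductive
    cache = _cache if _cache is not None else {}
    k = config.folds

    if "folds" not in cache:
        cache["folds"] = kfold_split(len(pairs), k, seed, labels, config.stratified)
    assignment = cache["folds"]

    need_attr = mode in ("attribute", "multiple")
    need_behav = mode in ("behavior", "multiple")
    if need_attr:
        if records is None:
            raise EvaluationError("attribute mode requires sequence records")
        if "attribute" not in cache:
            cache["attribute"] = attribute_features(records, config, _fold_seed(seed, 777))
    attr = cache.get("attribute")

    per_fold = []
    pairs_arr = list(pairs)
    labels_arr = np.asarray(labels, dtype=int)
    for fold in range(k):
        test_mask = assignment == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        train_pairs = [pairs_arr[i] for i in train_idx]
        train_labels = labels_arr[train_idx]
        test_pairs = [pairs_arr[i] for i in test_idx]
        test_labels = labels_arr[test_idx]

        behav = None
        if need_behav:
            key = "behavior_full" if transductive else ("behavior", fold)
            if key not in cache:
                train_edges = (
                    None
                    if transductive
                    else [p for p, l in zip(train_pairs, train_labels) if l == 1]
                )
                cache[key] = behavior_features(
                    graph, config, _fold_seed(seed, fold), train_edges
                )
            behav = cache[key]

        features = fuse_features(mode, behav, attr)
        scores = _fit_and_score(
            classifier, config, _fold_seed(seed, 100 + fold),
            train_pairs, train_labels, test_pairs, features,
        )
        fold_metrics = metrics(confusion(test_labels, scores, config.threshold))
        fold_metrics["AUC"] = auc(test_labels, scores)
        per_fold.append(fold_metrics)
        logger.info("fold %d/%d [%s/%s]: %s", fold + 1, k, mode, classifier,
                    {m: round(v, 4) for m, v in fold_metrics.items() if v is not None})

    return MetricsReport(
        mode=mode,
        classifier=classifier,
        per_fold=per_fold,
        metadata={"k": k, "seed": seed, "transductive": transductive,
                  "n_pairs": len(pairs), "stratified": config.stratified},
    )


def ablation_run(
    graph, records, pairs, labels, mode: str, config: RunConfig, seed: int,
    _cache: dict | None = None,
) -> MetricsReport:
    """Single-channel or fused evaluation with the identical CV protocol.

    mode 'behavior' feeds only the sigma-dim network embedding, 'attribute'
    only the sigma-dim sequence embedding, 'multiple' their 2-sigma fusion.
    """
    return cross_validate(
        graph, records, pairs, labels, config, seed, mode=mode, _cache=_cache
    )


def ablation_suite(
    graph, records, pairs, labels, config: RunConfig, seed: int
) -> dict[str, MetricsReport]:
    """All three feature modes with shared folds and shared embeddings."""
    cache: dict = {}
    return {
        mode: ablation_run(graph, records, pairs, labels, mode, config, seed, _cache=cache)
        for mode in MODES
    }


def baseline_run(
    graph, records, pairs, labels, classifier: str, config: RunConfig, seed: int,
    _cache: dict | None = None, mode: str = "multiple",
) -> MetricsReport:
    """Replace the DNN with a standard learner (LR or DT), same protocol.

    With a shared ``_cache`` (or just the same seed) the folds are identical
    across classifiers, so comparisons are paired.
    """
    return cross_validate(
        graph, records, pairs, labels, config, seed, mode=mode,
        classifier=classifier, _cache=_cache,
    )
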