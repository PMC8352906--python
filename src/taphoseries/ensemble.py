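"""Stacked and majority-vote ensembles of neural-network base learners.

Five multilayer perceptron base learners (differing in hidden widths and
seed) are trained on the relative-representation series.  In stacked mode a
meta-learner is trained on out-of-fold base probabilities (5-fold, so the
meta-learner never sees a base learner's training predictions); in majority
mode the base argmax votes decide and the reported probability is the mean
base probability of the winning class — a soft score accompanying the hard
vote, which is why reported values need not be multiples of 1/5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .series import CLASS_ORDER, PRIMARY, LabeledDataset
from .classifiers.base import ClassifierVerdict, resolve_tie

_DEFAULT_WIDTHS: tuple[tuple[int, int], ...] = (
    (64, 32),
    (48, 24),
    (32, 16),
    (64, 16),
    (32, 32),
)


@dataclass
class EnsembleConfig:
    """Settings shared by the stacked and majority-vote modes."""

    n_base: int = 5
    base_hidden_widths: tuple[tuple[int, ...], ...] = _DEFAULT_WIDTHS
    meta_hidden_widths: tuple[int, ...] = (16,)
    max_iter: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "stacked"
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_base < 2:
            raise ValueError("need at least 2 base learners")
        if len(self.base_hidden_widths) < self.n_base:
            raise ValueError("one hidden-width spec per base learner required")
        if self.mode not in ("stacked", "majority"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _make_base(config: EnsembleConfig, i: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=config.base_hidden_widths[i],
        solver="lbfgs",
        max_iter=config.max_iter,
        random_state=config.seed * 1000 + i,
    )


def f1_score_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = harmonic mean of precision and recall from confusion counts."""
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


@dataclass
class StackedEnsemble:
    """Fitted ensemble: base learners, optional meta-learner, OOF metrics."""

    bases: list
    meta: MLPClassifier | None
    classes: np.ndarray
    base_metrics: list[dict]
    config: EnsembleConfig

    def _base_probs(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_base) probability of class P from each base."""
        p_idx = list(self.classes).index(PRIMARY)
        return np.column_stack(
            [b.predict_proba(X)[:, p_idx] for b in self.bases]
        )


def fit_stacked(train: LabeledDataset, config: EnsembleConfig | None = None) -> StackedEnsemble:
    """Train base learners plus a meta-learner on out-of-fold probabilities.

    Each base learner's out-of-fold accuracy and F1 (class P positive) are
    reported in ``base_metrics``.
    """
    if config is None:
        config = EnsembleConfig()
    X, y = train.X, train.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ensemble training requires both classes")
    n_folds = min(config.n_folds, np.bincount(
        np.searchsorted(classes, y)).min())
    if n_folds < 2:
        raise ValueError("each class needs at least 2 samples")
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=config.seed
    )
    oof = np.zeros((len(y), config.n_base))
    oof_pred = np.empty((len(y), config.n_base), dtype=y.dtype)
    for train_idx, test_idx in skf.split(X, y):
        for i in range(config.n_base):
            base = _make_base(config, i).fit(X[train_idx], y[train_idx])
            p_idx = list(base.classes_).index(PRIMARY)
            oof[test_idx, i] = base.predict_proba(X[test_idx])[:, p_idx]
            oof_pred[test_idx, i] = base.predict(X[test_idx])
    base_metrics = []
    for i in range(config.n_base):
        pred = oof_pred[:, i]
        acc = float(np.mean(pred == y))
        tp = int(np.sum((pred == PRIMARY) & (y == PRIMARY)))
        fp = int(np.sum((pred == PRIMARY) & (y != PRIMARY)))
        fn = int(np.sum((pred != PRIMARY) & (y == PRIMARY)))
        base_metrics.append(
            {"accuracy": acc, "f1": f1_score_from_counts(tp, fp, fn)}
        )
    bases = [_make_base(config, i).fit(X, y) for i in range(config.n_base)]
    meta = MLPClassifier(
        hidden_layer_sizes=config.meta_hidden_widths,
        solver="lbfgs",
        max_iter=config.max_iter,
        random_state=config.seed * 1000 + 999,
    ).fit(oof, y)
    return StackedEnsemble(bases, meta, np.unique(y), base_metrics, config)


def predict_stacked(model: StackedEnsemble, query) -> ClassifierVerdict:
    """Meta-learner verdict: label by argmax, probability of that label."""
    q = np.atleast_2d(np.asarray(query, dtype=float))
    probs = model.meta.predict_proba(model._base_probs(q))[0]
    idx = int(np.argmax(probs))
    return ClassifierVerdict(
        "stacked", str(model.meta.classes_[idx]), float(probs[idx])
    )


def majority_vote(bases: Sequence, query) -> ClassifierVerdict:
    """Hard-vote verdict over fitted base learners.

    Probability = mean base probability of the winning class.  An even split
    breaks by higher mean probability, then by fixed class order.
    """
    if len(bases) < 2:
        raise ValueError("majority vote needs at least 2 base learners")
    q = np.atleast_2d(np.asarray(query, dtype=float))
    votes: dict[str, int] = {}
    probs: dict[str, list[float]] = {}
    for b in bases:
        p = b.predict_proba(q)[0]
        for cls, pc in zip(b.classes_, p):
            probs.setdefault(str(cls), []).append(float(pc))
        lab = str(b.classes_[int(np.argmax(p))])
        votes[lab] = votes.get(lab, 0) + 1
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    if len(tied) == 1:
        label = tied[0]
    else:
        means = {lab: float(np.mean(probs[lab])) for lab in tied}
        best = max(means.values())
        closest = [lab for lab in tied if means[lab] == best]
        label = closest[0] if len(closest) == 1 else resolve_tie(closest)
    return ClassifierVerdict("majority", label, float(np.mean(probs[label])))


def evaluate(predict, test: LabeledDataset) -> dict:
    """Accuracy and F1 (class P positive) of a verdict function on a test set."""
    preds = [predict(x).predicted for x in test.X]
    y = test.y
    acc = float(np.mean(np.asarray(preds) == y))
    tp = sum(1 for p, t in zip(preds, y) if p == PRIMARY and t == PRIMARY)
    fp = sum(1 for p, t in zip(preds, y) if p == PRIMARY and t != PRIMARY)
    fn = sum(1 for p, t in zip(preds, y) if p != PRIMARY and t == PRIMARY)
    return {"accuracy": acc, "f1": f1_score_from_counts(tp, fp, fn)}
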