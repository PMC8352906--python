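"""Markov Transition Field imaging of assemblage series.

The amplitudes of a series are quantile-binned into ``n_bins`` states; the
row-normalised first-order transition matrix W is estimated from consecutive
steps; the field ``M[i, j] = W[state(i), state(j)]`` projects those
transition probabilities back onto all time-point pairs.  The L×L field is
block-averaged down to a small image whose flattened pixels feed a logistic
or random-forest backend (the two families that report a classification
probability alongside the label).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .base import ClassifierVerdict


def _quantile_states(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    return np.searchsorted(edges, x, side="left")


def _row_stochastic(W: np.ndarray) -> np.ndarray:
    # states with no observed outgoing transition become absorbing
    # (self-loop), keeping the matrix row-stochastic without spreading
    # probability to states the series never reached
    row_sums = W.sum(axis=1, keepdims=True)
    out = np.where(row_sums > 0, W / np.where(row_sums == 0, 1, row_sums), 0.0)
    empty = np.flatnonzero(row_sums.ravel() == 0)
    out[empty, empty] = 1.0
    return out


def mtf_image(series, image_size: float | int = 0.1, n_bins: int = 6) -> np.ndarray:
    """Markov Transition Field of a series, block-averaged to a small image.

    ``image_size`` is either the output side length (integer) or a fraction
    of the series length (the side becomes ``ceil(image_size * L)``).
    Transition-matrix rows with no outgoing transitions become self-loops,
    so the matrix is always row-stochastic; a constant series therefore
    yields an all-ones field (its single occupied state always returns to
    itself) and a strictly increasing series with one state per point yields
    a field with entries in {0, 1}.
    """
    x = np.asarray(series, dtype=float)
    L = len(x)
    if L < 2:
        raise ValueError("MTF needs a series of length >= 2")
    states = _quantile_states(x, n_bins)
    W = np.zeros((n_bins, n_bins))
    np.add.at(W, (states[:-1], states[1:]), 1.0)
    W = _row_stochastic(W)
    field = W[np.ix_(states, states)]
    side = int(np.ceil(image_size * L)) if isinstance(image_size, float) else image_size
    side = max(1, min(side, L))
    bounds = np.linspace(0, L, side + 1).round().astype(int)
    image = np.empty((side, side))
    for i in range(side):
        for j in range(side):
            block = field[bounds[i]: bounds[i + 1], bounds[j]: bounds[j + 1]]
            image[i, j] = block.mean()
    return image


def transition_matrix(series, n_bins: int = 6) -> np.ndarray:
    """Row-stochastic state transition matrix used by :func:`mtf_image`."""
    x = np.asarray(series, dtype=float)
    states = _quantile_states(x, n_bins)
    W = np.zeros((n_bins, n_bins))
    np.add.at(W, (states[:-1], states[1:]), 1.0)
    return _row_stochastic(W)


class MtfClassifier:
    """Classifier over flattened MTF images (logistic or random forest).

    Emits a probability: the backend's class-membership probability for the
    predicted class (for the forest, the fraction of trees voting for it).
    """

    name = "mtf"

    def __init__(
        self,
        backend: str = "random_forest",
        image_size: float | int = 0.1,
        n_bins: int = 6,
        n_estimators: int = 100,
        seed: int = 0,
    ):
        if backend not in ("logistic", "random_forest"):
            raise ValueError(f"unknown backend {backend!r}")
        self.backend = backend
        self.image_size = image_size
        self.n_bins = n_bins
        self.n_estimators = n_estimators
        self.seed = seed

    def _features(self, X: np.ndarray) -> np.ndarray:
        return np.stack(
            [mtf_image(x, self.image_size, self.n_bins).ravel() for x in X]
        )

    def fit(self, X, y) -> "MtfClassifier":
        X = np.asarray(X, dtype=float)
        if self.backend == "logistic":
            self._model = LogisticRegression(solver="liblinear")
        else:
            self._model = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.seed
            )
        self._model.fit(self._features(X), np.asarray(y))
        return self

    def classify(self, series) -> ClassifierVerdict:
        f = self._features(np.atleast_2d(np.asarray(series, dtype=float)))
        probs = self._model.predict_proba(f)[0]
        idx = int(np.argmax(probs))
        label = str(self._model.classes_[idx])
        return ClassifierVerdict(self.name, label, float(probs[idx]))

    def predict(self, X) -> np.ndarray:
        return self._model.predict(self._features(np.asarray(X, dtype=float)))
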