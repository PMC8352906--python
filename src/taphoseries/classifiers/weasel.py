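"""WEASEL: word extraction for time-series classification.

For every window size in a sweep range, stride-1 windows are turned into SFA
words (windows are *not* z-normalised; coefficients are discretised by
equi-depth multiple coefficient binning learned on training windows).  Words
are collected as unigrams and as bigrams of words one window-length apart,
tagged by window size so vocabularies never collide across scales.  A
chi-squared test against the class labels scores every feature on the
training counts and only the top quantile is retained; a liblinear logistic
model classifies the selected count vectors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.sparse import csr_matrix
from sklearn.feature_selection import chi2
from sklearn.linear_model import LogisticRegression

from .base import ClassifierVerdict
from .symbolic import SfaTransformer


class WeaselClassifier:
    """Multi-window bag-of-SFA-words with chi² selection + logistic backend.

    Parameters
    ----------
    word_size:
        Number of Fourier symbols per word.
    window_range:
        Inclusive (min, max) sweep of window sizes; ``window_step`` thins the
        sweep (1 = every size).
    alphabet:
        Symbols per coefficient.
    selection_quantile:
        Features with chi² score at or above this quantile of all scores are
        kept (default: top 10%).
    bigrams:
        Also emit pairs of words one window-length apart.
    """

    name = "weasel"

    def __init__(
        self,
        word_size: int = 4,
        window_range: tuple[int, int] = (5, 110),
        window_step: int = 1,
        alphabet: int = 4,
        selection_quantile: float = 0.9,
        bigrams: bool = True,
    ):
        if window_range[0] < 2 or window_range[1] < window_range[0]:
            raise ValueError(f"bad window_range {window_range}")
        self.word_size = word_size
        self.window_range = window_range
        self.window_step = window_step
        self.alphabet = alphabet
        self.selection_quantile = selection_quantile
        self.bigrams = bigrams

    @property
    def window_sizes(self) -> list[int]:
        lo, hi = self.window_range
        return list(range(lo, hi + 1, self.window_step))

    def _series_counts(self, X: np.ndarray, fit: bool) -> list[dict]:
        """Per-series feature→count dicts across all window sizes."""
        counts: list[dict] = [dict() for _ in range(len(X))]
        if fit:
            self._sfas = {}
        for w in self.window_sizes:
            if w > X.shape[1]:
                continue
            windows = sliding_window_view(X, w, axis=1)
            flat = windows.reshape(-1, w)
            if fit:
                sfa = SfaTransformer(
                    self.word_size, self.alphabet, znorm_windows=False
                ).fit(flat)
                self._sfas[w] = sfa
            else:
                sfa = self._sfas.get(w)
                if sfa is None:
                    continue
            n_win = windows.shape[1]
            words = sfa.transform(flat)
            for i in range(len(X)):
                row = counts[i]
                series_words = words[i * n_win : (i + 1) * n_win]
                for word in series_words:
                    key = (w, word)
                    row[key] = row.get(key, 0) + 1
                if self.bigrams:
                    for j in range(w, n_win):
                        key = (w, series_words[j - w], series_words[j])
                        row[key] = row.get(key, 0) + 1
        return counts

    def _sparse(self, counts: list[dict], vocab: dict) -> csr_matrix:
        data, indices, indptr = [], [], [0]
        for row in counts:
            for key, c in row.items():
                j = vocab.get(key)
                if j is not None:
                    indices.append(j)
                    data.append(c)
            indptr.append(len(indices))
        return csr_matrix(
            (data, indices, indptr), shape=(len(counts), len(vocab))
        )

    def fit(self, X, y) -> "WeaselClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(set(y)) < 2:
            raise ValueError("WEASEL needs at least two classes to select features")
        counts = self._series_counts(X, fit=True)
        full_vocab = {}
        for row in counts:
            for key in row:
                if key not in full_vocab:
                    full_vocab[key] = len(full_vocab)
        if not full_vocab:
            raise ValueError("no features extracted; check window_range")
        M = self._sparse(counts, full_vocab)
        scores, _ = chi2(M, y)
        scores = np.nan_to_num(scores)
        threshold = np.quantile(scores, self.selection_quantile)
        keep = np.flatnonzero(scores >= threshold)
        if keep.size == 0:
            raise ValueError("feature vocabulary empty after chi-squared selection")
        inv = {j: key for key, j in full_vocab.items()}
        self._vocab = {inv[j]: i for i, j in enumerate(keep)}
        M_sel = self._sparse(counts, self._vocab)
        self._model = LogisticRegression(solver="liblinear").fit(M_sel, y)
        return self

    def transform(self, X) -> csr_matrix:
        """Selected-feature count matrix for already-fitted vocabulary."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._sparse(self._series_counts(X, fit=False), self._vocab)

    def classify(self, series) -> ClassifierVerdict:
        label = self._model.predict(self.transform(series))[0]
        return ClassifierVerdict(self.name, str(label))

    def predict(self, X) -> np.ndarray:
        return self._model.predict(self.transform(X))
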