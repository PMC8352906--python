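"""Symbolic time-series transforms and the bag-of-words classifier families.

Building blocks
---------------
* :func:`paa` — piecewise aggregate approximation (segment means, with
  fractional-boundary weighting when the length is not divisible);
* :func:`sax_word` — symbolic aggregate approximation of a z-normalised
  series using Gaussian quantile breakpoints;
* :class:`SfaTransformer` — symbolic Fourier approximation: the leading DFT
  coefficients of a window (mean coefficient dropped), each discretised by
  its own quantile edges learned on training windows (multiple coefficient
  binning, MCB);
* :func:`boss_histogram` — sliding-window SFA words with numerosity
  reduction (runs of identical consecutive words count once).

Classifiers
-----------
* :class:`BossClassifier` — BOSS histograms compared with the asymmetric
  BOSS distance (1-NN) or fed to a linear SVM;
* :class:`BossVsClassifier` — BOSS in vector space: per-class tf-idf vectors
  from class-merged bags, cosine similarity, majority over word sizes;
* :class:`SaxVsmClassifier` — the same vector-space scheme over sliding
  SAX words.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm
from sklearn.svm import LinearSVC

from ..series import CLASS_ORDER
from .base import ClassifierVerdict, resolve_tie

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def znorm(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-normalise; a zero-variance input maps to the all-zero vector."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def paa(series, word_size: int) -> np.ndarray:
    """Piecewise aggregate approximation to ``word_size`` segment means.

    Segment boundaries fall at ``i * L / word_size``; samples straddling a
    boundary contribute fractionally to both segments.
    """
    x = np.asarray(series, dtype=float)
    L = len(x)
    if word_size > L:
        raise ValueError(f"word_size {word_size} exceeds series length {L}")
    if L % word_size == 0:
        return x.reshape(word_size, -1).mean(axis=1)
    out = np.empty(word_size)
    for i in range(word_size):
        start, end = i * L / word_size, (i + 1) * L / word_size
        j0, j1 = int(np.floor(start)), int(np.ceil(end))
        idx = np.arange(j0, j1)
        weights = np.minimum(idx + 1, end) - np.maximum(idx, start)
        out[i] = (x[j0:j1] * weights).sum() / (end - start)
    return out


def _gaussian_breakpoints(n_symbols: int) -> np.ndarray:
    return norm.ppf(np.arange(1, n_symbols) / n_symbols)


def sax_word(
    series,
    word_size: int,
    n_bins_symbols: int = 2,
    strategy: str = "normal",
) -> str:
    """SAX word of a series: z-normalise, PAA, breakpoint lookup.

    ``strategy='normal'`` uses standard Gaussian quantile breakpoints on the
    z-normalised series; ``'uniform'`` equal-width and ``'quantile'``
    empirical-quantile breakpoints on the original amplitudes.  A segment
    value exactly on a breakpoint takes the lower symbol, so a zero-variance
    series yields a well-defined degenerate word (all lowest symbol under
    ``'normal'``).
    """
    if n_bins_symbols < 2:
        raise ValueError("alphabet size must be >= 2")
    x = np.asarray(series, dtype=float)
    if strategy == "normal":
        segments = paa(znorm(x), word_size)
        bp = _gaussian_breakpoints(n_bins_symbols)
    elif strategy == "uniform":
        segments = paa(x, word_size)
        bp = np.linspace(x.min(), x.max(), n_bins_symbols + 1)[1:-1]
    elif strategy == "quantile":
        segments = paa(x, word_size)
        bp = np.quantile(x, np.arange(1, n_bins_symbols) / n_bins_symbols)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    idx = np.searchsorted(bp, segments, side="left")
    return "".join(_ALPHABET[i] for i in idx)


class SfaTransformer:
    """Symbolic Fourier approximation with multiple coefficient binning.

    ``fit`` learns per-coefficient quantile edges on a stack of training
    windows; ``transform`` maps windows to words (tuples of symbol indices).
    ``znorm_windows`` controls whether each window is z-normalised before the
    DFT (BOSS does, WEASEL does not).
    """

    def __init__(
        self, word_size: int, alphabet: int = 4, znorm_windows: bool = True
    ):
        if word_size < 1:
            raise ValueError("word_size must be >= 1")
        if alphabet < 2:
            raise ValueError("alphabet must be >= 2")
        self.word_size = word_size
        self.alphabet = alphabet
        self.znorm_windows = znorm_windows
        self.edges_: np.ndarray | None = None

    def coefficients(self, windows: np.ndarray) -> np.ndarray:
        """Leading real/imag DFT coefficients (DC dropped), interleaved."""
        windows = np.atleast_2d(np.asarray(windows, dtype=float))
        if windows.shape[1] < 2:
            raise ValueError("SFA windows must have length >= 2")
        if self.znorm_windows:
            windows = znorm(windows, axis=1)
        F = np.fft.rfft(windows, axis=1)[:, 1:]  # drop the mean coefficient
        inter = np.empty((F.shape[0], 2 * F.shape[1]))
        inter[:, 0::2] = F.real
        inter[:, 1::2] = F.imag
        return inter[:, : self.word_size]

    def fit(self, windows: np.ndarray) -> "SfaTransformer":
        c = self.coefficients(windows)
        q = np.arange(1, self.alphabet) / self.alphabet
        self.edges_ = np.stack(
            [np.quantile(c[:, j], q) for j in range(c.shape[1])]
        )
        return self

    def transform(self, windows: np.ndarray) -> list[tuple[int, ...]]:
        if self.edges_ is None:
            raise RuntimeError("SfaTransformer is not fitted")
        c = self.coefficients(windows)
        if c.shape[1] != self.edges_.shape[0]:
            raise ValueError("window length inconsistent with fitted state")
        symbols = np.empty_like(c, dtype=np.int64)
        for j in range(c.shape[1]):
            symbols[:, j] = np.searchsorted(self.edges_[j], c[:, j], side="right")
        return [tuple(row) for row in symbols]

    def word_strings(self, windows: np.ndarray) -> list[str]:
        """Words rendered in the letter alphabet (for inspection)."""
        return [
            "".join(_ALPHABET[i] for i in w) for w in self.transform(windows)
        ]


def _numerosity_reduce(words: Sequence) -> list:
    out = []
    prev = object()
    for w in words:
        if w != prev:
            out.append(w)
        prev = w
    return out


def boss_histogram(
    series, window_size: int, sfa: SfaTransformer
) -> Counter:
    """Bag of SFA words of all stride-1 windows, after numerosity reduction."""
    x = np.asarray(series, dtype=float)
    if window_size > len(x):
        raise ValueError(
            f"window_size {window_size} exceeds series length {len(x)}"
        )
    windows = sliding_window_view(x, window_size)
    return Counter(_numerosity_reduce(sfa.transform(windows)))


def boss_distance(q: Counter, t: Counter) -> float:
    """Asymmetric BOSS distance: squared count differences over q's words."""
    return float(sum((c - t.get(w, 0)) ** 2 for w, c in q.items()))


class BossClassifier:
    """Bag-of-SFA-symbols classifier (1-NN BOSS distance or linear SVM)."""

    name = "boss"

    def __init__(
        self,
        word_size: int = 4,
        window_size: int = 119,
        alphabet: int = 2,
        backend: str = "knn",
    ):
        if backend not in ("knn", "linear_svm"):
            raise ValueError(f"unknown backend {backend!r}")
        self.word_size = word_size
        self.window_size = window_size
        self.alphabet = alphabet
        self.backend = backend

    def _all_windows(self, X: np.ndarray) -> np.ndarray:
        return sliding_window_view(X, self.window_size, axis=1).reshape(
            -1, self.window_size
        )

    def fit(self, X, y) -> "BossClassifier":
        X = np.asarray(X, dtype=float)
        if self.window_size > X.shape[1]:
            raise ValueError("window_size exceeds series length")
        self._sfa = SfaTransformer(
            self.word_size, self.alphabet, znorm_windows=True
        ).fit(self._all_windows(X))
        self._hists = [boss_histogram(x, self.window_size, self._sfa) for x in X]
        self._y = np.asarray(y)
        if self.backend == "linear_svm":
            self._vocab = sorted({w for h in self._hists for w in h})
            self._index = {w: i for i, w in enumerate(self._vocab)}
            M = self._matrix(self._hists)
            self._svm = LinearSVC().fit(M, self._y)
        return self

    def _matrix(self, hists: list[Counter]) -> np.ndarray:
        M = np.zeros((len(hists), len(self._vocab)))
        for i, h in enumerate(hists):
            for w, c in h.items():
                j = self._index.get(w)
                if j is not None:
                    M[i, j] = c
        return M

    def classify(self, series) -> ClassifierVerdict:
        q = boss_histogram(np.asarray(series, float), self.window_size, self._sfa)
        if self.backend == "knn":
            dists = np.array([boss_distance(q, t) for t in self._hists])
            best = dists.min()
            labels = set(self._y[dists == best])
            label = labels.pop() if len(labels) == 1 else resolve_tie(labels)
        else:
            label = self._svm.predict(self._matrix([q]))[0]
        return ClassifierVerdict(self.name, str(label))

    def predict(self, X) -> np.ndarray:
        return np.array([self.classify(x).predicted for x in X])


class _TfIdfBags:
    """Per-class tf-idf vectors over a shared word vocabulary.

    Two weightings:

    * ``"strict"`` — raw term frequency × log(n_classes / document
      frequency); a word present in every class carries zero weight.  This is
      the classic vector-space weighting and suits large vocabularies.
    * ``"sublinear_smooth"`` — (1 + log tf) × log(1 + n_classes / df), the
      weighting of the original BOSS-in-vector-space formulation.  With a
      coarse alphabet the entire (tiny) vocabulary occurs in every class, so
      the strict idf would zero all weights; the smoothed form keeps the
      class term-frequency profiles comparable.

    Queries are compared by cosine similarity of their raw term-frequency
    vector against each class vector.
    """

    def __init__(self, class_bags: dict[str, Counter], weighting: str = "strict"):
        if weighting not in ("strict", "sublinear_smooth"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.classes = [c for c in CLASS_ORDER if c in class_bags] + sorted(
            set(class_bags) - set(CLASS_ORDER)
        )
        vocab = sorted({w for bag in class_bags.values() for w in bag})
        self.index = {w: i for i, w in enumerate(vocab)}
        n_classes = len(self.classes)
        df = np.zeros(len(vocab))
        tf = np.zeros((n_classes, len(vocab)))
        for ci, c in enumerate(self.classes):
            for w, count in class_bags[c].items():
                j = self.index[w]
                tf[ci, j] = count
                df[j] += 1
        if weighting == "strict":
            self.tfidf = tf * np.log(n_classes / df)
        else:
            logtf = np.zeros_like(tf)
            np.log(tf, out=logtf, where=tf > 0)
            self.tfidf = np.where(tf > 0, 1 + logtf, 0.0) * np.log(
                1 + n_classes / df
            )

    def query_vector(self, bag: Counter) -> np.ndarray:
        v = np.zeros(len(self.index))
        for w, c in bag.items():
            j = self.index.get(w)
            if j is not None:
                v[j] = c
        return v

    def best_class(self, bag: Counter) -> str:
        v = self.query_vector(bag)
        vnorm = np.linalg.norm(v)
        if vnorm == 0:
            raise ValueError(
                "query shares no vocabulary with the training corpus"
            )
        sims = np.zeros(len(self.classes))
        for ci in range(len(self.classes)):
            cnorm = np.linalg.norm(self.tfidf[ci])
            if cnorm > 0:
                sims[ci] = self.tfidf[ci] @ v / (cnorm * vnorm)
        best = sims.max()
        tied = [c for c, s in zip(self.classes, sims) if s == best]
        return tied[0] if len(tied) == 1 else resolve_tie(tied)


class BossVsClassifier:
    """BOSS in vector space: class tf-idf vectors, cosine similarity.

    One model is fitted per word size in ``word_sizes``; the verdict is the
    majority over word sizes, ties resolving to the fixed class order.  If no
    ``window_size`` is given, the window length is selected from a candidate
    grid (fractions of the series length) by leave-one-out accuracy on the
    training set, as the algorithm's published formulation prescribes.
    """

    name = "boss_vs"

    def __init__(
        self,
        word_sizes: Sequence[int] = (2, 3, 4),
        alphabet: int = 2,
        window_size: int | None = None,
        window_candidates: Sequence[int] | None = None,
    ):
        self.word_sizes = tuple(word_sizes)
        self.alphabet = alphabet
        self.window_size = window_size
        self.window_candidates = window_candidates

    def _fit_window(self, X, y, window: int):
        windows = sliding_window_view(X, window, axis=1).reshape(-1, window)
        models = []
        per_sample: list[list[Counter]] = []
        for ws in self.word_sizes:
            sfa = SfaTransformer(ws, self.alphabet, znorm_windows=True).fit(windows)
            hists = [boss_histogram(x, window, sfa) for x in X]
            bags: dict[str, Counter] = {}
            for h, label in zip(hists, y):
                bags.setdefault(label, Counter()).update(h)
            models.append(
                (sfa, _TfIdfBags(bags, weighting="sublinear_smooth"), bags)
            )
            per_sample.append(hists)
        return models, per_sample

    @staticmethod
    def _loo_score(models, per_sample, y) -> float:
        """Leave-one-out accuracy: each sample scored against class vectors
        rebuilt without its own word counts."""
        correct = 0
        n = len(y)
        for i in range(n):
            votes = []
            for (sfa, _, bags), hists in zip(models, per_sample):
                reduced = {c: bag.copy() for c, bag in bags.items()}
                reduced[y[i]].subtract(hists[i])
                reduced = {
                    c: +bag for c, bag in reduced.items()
                }  # drop non-positive counts
                if any(not bag for bag in reduced.values()):
                    continue
                try:
                    votes.append(
                        _TfIdfBags(
                            reduced, weighting="sublinear_smooth"
                        ).best_class(hists[i])
                    )
                except ValueError:
                    continue
            if votes:
                counts = Counter(votes)
                top = max(counts.values())
                tied = [c for c, v in counts.items() if v == top]
                label = tied[0] if len(tied) == 1 else resolve_tie(tied)
                correct += label == y[i]
        return correct / n

    def fit(self, X, y) -> "BossVsClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        L = X.shape[1]
        if self.window_size is not None:
            if self.window_size > L:
                raise ValueError("window_size exceeds series length")
            candidates = [self.window_size]
        elif self.window_candidates is not None:
            candidates = [w for w in self.window_candidates if w <= L]
        else:
            candidates = sorted(
                {max(4, w) for w in (L // 6, L // 4, L // 3, L // 2, 3 * L // 4)}
            )
        if not candidates:
            raise ValueError("no admissible window size")
        best = None
        for w in candidates:
            models, per_sample = self._fit_window(X, y, w)
            if len(candidates) == 1:
                best = (1.0, w, models)
                break
            score = self._loo_score(models, per_sample, y)
            if best is None or score > best[0]:
                best = (score, w, models)
        _, self.window_size_, raw_models = best
        self._models = [(sfa, bags) for sfa, bags, _ in raw_models]
        return self

    def classify(self, series) -> ClassifierVerdict:
        votes = []
        for sfa, bags in self._models:
            q = boss_histogram(
                np.asarray(series, float), self.window_size_, sfa
            )
            votes.append(bags.best_class(q))
        counts = Counter(votes)
        top = max(counts.values())
        tied = [c for c, v in counts.items() if v == top]
        label = tied[0] if len(tied) == 1 else resolve_tie(tied)
        return ClassifierVerdict(self.name, label)

    def predict(self, X) -> np.ndarray:
        return np.array([self.classify(x).predicted for x in X])


class SaxVsmClassifier:
    """SAX words in vector space (tf-idf class corpora, cosine similarity).

    Sliding windows are z-normalised individually before SAX discretisation,
    which makes the verdict invariant to rescaling the query.
    """

    name = "sax_vsm"

    def __init__(
        self,
        word_size: int = 6,
        n_bins_symbols: int = 2,
        strategy: str = "normal",
        window_size: int | None = None,
        weighting: str = "sublinear_smooth",
    ):
        self.word_size = word_size
        self.n_bins_symbols = n_bins_symbols
        self.strategy = strategy
        self.window_size = window_size
        self.weighting = weighting

    def _bag(self, x: np.ndarray, window_size: int) -> Counter:
        windows = sliding_window_view(x, window_size)
        words = [
            sax_word(w, self.word_size, self.n_bins_symbols, self.strategy)
            for w in windows
        ]
        return Counter(_numerosity_reduce(words))

    def fit(self, X, y) -> "SaxVsmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self._window = self.window_size or max(self.word_size, X.shape[1] // 4)
        if self._window > X.shape[1]:
            raise ValueError("window_size exceeds series length")
        bags: dict[str, Counter] = {}
        for x, label in zip(X, y):
            bags.setdefault(label, Counter()).update(self._bag(x, self._window))
        self._bags = _TfIdfBags(bags, weighting=self.weighting)
        return self

    def classify(self, series) -> ClassifierVerdict:
        q = self._bag(np.asarray(series, dtype=float), self._window)
        return ClassifierVerdict(self.name, self._bags.best_class(q))

    def predict(self, X) -> np.ndarray:
        return np.array([self.classify(x).predicted for x in X])
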