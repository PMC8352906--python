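"""Unit tests of the six classifier families and their transforms."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taphoseries.classifiers import (
    BossClassifier,
    BossVsClassifier,
    KnnDtwClassifier,
    MtfClassifier,
    SaxVsmClassifier,
    SfaTransformer,
    WeaselClassifier,
    boss_distance,
    boss_histogram,
    dtw_distance,
    mtf_image,
    paa,
    sax_word,
)
from taphoseries.classifiers.mtf import transition_matrix
from taphoseries.classifiers.symbolic import _TfIdfBags


class TestDtw:
    def test_identity_is_zero(self):
        assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset_hand_value(self):
        # 3x3 grid, squared cost: diagonal path accumulates 1+1+1
        assert dtw_distance([0, 0, 0], [1, 1, 1]) == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    @given(
        a=st.lists(st.floats(-5, 5), min_size=1, max_size=12),
        b=st.lists(st.floats(-5, 5), min_size=1, max_size=12),
    )
    @settings(derandomize=True, max_examples=100)
    def test_symmetry(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))


class TestKnnDtw:
    def test_k1_probability_always_one(self, separable_split):
        train, test = separable_split
        clf = KnnDtwClassifier(k=1).fit(train.X, train.y)
        verdicts = [clf.classify(x) for x in test.X[:5]]
        assert all(v.probability == 1.0 for v in verdicts)

    def test_query_equal_to_training_series(self):
        X = np.array([[0.0, 0, 0, 0], [5.0, 5, 5, 5]])
        clf = KnnDtwClassifier(k=1).fit(X, ["P", "S"])
        assert clf.classify(X[1]).predicted == "S"

    def test_k3_vote_fraction(self):
        X = np.array([[0.0, 0], [0.1, 0.1], [0.2, 0.2], [9.0, 9.0]])
        y = ["P", "P", "S", "S"]
        v = KnnDtwClassifier(k=3).fit(X, y).classify([0.05, 0.05])
        assert v.predicted == "P"
        assert v.probability == pytest.approx(2 / 3)


class TestPaa:
    def test_segment_means(self):
        assert np.allclose(paa([2, 2, 4, 4], 2), [2, 4])

    def test_identity_when_word_equals_length(self):
        x = [1.0, 3.0, 2.0]
        assert np.allclose(paa(x, 3), x)

    def test_constant_series(self):
        assert np.allclose(paa([5.0] * 7, 3), [5, 5, 5])

    def test_fractional_boundaries_preserve_mean(self):
        x = np.arange(10.0)
        assert paa(x, 3).mean() == pytest.approx(x.mean())

    def test_word_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            paa([1.0, 2.0], 3)


class TestSax:
    def test_two_symbol_breakpoint_is_zero(self):
        # values above the series mean map to 'b', below to 'a'
        assert sax_word([-1, -1, 1, 1], 2, 2) == "ab"

    def test_hand_word(self):
        assert sax_word([0, 0, 10, 10, 0, 0], 3, 2) == "aba"

    def test_constant_series_degenerate_word(self):
        assert sax_word([3.0] * 8, 4, 2) == "aaaa"

    @given(
        values=st.lists(
            st.floats(-10, 10), min_size=6, max_size=24
        ).filter(lambda v: np.std(v) > 1e-6),
        scale=st.floats(0.1, 100),
    )
    @settings(derandomize=True, max_examples=60)
    def test_scale_invariance_under_znorm(self, values, scale):
        x = np.asarray(values)
        assert sax_word(x, 3, 2) == sax_word(x * scale, 3, 2)


class TestSfa:
    def test_mcb_edge_at_median(self):
        # windows [c, 0, -c, 0] have first Fourier coefficient (real) = 2c
        windows = np.array([[c, 0, -c, 0] for c in (0.0, 0.5, 1.0, 1.5)])
        sfa = SfaTransformer(word_size=1, alphabet=2, znorm_windows=False).fit(windows)
        assert sfa.edges_[0][0] == pytest.approx(1.5)
        words = sfa.transform(windows)
        assert words == [(0,), (0,), (0,), (1,)] or words == [(0,), (0,), (1,), (1,)]

    def test_pure_cosine_energy_in_fundamental_pair(self):
        w = 16
        t = np.arange(w)
        windows = np.array([a * np.cos(2 * np.pi * t / w) for a in (1, 2, 3, 4)])
        sfa = SfaTransformer(word_size=4, alphabet=2, znorm_windows=False)
        coeffs = sfa.coefficients(windows)
        # energy isolated in the fundamental's real part; other coeffs ~ 0
        assert np.all(np.abs(coeffs[:, 0]) > 1)
        assert np.allclose(coeffs[:, 1:], 0, atol=1e-9)
        sfa.fit(windows)
        top = sfa.transform(windows[3:])[0]
        assert top[0] == 1  # largest amplitude sits in the top bin

    def test_identical_windows_identical_words(self):
        windows = np.tile(np.array([1.0, 4.0, 2.0, 3.0, 0.0]), (2, 1))
        sfa = SfaTransformer(2, 2).fit(windows)
        w1, w2 = sfa.transform(windows)
        assert w1 == w2

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            SfaTransformer(2, 2).coefficients(np.array([[1.0]]))


class TestBossHistogram:
    def test_window_count_before_reduction(self):
        x = np.random.default_rng(0).normal(size=120)
        sfa = SfaTransformer(4, 4).fit(
            np.lib.stride_tricks.sliding_window_view(x, 119)
        )
        # L - w + 1 = 2 windows; distinct words keep both counts
        h = boss_histogram(x, 119, sfa)
        assert sum(h.values()) in (1, 2)

    def test_constant_series_single_word(self):
        x = np.full(40, 2.0)
        sfa = SfaTransformer(3, 2).fit(
            np.lib.stride_tricks.sliding_window_view(x, 10)
        )
        h = boss_histogram(x, 10, sfa)
        assert len(h) == 1 and list(h.values()) == [1]

    def test_boss_distance_against_brute_force(self, rng):
        for _ in range(20):
            q = Counter(
                {tuple(rng.integers(0, 3, 2)): int(rng.integers(1, 5)) for _ in range(4)}
            )
            t = Counter(
                {tuple(rng.integers(0, 3, 2)): int(rng.integers(1, 5)) for _ in range(4)}
            )
            brute = sum(
                (q.get(w, 0) - t.get(w, 0)) ** 2 for w in set(q) | set(t) if w in q
            )
            assert boss_distance(q, t) == brute

    def test_boss_distance_is_asymmetric(self):
        q = Counter({("a",): 2})
        t = Counter({("a",): 2, ("b",): 3})
        assert boss_distance(q, t) == 0
        assert boss_distance(t, q) == 9


class TestBossClassifier:
    def test_query_identical_to_training_series(self, separable_split):
        train, _ = separable_split
        clf = BossClassifier(window_size=119).fit(train.X, train.y)
        assert clf.classify(train.X[0]).predicted == train.y[0]

    @pytest.mark.parametrize("backend", ["knn", "linear_svm"])
    def test_disjoint_toys_fully_separated(self, backend):
        rng = np.random.default_rng(1)
        # class P oscillates fast, class S slow: disjoint vocabularies
        t = np.arange(60.0)
        P = [np.sin(t * 1.5) * 5 + rng.normal(0, 0.1, 60) for _ in range(6)]
        S = [np.sin(t * 0.2) * 5 + rng.normal(0, 0.1, 60) for _ in range(6)]
        X = np.array(P + S)
        y = ["P"] * 6 + ["S"] * 6
        clf = BossClassifier(word_size=4, window_size=30, backend=backend).fit(X, y)
        assert (clf.predict(X) == np.array(y)).all()

    def test_no_probability_emitted(self, separable_split):
        train, _ = separable_split
        v = BossClassifier(window_size=119).fit(train.X, train.y).classify(train.X[0])
        assert v.probability is None


class TestVectorSpaceFamilies:
    def test_strict_idf_zeroes_words_shared_by_all_classes(self):
        bags = {
            "P": Counter({("x",): 4, ("y",): 1}),
            "S": Counter({("x",): 2, ("z",): 3}),
        }
        tfidf = _TfIdfBags(bags, weighting="strict")
        j = tfidf.index[("x",)]
        assert tfidf.tfidf[:, j] == pytest.approx([0.0, 0.0])  # idf log(2/2) = 0
        assert tfidf.tfidf[0, tfidf.index[("y",)]] > 0

    def test_query_matching_class_corpus(self, separable_split):
        train, _ = separable_split
        clf = BossVsClassifier().fit(train.X, train.y)
        assert clf.classify(train.X[0]).predicted == train.y[0]

    def test_identical_corpora_tie_resolves_to_primary(self):
        X = np.tile(np.sin(np.arange(60.0)), (4, 1))
        clf = SaxVsmClassifier(window_size=15).fit(X, ["P", "P", "S", "S"])
        assert clf.classify(X[0]).predicted == "P"

    def test_sax_vsm_verdict_scale_invariant(self, separable_split):
        train, test = separable_split
        clf = SaxVsmClassifier().fit(train.X, train.y)
        for x in test.X[:5]:
            assert clf.classify(x).predicted == clf.classify(x * 10).predicted

    def test_cosine_similarity_bounded(self):
        bags = {"P": Counter({("a",): 3}), "S": Counter({("b",): 2})}
        tfidf = _TfIdfBags(bags, weighting="sublinear_smooth")
        assert tfidf.best_class(Counter({("a",): 1})) == "P"
        with pytest.raises(ValueError, match="vocabulary"):
            tfidf.best_class(Counter({("q",): 1}))


class TestWeasel:
    def test_separable_toy_perfect_train_accuracy(self, separable_split):
        train, _ = separable_split
        clf = WeaselClassifier(window_range=(5, 60), window_step=5).fit(
            train.X, train.y
        )
        assert (clf.predict(train.X) == train.y).all()

    def test_identical_series_identical_rows(self, separable_split):
        train, _ = separable_split
        clf = WeaselClassifier(window_range=(5, 40), window_step=5).fit(
            train.X, train.y
        )
        a = clf.transform(train.X[0]).toarray()
        b = clf.transform(train.X[0].copy()).toarray()
        assert np.array_equal(a, b)

    def test_feature_count_monotone_in_window_sizes(self, separable_split):
        train, _ = separable_split
        few = WeaselClassifier(window_range=(10, 20), window_step=5,
                               selection_quantile=0.0).fit(train.X, train.y)
        many = WeaselClassifier(window_range=(10, 40), window_step=5,
                                selection_quantile=0.0).fit(train.X, train.y)
        assert len(many._vocab) > len(few._vocab)

    def test_training_order_permutation_invariant(self, separable_split):
        train, test = separable_split
        idx = np.random.default_rng(3).permutation(len(train))
        a = WeaselClassifier(window_range=(5, 40), window_step=5).fit(
            train.X, train.y
        )
        b = WeaselClassifier(window_range=(5, 40), window_step=5).fit(
            train.X[idx], train.y[idx]
        )
        assert (a.predict(test.X) == b.predict(test.X)).all()

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 30))
        with pytest.raises(ValueError):
            WeaselClassifier(window_range=(5, 10)).fit(X, ["P"] * 4)


class TestMtf:
    def test_transition_matrix_row_stochastic(self, rng):
        for _ in range(20):
            x = rng.normal(size=50)
            W = transition_matrix(x, n_bins=6)
            assert np.allclose(W.sum(axis=1), 1.0)

    def test_strictly_increasing_superdiagonal(self):
        x = np.arange(6.0)
        W = transition_matrix(x, n_bins=6)
        assert np.allclose(W[:5], np.eye(6, k=1)[:5])
        assert W[5, 5] == 1.0  # terminal state is absorbing
        field = mtf_image(x, image_size=6, n_bins=6)
        assert set(np.unique(field)) <= {0.0, 1.0}

    def test_constant_series_field_all_ones(self):
        field = mtf_image(np.full(20, 3.0), image_size=4, n_bins=5)
        assert np.allclose(field, 1.0)

    def test_fractional_image_size(self):
        img = mtf_image(np.random.default_rng(0).normal(size=120), image_size=0.1)
        assert img.shape == (12, 12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mtf_image([1.0])

    def test_random_forest_probability_is_tree_vote_fraction(self, separable_split):
        train, test = separable_split
        clf = MtfClassifier(backend="random_forest", n_estimators=15, seed=2).fit(
            train.X, train.y
        )
        x = test.X[0]
        v = clf.classify(x)
        feats = clf._features(np.atleast_2d(x))
        votes = [t.predict(feats)[0] for t in clf._model.estimators_]
        classes = clf._model.classes_
        frac = np.mean([classes[int(round(p))] == v.predicted for p in votes])
        assert v.probability == pytest.approx(frac)

    def test_logistic_probability_strictly_inside_unit_interval(self, separable_split):
        train, test = separable_split
        clf = MtfClassifier(backend="logistic").fit(train.X, train.y)
        v = clf.classify(test.X[0])
        assert 0.0 < v.probability < 1.0
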