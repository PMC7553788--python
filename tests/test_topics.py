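import datetime as dt

import numpy as np
import pytest
from scipy.optimize import nnls

from infodem import (Corpus, NMFTopicModel, build_vocabulary,
                     doc_term_counts, interest_share_diff, match_topics,
                     tfidf_matrix, topic_coherence, topic_half_time,
                     topic_relevance, topic_strength_series)

from conftest import make_doc


def corpus_of(bodies):
    return Corpus([make_doc(i, body=b) for i, b in enumerate(bodies)])


class TestVocabulary:
    def test_min_df_boundary(self):
        bodies = ["vaccine news"] * 20
        bodies = [b if i < 9 else "vaccine update"
                  for i, b in enumerate(bodies)]
        vocab = build_vocabulary(corpus_of(bodies), min_df=10,
                                 bigram_min_count=100)
        assert "vaccine" in vocab.index       # df 20
        assert "news" not in vocab.index      # df 9 < 10
        assert "update" in vocab.index        # df 11

    def test_collocation_bigram_detected(self):
        filler = [f"w{i} x{i} y{i} z{i}" for i in range(15)]
        bodies = [f"{f} social distancing rules" for f in filler]
        vocab = build_vocabulary(corpus_of(bodies), min_df=10,
                                 bigram_min_count=10,
                                 collocation_threshold=3.0)
        assert "social_distancing" in vocab.index
        assert ("social", "distancing") in vocab.bigrams

    def test_topical_cooccurrence_not_merged(self):
        # terms sharing documents but not adjacency structure stay unigrams
        rng = np.random.default_rng(0)
        words = ["alpha", "beta", "gamma", "delta"]
        bodies = [" ".join(rng.permutation(words * 4)) for _ in range(20)]
        vocab = build_vocabulary(corpus_of(bodies), min_df=5,
                                 bigram_min_count=5)
        assert not vocab.bigrams

    def test_empty_corpus_error(self):
        with pytest.raises(ValueError):
            build_vocabulary(Corpus([]), min_df=1)

    def test_deterministic_lexicographic_order(self):
        vocab = build_vocabulary(corpus_of(["b a c"] * 3), min_df=1)
        assert vocab.terms == sorted(vocab.terms)


class TestTfidf:
    def test_hand_computed_three_docs(self):
        corpus = corpus_of(["apple banana apple", "banana cherry", "apple"])
        vocab = build_vocabulary(corpus, min_df=1, bigram_min_count=100)
        X = tfidf_matrix(corpus, vocab).toarray()
        # terms sorted: apple, banana, cherry; idf = ln(4/(1+df)) + 1
        # row 0: tf (2, 1, 0), same idf for both -> L2 (2, 1)/sqrt(5)
        np.testing.assert_allclose(
            X[0], [2 / np.sqrt(5), 1 / np.sqrt(5), 0.0], atol=1e-10)
        idf_b = np.log(4 / 3) + 1
        idf_c = np.log(4 / 2) + 1
        norm = np.hypot(idf_b, idf_c)
        np.testing.assert_allclose(X[1], [0.0, idf_b / norm, idf_c / norm],
                                   atol=1e-10)
        np.testing.assert_allclose(X[2], [1.0, 0.0, 0.0], atol=1e-10)

    def test_matches_sklearn_vectorizer(self):
        from sklearn.feature_extraction.text import TfidfVectorizer

        bodies = ["covid cases rise", "cases fall today",
                  "covid covid response", "markets rise today today"]
        corpus = corpus_of(bodies)
        vocab = build_vocabulary(corpus, min_df=1, bigram_min_count=100)
        ours = tfidf_matrix(corpus, vocab).toarray()
        vec = TfidfVectorizer(norm="l2", smooth_idf=True,
                              vocabulary=vocab.terms)
        theirs = vec.fit_transform(bodies).toarray()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_document_without_vocab_terms_zero_row(self):
        corpus = corpus_of(["apple apple", "zzz qqq"])
        vocab = build_vocabulary(corpus_of(["apple apple"]), min_df=1)
        X = tfidf_matrix(corpus, vocab).toarray()
        assert X[1].sum() == 0.0

    def test_single_term_row_normalizes_to_one(self):
        corpus = corpus_of(["apple apple apple apple apple"])
        vocab = build_vocabulary(corpus, min_df=1)
        X = tfidf_matrix(corpus, vocab).toarray()
        assert X[0, 0] == pytest.approx(1.0)


class TestNMF:
    def test_planted_low_rank_recovery(self):
        rng = np.random.default_rng(1)
        W0 = rng.random((60, 4))
        H0 = rng.random((4, 40))
        X = W0 @ H0
        model = NMFTopicModel(n_topics=4, max_iter=800, tol=0.0,
                              inner_iter=10, random_state=0)
        W = model.fit_transform(X)
        rel = np.linalg.norm(X - W @ model.components_) / np.linalg.norm(X)
        assert rel < 1e-2
        assert (np.diff(model.objective_trace_) <= 1e-9).all()

    def test_rank_one(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([0.2, 0.5, 0.3, 0.9])
        X = np.outer(u, v)
        model = NMFTopicModel(n_topics=1, max_iter=500, tol=0.0,
                              random_state=0)
        W = model.fit_transform(X)
        rel = np.linalg.norm(X - W @ model.components_) / np.linalg.norm(X)
        assert rel < 1e-6
        h = model.components_[0]
        cos = h @ v / (np.linalg.norm(h) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 20))
        W1 = NMFTopicModel(n_topics=3, random_state=7).fit_transform(X)
        W2 = NMFTopicModel(n_topics=3, random_state=7).fit_transform(X)
        np.testing.assert_array_equal(W1, W2)

    def test_nonnegativity(self):
        rng = np.random.default_rng(3)
        X = rng.random((25, 15))
        model = NMFTopicModel(n_topics=3, random_state=0)
        W = model.fit_transform(X)
        assert (W >= 0).all() and (model.components_ >= 0).all()

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            NMFTopicModel(n_topics=10).fit(np.ones((5, 8)))

    def test_nonfinite_rejected(self):
        X = np.ones((10, 6))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            NMFTopicModel(n_topics=2).fit(X)

    def test_comparable_to_sklearn_nmf(self):
        # independent solver should land at a similar objective
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(4)
        X = rng.random((50, 30))
        ours = NMFTopicModel(n_topics=5, max_iter=500, tol=0.0,
                             inner_iter=10, random_state=0)
        W = ours.fit_transform(X)
        err_ours = np.linalg.norm(X - W @ ours.components_)
        sk = NMF(n_components=5, init="random", random_state=0,
                 max_iter=1000)
        Wsk = sk.fit_transform(X)
        err_sk = np.linalg.norm(X - Wsk @ sk.components_)
        assert err_ours <= 1.1 * err_sk


class TestTransform:
    def _fitted(self):
        rng = np.random.default_rng(5)
        H = rng.random((3, 25))
        model = NMFTopicModel(n_topics=3, max_iter=2000, tol=0.0,
                              inner_iter=10, random_state=0)
        model.components_ = H
        return model, H

    def test_scaled_basis_row_projects_to_unit_vector(self):
        model, H = self._fitted()
        W = model.transform(3.0 * H[1:2])
        assert W[0, 1] == pytest.approx(3.0, rel=1e-3)
        off = np.delete(W[0], 1)
        assert (off < 1e-3 * W[0, 1]).all()

    def test_zero_matrix(self):
        model, H = self._fitted()
        np.testing.assert_allclose(model.transform(np.zeros((4, 25))), 0.0,
                                   atol=1e-12)

    def test_matches_scipy_nnls(self):
        model, H = self._fitted()
        rng = np.random.default_rng(6)
        X = rng.random((8, 25))
        W = model.transform(X)
        for i in range(8):
            w_ref, _ = nnls(H.T, X[i])
            np.testing.assert_allclose(W[i], w_ref, atol=1e-4)

    def test_dimension_mismatch(self):
        model, _ = self._fitted()
        with pytest.raises(ValueError):
            model.transform(np.ones((4, 7)))

    def test_transform_of_training_data_consistent(self):
        rng = np.random.default_rng(7)
        X = rng.random((40, 20))
        model = NMFTopicModel(n_topics=4, max_iter=500, tol=0.0,
                              inner_iter=10, random_state=0)
        W_fit = model.fit_transform(X)
        err_fit = np.linalg.norm(X - W_fit @ model.components_)
        W_tr = model.transform(X)
        err_tr = np.linalg.norm(X - W_tr @ model.components_)
        assert err_tr <= err_fit * (1 + 1e-3)


class TestDynamics:
    def test_one_hot_document(self):
        W = np.array([[0.0, 1.0]])
        S, idx = topic_strength_series(
            W, [dt.date(2020, 2, 10)], weights=[5.0],
            window=(dt.date(2020, 2, 7), dt.date(2020, 2, 13)))
        assert S.shape == (2, 7)
        assert S[1, 3] == 5.0
        assert S.sum() == 5.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        n, K, T = 40, 3, 10
        W = rng.random((n, K))
        days = rng.integers(0, T, size=n)
        w = rng.integers(0, 5, size=n).astype(float)
        dates = [dt.date(2020, 3, 1) + dt.timedelta(days=int(d))
                 for d in days]
        S, _ = topic_strength_series(
            W, dates, weights=w,
            window=(dt.date(2020, 3, 1), dt.date(2020, 3, 10)))
        expected = np.zeros((K, T))
        for i in range(n):
            for k in range(K):
                expected[k, days[i]] += w[i] * W[i, k]
        np.testing.assert_array_equal(S, expected)

    def test_conservation(self):
        rng = np.random.default_rng(9)
        W = rng.random((30, 4))
        dates = [dt.date(2020, 3, 1) + dt.timedelta(days=int(d))
                 for d in rng.integers(0, 20, size=30)]
        S, _ = topic_strength_series(W, dates)
        assert S.sum() == pytest.approx(W.sum(), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        W = rng.random((20, 3))
        days = rng.integers(0, 5, size=20)
        dates = [dt.date(2020, 3, 1) + dt.timedelta(days=int(d))
                 for d in days]
        w = rng.random(20)
        window = (dt.date(2020, 3, 1), dt.date(2020, 3, 5))
        S1, _ = topic_strength_series(W, dates, weights=w, window=window)
        perm = rng.permutation(20)
        S2, _ = topic_strength_series(W[perm],
                                      [dates[i] for i in perm],
                                      weights=w[perm], window=window)
        np.testing.assert_allclose(S1, S2, rtol=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            topic_strength_series(np.ones((1, 2)), [dt.date(2020, 3, 1)],
                                  weights=[-1.0])

    def test_relevance_and_half_time(self):
        S = np.array([[1.0, 1.0, 1.0, 1.0],
                      [4.0, 0.0, 0.0, 0.0],
                      [0.0, 0.0, 0.0, 0.0]])
        R = topic_relevance(S)
        np.testing.assert_array_equal(R, [4.0, 4.0, 0.0])
        th = topic_half_time(S)
        assert th[0] == 1   # cumulative 2 >= 2 on the second day
        assert th[1] == 0
        assert th[2] is None

    def test_share_diff_arithmetic(self):
        d = interest_share_diff([3.0, 1.0], [1.0, 1.0])
        np.testing.assert_allclose(d, [25.0, -25.0])
        assert d.sum() == pytest.approx(0.0, abs=1e-9)

    def test_share_diff_identical_sources(self):
        np.testing.assert_allclose(
            interest_share_diff([2.0, 5.0], [4.0, 10.0]), 0.0, atol=1e-12)

    def test_share_diff_zero_total(self):
        with pytest.raises(ValueError):
            interest_share_diff([0.0, 0.0], [1.0, 1.0])


class TestCoherence:
    def _setting(self):
        # topic A terms always co-occur; topic B terms never do
        bodies = (["alpha beta filler%d" % i for i in range(5)] +
                  ["gamma filler%d" % i for i in range(5, 8)] +
                  ["delta filler%d" % i for i in range(8, 11)])
        corpus = corpus_of(bodies)
        vocab = build_vocabulary(corpus, min_df=1, bigram_min_count=100)
        H = np.zeros((2, len(vocab)))
        H[0, vocab.index["alpha"]] = 1.0
        H[0, vocab.index["beta"]] = 0.9
        H[1, vocab.index["gamma"]] = 1.0
        H[1, vocab.index["delta"]] = 0.9
        return H, vocab, corpus

    def test_cooccurring_topic_scores_maximum(self):
        H, vocab, corpus = self._setting()
        scores = topic_coherence(H, vocab, corpus, top_n=2)
        # df(alpha)=df(beta)=joint=5: both ordered pairs give ln(6/6)=0,
        # the maximum attainable for this df configuration
        assert scores[0] == pytest.approx(0.0, abs=1e-12)
        assert scores[1] < scores[0]

    def test_pair_hand_arithmetic(self):
        H, vocab, corpus = self._setting()
        scores = topic_coherence(H, vocab, corpus, top_n=2)
        # gamma/delta: df 3 each, joint 0 -> 2 * ln(1/4)
        assert scores[1] == pytest.approx(2 * np.log(1 / 4), abs=1e-12)

    def test_top_n_validation(self):
        H, vocab, corpus = self._setting()
        with pytest.raises(ValueError):
            topic_coherence(H, vocab, corpus, top_n=1)


class TestMatchTopics:
    def test_recovers_permutation(self):
        rng = np.random.default_rng(11)
        H = rng.random((5, 12))
        perm = np.array([3, 0, 4, 1, 2])
        scale = rng.uniform(0.5, 2.0, size=5)[:, None]
        H_est = H[perm] * scale
        got, cos = match_topics(H, H_est)
        # H_est[got[k]] should equal H[k] up to scale
        np.testing.assert_array_equal(np.argsort(perm), got)
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)
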