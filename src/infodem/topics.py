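"""Dynamic topic analysis: TF-IDF + NMF, fixed-basis projection, dynamics.

A reference corpus (news articles shared on a discussion platform) is
turned into a TF-IDF matrix X (|D| x |V|) and factorized as X ~ W H with
W, H >= 0 by minimizing the Frobenius reconstruction error with an
alternating projected-gradient solver.  The topic-term basis H is then held
fixed to project other corpora (e.g. all articles published by media
outlets) onto the same K topics, which makes interest directly comparable
across sources.

Per-topic dynamics: the strength ``s_k(t)`` is the daily sum of document
loadings on topic k, optionally weighted by per-document comment counts
(discussion corpora); the relevance ``R_k`` is the strength summed over the
analysis window; the half-relevance time ``t_half`` is the earliest day at
which the cumulative strength reaches R_k / 2; interest shares are
``100 * R_k / sum(R)`` per source, and their difference across sources
measures the attention mismatch per topic in percentage points.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import normalize as _l2_normalize

from .corpus import Corpus, tokenize


# --------------------------------------------------------------------------
# vocabulary and TF-IDF

@dataclass
class Vocabulary:
    """Ordered term list (unigrams + merged bigrams) with document counts."""

    terms: list[str]
    doc_freq: dict[str, int]
    n_docs: int
    bigrams: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


def _merge_bigrams(tokens: list[str], bigrams) -> list[str]:
    """Greedy left-to-right replacement of detected collocations."""
    if not bigrams:
        return tokens
    out = []
    i = 0
    while i < len(tokens):
        if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in bigrams:
            out.append(tokens[i] + "_" + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def _doc_tokens(doc) -> list[str]:
    return tokenize(doc.title + " " + doc.body)


def build_vocabulary(corpus: Corpus, min_df: int = 10,
                     bigram_min_count: int = 10,
                     collocation_threshold: float = 8.0) -> Vocabulary:
    """Build the term list for topic extraction.

    Adjacent token pairs with joint count >= ``bigram_min_count`` and
    pointwise mutual information (bits) >= ``collocation_threshold`` are
    merged into single bigram terms.  The default threshold is high on
    purpose: genuine phrases ("social distancing") are nearly always
    adjacent and score far above 10 bits, while terms that merely share a
    topic score around log2(#topics) bits and must not be merged.  Terms appearing in fewer than
    ``min_df`` documents are discarded.  Ordering is lexicographic, so the
    vocabulary is deterministic.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    token_lists = [_doc_tokens(d) for d in corpus]

    uni = Counter()
    pair = Counter()
    n_pairs = 0
    for toks in token_lists:
        uni.update(toks)
        for a, b in zip(toks, toks[1:]):
            pair[(a, b)] += 1
            n_pairs += 1
    n_tokens = sum(uni.values())

    bigrams = set()
    for (a, b), c in pair.items():
        if c < bigram_min_count:
            continue
        pmi = math.log2((c / n_pairs) /
                        ((uni[a] / n_tokens) * (uni[b] / n_tokens)))
        if pmi >= collocation_threshold:
            bigrams.add((a, b))

    df = Counter()
    for toks in token_lists:
        df.update(set(_merge_bigrams(toks, bigrams)))

    terms = sorted(t for t, c in df.items() if c >= min_df)
    if not terms:
        raise ValueError("vocabulary empty after min_df filtering")
    return Vocabulary(terms=terms,
                      doc_freq={t: df[t] for t in terms},
                      n_docs=len(corpus),
                      bigrams=frozenset(bigrams))


def doc_term_counts(corpus: Corpus, vocab: Vocabulary) -> sp.csr_matrix:
    """Raw bag-of-words counts, |D| x |V|, using the vocabulary's tokenizer
    conventions (bigram merges included)."""
    rows, cols, vals = [], [], []
    for i, doc in enumerate(corpus):
        counts = Counter(_merge_bigrams(_doc_tokens(doc), vocab.bigrams))
        for term, c in counts.items():
            j = vocab.index.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(len(corpus), len(vocab)), dtype=float)


def tfidf_matrix(corpus: Corpus, vocab: Vocabulary) -> sp.csr_matrix:
    """TF-IDF weighting with smoothed idf and L2-normalized rows.

    tf is the raw count; idf = ln((1 + N)/(1 + df)) + 1 with N and df taken
    from the reference corpus the vocabulary was built on, so projections of
    new corpora reuse the reference weighting.  Rows with no vocabulary
    term stay zero.
    """
    X = doc_term_counts(corpus, vocab)
    df = np.array([vocab.doc_freq[t] for t in vocab.terms], dtype=float)
    idf = np.log((1.0 + vocab.n_docs) / (1.0 + df)) + 1.0
    X = X.multiply(idf[None, :]).tocsr()
    return _l2_normalize(X, norm="l2", copy=False)


# --------------------------------------------------------------------------
# projected-gradient NMF

def _frob2(X, W, H, trXX: float) -> float:
    # ||X - WH||_F^2 without densifying X
    WtX = (X.T @ W) if sp.issparse(X) else X.T @ W
    G = W.T @ W
    return float(trXX - 2.0 * np.sum(np.asarray(WtX) * H.T)
                 + np.sum(G * (H @ H.T)))


def _pg_update(F: np.ndarray, G: np.ndarray, P: np.ndarray,
               n_steps: int) -> np.ndarray:
    """Projected-gradient steps for min_{F>=0} ||M - F G||^2 given
    P = M G^T and the Gram matrix GGt = G G^T (passed via closure args).

    F <- max(0, F - (F GGt - P)/L) with Lipschitz step L = ||GGt||_2,
    which decreases the objective monotonically.
    """
    GGt = G @ G.T
    L = float(np.linalg.norm(GGt, 2))
    if L == 0.0:
        return F
    for _ in range(n_steps):
        grad = F @ GGt - P
        F = np.maximum(0.0, F - grad / L)
    return F


class NMFTopicModel(BaseEstimator, TransformerMixin):
    """Nonnegative matrix factorization by alternating projected gradient.

    Minimizes ``||X - W H||_F^2`` subject to ``W, H >= 0``, alternating
    Lipschitz-stepped projected-gradient updates of W and H.  An optional
    L1 shrinkage (``sparseness``) can be applied to H at each update to
    encourage sparse topic bases; it is off by default.

    Parameters
    ----------
    n_topics : int, default 64
        Number of topics K.
    max_iter : int
        Outer alternation limit.
    tol : float
        Relative objective-decrease stopping threshold.
    random_state : int
        Seed for the nonnegative random initialization (entries uniform,
        scaled by sqrt(mean(X)/K)); runs are deterministic given the seed.
    inner_iter : int
        Projected-gradient steps per factor per outer iteration.
    sparseness : float
        L1 shrinkage applied to H (0 disables).

    Attributes
    ----------
    components_ : ndarray (K, |V|) — the topic-term basis H.
    objective_trace_ : list of ``||X - WH||_F^2`` values, non-increasing.
    reconstruction_err_ : final relative Frobenius error.
    n_iter_ : outer iterations run.
    """

    def __init__(self, n_topics: int = 64, max_iter: int = 300,
                 tol: float = 1e-5, random_state: int = 0,
                 inner_iter: int = 5, sparseness: float = 0.0):
        self.n_topics = n_topics
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.inner_iter = inner_iter
        self.sparseness = sparseness

    def _validate(self, X):
        if sp.issparse(X):
            if (X.data < 0).any():
                raise ValueError("X must be nonnegative")
            if not np.all(np.isfinite(X.data)):
                raise ValueError("X contains non-finite entries")
        else:
            X = np.asarray(X, dtype=float)
            if not np.all(np.isfinite(X)):
                raise ValueError("X contains non-finite entries")
            if (X < 0).any():
                raise ValueError("X must be nonnegative")
        return X

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = self._validate(X)
        n, m = X.shape
        K = self.n_topics
        if K >= min(n, m):
            raise ValueError(f"n_topics={K} must be < min{X.shape}")
        rng = np.random.default_rng(self.random_state)
        mean = float(X.mean())
        scale = math.sqrt(max(mean, np.finfo(float).tiny) / K)
        W = rng.random((n, K)) * scale
        H = rng.random((K, m)) * scale

        trXX = float((X.multiply(X)).sum()) if sp.issparse(X) \
            else float(np.sum(X * X))
        trace = [_frob2(X, W, H, trXX)]
        for it in range(self.max_iter):
            # update W: min ||X - W H||, rows of W
            P = np.asarray(X @ H.T)
            W = _pg_update(W, H, P, self.inner_iter)
            # update H via the transposed problem
            Q = np.asarray((X.T @ W)).T        # K x m
            Ht = _pg_update(H.T, W.T, Q.T, self.inner_iter)
            H = Ht.T
            if self.sparseness > 0.0:
                H = np.maximum(0.0, H - self.sparseness)
            f = _frob2(X, W, H, trXX)
            trace.append(f)
            prev = trace[-2]
            if prev > 0 and (prev - f) / prev < self.tol:
                break
        self.components_ = H
        self.objective_trace_ = trace
        self.n_iter_ = len(trace) - 1
        self.reconstruction_err_ = math.sqrt(max(trace[-1], 0.0) /
                                             max(trXX, np.finfo(float).tiny))
        return W

    def transform(self, X):
        """Project a corpus onto the fixed basis H: nonnegative least
        squares for W with the same solver and stopping rule as fit."""
        if not hasattr(self, "components_"):
            raise RuntimeError("model is not fitted")
        X = self._validate(X)
        H = self.components_
        if X.shape[1] != H.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} columns, basis expects {H.shape[1]}")
        n, K = X.shape[0], H.shape[0]
        rng = np.random.default_rng(self.random_state)
        mean = float(X.mean())
        W = rng.random((n, K)) * math.sqrt(max(mean, np.finfo(float).tiny) / K)
        P = np.asarray(X @ H.T)
        trXX = float((X.multiply(X)).sum()) if sp.issparse(X) \
            else float(np.sum(np.asarray(X) ** 2))
        prev = _frob2(X, W, H, trXX)
        for _ in range(self.max_iter):
            W = _pg_update(W, H, P, self.inner_iter)
            f = _frob2(X, W, H, trXX)
            if prev > 0 and (prev - f) / prev < self.tol:
                break
            prev = f
        return W


def nmf_fit(X, K: int, seed: int = 0, tol: float = 1e-5,
            max_iter: int = 300) -> tuple[NMFTopicModel, np.ndarray]:
    model = NMFTopicModel(n_topics=K, max_iter=max_iter, tol=tol,
                          random_state=seed)
    W = model.fit_transform(X)
    return model, W


def nmf_transform(X_new, model: NMFTopicModel) -> np.ndarray:
    return model.transform(X_new)


# --------------------------------------------------------------------------
# topic dynamics

def topic_strength_series(W: np.ndarray, timestamps: Sequence[dt.date],
                          weights=None,
                          window: tuple[dt.date, dt.date] | None = None,
                          ) -> tuple[np.ndarray, pd.DatetimeIndex]:
    """Daily topic strengths ``s_k(t) = sum_{i in D(t)} w_i W_ik``.

    ``weights`` default to 1 per document (news); pass comment counts for
    discussion corpora.  Returns a K x T array over the daily window plus
    its date index; days without documents are 0.
    """
    W = np.asarray(W, dtype=float)
    if len(timestamps) != W.shape[0]:
        raise ValueError("timestamps must align with W rows")
    if weights is None:
        w = np.ones(W.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if w.size != W.shape[0]:
            raise ValueError("weights must align with W rows")
    ts = pd.DatetimeIndex(pd.to_datetime(list(timestamps))).normalize()
    if window is None:
        window = (ts.min().date(), ts.max().date())
    idx = pd.date_range(window[0], window[1], freq="D")
    pos = idx.get_indexer(ts)
    if (pos < 0).any():
        raise ValueError("timestamps outside the analysis window")
    S = np.zeros((W.shape[1], len(idx)))
    np.add.at(S.T, pos, w[:, None] * W)
    return S, idx


def topic_relevance(strengths: np.ndarray) -> np.ndarray:
    """Relevance R_k: the strength integrated (summed) over the window."""
    S = np.asarray(strengths, dtype=float)
    if (S < 0).any():
        raise ValueError("strengths must be nonnegative")
    return S.sum(axis=1)


def topic_half_time(strengths: np.ndarray,
                    dates: pd.DatetimeIndex | None = None) -> list:
    """Earliest time at which each topic reaches half its total relevance.

    Topics with zero relevance get ``None`` (undefined).  Returns dates if
    an index is given, else integer positions.
    """
    S = np.asarray(strengths, dtype=float)
    R = topic_relevance(S)
    out = []
    cum = np.cumsum(S, axis=1)
    for k in range(S.shape[0]):
        if R[k] == 0:
            out.append(None)
            continue
        t = int(np.argmax(cum[k] >= R[k] / 2.0))
        out.append(dates[t].date() if dates is not None else t)
    return out


def interest_share_diff(R_source1: np.ndarray,
                        R_source2: np.ndarray) -> np.ndarray:
    """Per-topic difference of percentage interest shares (points).

    share_k = 100 R_k / sum(R) within each source; the differences sum to
    zero.  Positive entries mean source 1 dedicates proportionally more
    attention to the topic.
    """
    R1 = np.asarray(R_source1, dtype=float)
    R2 = np.asarray(R_source2, dtype=float)
    if R1.shape != R2.shape:
        raise ValueError("relevance vectors must have the same length")
    if (R1 < 0).any() or (R2 < 0).any():
        raise ValueError("relevance must be nonnegative")
    if R1.sum() <= 0 or R2.sum() <= 0:
        raise ValueError("each source needs positive total relevance")
    return 100.0 * R1 / R1.sum() - 100.0 * R2 / R2.sum()


def topic_coherence(H: np.ndarray, vocab: Vocabulary, corpus: Corpus,
                    top_n: int = 10) -> np.ndarray:
    """Document co-occurrence coherence per topic.

    For each topic's ``top_n`` highest-weight terms, sums
    ``ln((df(w_i, w_j) + 1) / (df(w_j) + 1))`` over ordered pairs of
    distinct terms, where df counts documents in ``corpus``.  Terms missing
    from the corpus contribute with df 0 under the +1 smoothing.  Higher is
    more coherent; the maximum for a given df configuration (0) is attained
    when top terms always co-occur.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    H = np.asarray(H, dtype=float)
    doc_sets = [set(_merge_bigrams(_doc_tokens(d), vocab.bigrams))
                for d in corpus]
    df = Counter()
    for s in doc_sets:
        df.update(s)
    scores = np.zeros(H.shape[0])
    for k in range(H.shape[0]):
        top = [vocab.terms[j] for j in np.argsort(-H[k])[:top_n]]
        s = 0.0
        for wi in top:
            for wj in top:
                if wi == wj:
                    continue
                joint = sum(1 for ds in doc_sets if wi in ds and wj in ds)
                s += math.log((joint + 1.0) / (df[wj] + 1.0))
        scores[k] = s
    return scores


def match_topics(H_true: np.ndarray, H_est: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment of estimated to true topics on cosine similarity.

    NMF is identifiable only up to permutation and scaling, so evaluation
    against planted topics matches rows first.  Returns (permutation such
    that ``H_est[perm[k]]`` corresponds to ``H_true[k]``, matched cosines).
    """
    from scipy.optimize import linear_sum_assignment

    A = np.asarray(H_true, dtype=float)
    B = np.asarray(H_est, dtype=float)
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    C = An @ Bn.T
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]
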