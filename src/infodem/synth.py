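"""Synthetic study inputs with known ground truth.

Every analysis stage in this package is exercised against data generated
here: a deterministic SIR incidence curve, a news series driven by lagged
incidence, an attention series generated by the memory-kernel regression
(Model III) with known coefficients, a timestamped two-source corpus with
planted topic-term structure / temporal bumps / per-topic comment affinity,
self-report location sentences, and a citation corpus with a planted shift
in home-country mention rates.  Each generator returns a machine-readable
truth record so recovery can be measured against the planted parameters.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`
(or the seed in :class:`SimConfig`); identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attention import build_memory_series
from .corpus import Corpus, Document, write_corpus
from .timeseries import make_series, write_timeseries, zscore


@dataclass
class EpiConfig:
    """Discrete-time SIR parameters for the incidence curves.

    The global epidemic is modelled as the same SIR system seeded much
    earlier (larger initial infected count), so the global curve peaks
    weeks before the domestic one — media coverage of a pandemic follows
    the world situation before the domestic outbreak erupts.
    """

    transmission_rate: float = 0.3   # per day
    recovery_rate: float = 0.1      # per day
    population: float = 1_000_000.0
    initial_infected: float = 10.0
    global_initial_infected: float = 5_000.0


@dataclass
class NewsConfig:
    """News volume driven by global + domestic incidence plus noise."""

    incidence_coefficient: float = 1.0
    global_weight: float = 0.7  # share of coverage tracking the global curve
    lag_days: int = 3
    noise_sd: float = 0.25  # relative to the driver sd


@dataclass
class AttentionConfig:
    """Model III generating process: planted saturation (alpha2 < 0)."""

    alpha1: float = 1.0
    alpha2: float = -0.45
    tau: float = 10.0
    noise_sd: float = 0.1  # applied after standardization


@dataclass
class TopicConfig:
    """Planted topic corpus: sparse topics, temporal bumps, comment affinity."""

    k_true: int = 8
    vocab_size: int = 400
    docs_per_day: float = 20.0
    concentration: float = 0.05     # Dirichlet concentration per term
    disjoint_supports: bool = False  # one vocab block per topic
    bump_centers: list | None = None  # default: evenly spaced in [10, 88]
    bump_width: float = 5.0          # days
    comment_affinity: list | None = None
    base_comments: float = 20.0
    nb_dispersion: float = 5.0
    doc_length: float = 60.0         # mean tokens per document
    background_mix: float = 0.1


@dataclass
class GeoConfig:
    n_users: int = 200
    report_rate: float = 0.8
    inconsistency_rate: float = 0.1


@dataclass
class SimConfig:
    seed: int = 0
    n_days: int = 98                       # Feb 7 - May 15 window length
    start: dt.date = dt.date(2020, 2, 7)
    epi: EpiConfig = field(default_factory=EpiConfig)
    news: NewsConfig = field(default_factory=NewsConfig)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    topics: TopicConfig = field(default_factory=TopicConfig)
    geoloc: GeoConfig = field(default_factory=GeoConfig)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_days, freq="D")


def gen_incidence(cfg: SimConfig, global_curve: bool = False) -> pd.Series:
    """Deterministic daily new cases from a discrete-time SIR recurrence.

    new_t = beta * S_t * I_t / N; S, I, R update accordingly.  Nonnegative
    and single-peaked for standard parameters; S + I + R is conserved.
    With ``global_curve`` the epidemic is seeded with the (much larger)
    global initial infected count, so it peaks earlier in the window.
    """
    epi = cfg.epi
    if epi.population <= 0:
        raise ValueError("population must be > 0")
    N = epi.population
    i0 = epi.global_initial_infected if global_curve else epi.initial_infected
    S = N - i0
    I = i0
    inc = np.zeros(cfg.n_days)
    for t in range(cfg.n_days):
        new = epi.transmission_rate * S * I / N
        rec = epi.recovery_rate * I
        S -= new
        I += new - rec
        inc[t] = new
    kind = "global_incidence" if global_curve else "incidence"
    return make_series(inc, cfg.dates(), kind=kind)


def gen_news(incidence: pd.Series, cfg: SimConfig,
             rng: np.random.Generator,
             global_incidence: pd.Series | None = None) -> pd.Series:
    """News volume: lagged mix of global and domestic incidence plus noise.

    Coverage of a pandemic tracks the world situation before (and while)
    the domestic outbreak unfolds, so the driver is
    ``w * global + (1 - w) * domestic`` lagged by the media delay, plus
    Gaussian noise (sd relative to the driver sd), floored at 0.  With no
    global curve supplied, the driver is the domestic curve alone.
    """
    news_cfg = cfg.news
    x = np.asarray(incidence, dtype=float)
    if global_incidence is not None:
        g = np.asarray(global_incidence, dtype=float)
        w = news_cfg.global_weight
        driver = w * g + (1.0 - w) * x
    else:
        driver = x
    if news_cfg.lag_days >= x.size:
        raise ValueError("lag must be smaller than the window")
    lagged = np.concatenate([np.zeros(news_cfg.lag_days),
                             driver[:driver.size - news_cfg.lag_days]])
    noise = rng.normal(0.0, news_cfg.noise_sd * driver.std(ddof=1), x.size)
    vals = np.maximum(0.0, news_cfg.incidence_coefficient * lagged + noise)
    return make_series(vals, incidence.index, kind="news")


def gen_attention(news: pd.Series, cfg: SimConfig,
                  rng: np.random.Generator) -> tuple[pd.Series, dict]:
    """Attention generated by Model III with planted (alpha1, alpha2, tau).

    The news series is z-scored, the memory series is built from the
    z-scored news (strictly past) and z-scored itself, and
    ``y = alpha1 * news_z + alpha2 * mem_z + noise``.  Returns the series
    plus a truth record holding the planted parameters and the exact
    regressors used.
    """
    att = cfg.attention
    news_z = zscore(news)
    mem = build_memory_series(news_z, att.tau, include_current_day=False)
    mem_z = zscore(mem)
    noise = rng.normal(0.0, att.noise_sd, len(news))
    y = att.alpha1 * np.asarray(news_z) + att.alpha2 * np.asarray(mem_z) \
        + noise
    series = make_series(y, news.index, kind="attention")
    truth = {"alpha1": att.alpha1, "alpha2": att.alpha2, "tau": att.tau,
             "noise_sd": att.noise_sd,
             "news_z": np.asarray(news_z), "mem_z": np.asarray(mem_z)}
    return series, truth


def _default_centers(k: int, n_days: int) -> np.ndarray:
    lo, hi = 0.1 * n_days, 0.9 * n_days
    return np.linspace(lo, hi, k)


def _default_affinity(k: int) -> np.ndarray:
    # alternating above/below 1 with margins, so planted share-difference
    # signs are well separated from the source average
    base = [2.0, 0.5, 1.6, 0.6, 1.5, 0.7, 1.4, 0.8]
    reps = int(np.ceil(k / len(base)))
    return np.array((base * reps)[:k])


def gen_topic_corpus(cfg: SimConfig, rng: np.random.Generator,
                     n_docs: int | None = None,
                     truth: dict | None = None
                     ) -> tuple[Corpus, Corpus, dict]:
    """Two-source corpus with planted topic structure.

    Topic-term distributions are sparse Dirichlet draws over a synthetic
    vocabulary; each document mixes its dominant topic with a uniform
    background, draws Poisson-length token counts multinomially, and gets a
    timestamp from the topic's Gaussian temporal bump.  The discussion-side
    copy of each document receives a negative-binomial comment count whose
    mean is scaled by the topic's planted comment affinity.  The truth
    record carries the topic-term matrix, per-document labels, bump
    centers, affinities and the expected interest-share difference signs.

    Passing a previous call's ``truth`` reuses its planted topic-term
    matrix, centers and affinities, so held-out documents can be generated
    from the same topics.
    """
    tc = cfg.topics
    if tc.k_true < 2:
        raise ValueError("need at least 2 planted topics")
    if tc.vocab_size < 10 * tc.k_true:
        raise ValueError("vocab too small to separate topics "
                         "(need >= 10 * k_true)")
    K, V = tc.k_true, tc.vocab_size
    vocab = [f"term{j:04d}" for j in range(V)]
    if truth is not None:
        topic_term = truth["topic_term"]
        centers = truth["centers"]
        affinity = truth["affinity"]
    else:
        centers = np.asarray(tc.bump_centers if tc.bump_centers is not None
                             else _default_centers(K, cfg.n_days),
                             dtype=float)
        if centers.min() < 0 or centers.max() > cfg.n_days:
            raise ValueError("bump centers outside the analysis window")
        affinity = np.asarray(tc.comment_affinity if tc.comment_affinity
                              is not None else _default_affinity(K),
                              dtype=float)
        if tc.disjoint_supports:
            block = V // K
            topic_term = np.zeros((K, V))
            for k in range(K):
                sl = slice(k * block, (k + 1) * block)
                topic_term[k, sl] = rng.dirichlet(
                    np.full(block, tc.concentration))
        else:
            topic_term = rng.dirichlet(np.full(V, tc.concentration), size=K)
    background = topic_term.mean(axis=0)

    if n_docs is None:
        n_docs = int(round(tc.docs_per_day * cfg.n_days))
    labels = rng.integers(0, K, size=n_docs)
    days = np.clip(np.rint(rng.normal(centers[labels], tc.bump_width)),
                   0, cfg.n_days - 1).astype(int)
    lengths = rng.poisson(tc.doc_length, size=n_docs)

    mean_c = tc.base_comments * affinity[labels]
    r = tc.nb_dispersion
    comments = rng.negative_binomial(r, r / (r + mean_c))

    news_docs, reddit_docs = [], []
    dates = cfg.dates()
    for i in range(n_docs):
        p = (1.0 - tc.background_mix) * topic_term[labels[i]] \
            + tc.background_mix * background
        counts = rng.multinomial(lengths[i], p)
        toks = np.repeat(np.arange(V), counts)
        rng.shuffle(toks)  # interleave terms as in real text
        body = " ".join(vocab[j] for j in toks)
        ts = dates[days[i]].date()
        news_docs.append(Document(id=f"n{i:06d}", timestamp=ts,
                                  source="news", body=body))
        reddit_docs.append(Document(id=f"r{i:06d}", timestamp=ts,
                                    source="reddit_submission", body=body,
                                    comment_count=int(comments[i])))

    exp_sign = np.sign(affinity - affinity.mean())
    truth = {"topic_term": topic_term, "labels": labels,
             "days": days, "centers": centers, "affinity": affinity,
             "expected_share_sign": exp_sign, "vocab": vocab,
             "comments": comments}
    return Corpus(news_docs), Corpus(reddit_docs), truth


_REPORT_TEMPLATES = (
    "I am from {place} and I have been following the outbreak closely.",
    "I live in {place} and things changed fast here.",
    "I'm from {place}, the situation is tense.",
)


def gen_self_report_texts(cfg: SimConfig, rng: np.random.Generator,
                          places_by_country: dict[str, list[str]]
                          ) -> tuple[Corpus, dict]:
    """Self-report sentences with known user countries.

    Each reporting user posts one sentence naming a place of their true
    country; an ``inconsistency_rate`` fraction posts a second sentence
    naming a place from a different country (these users must resolve to
    no country).  Truth maps author_id -> expected assignment (ISO code or
    None).
    """
    gc = cfg.geoloc
    countries = sorted(places_by_country)
    if len(countries) < 2:
        raise ValueError("need places from at least 2 countries")
    docs, truth = [], {}
    doc_i = 0
    start = cfg.start
    for u in range(gc.n_users):
        author = f"user{u:05d}"
        if rng.random() >= gc.report_rate:
            continue
        home = countries[rng.integers(len(countries))]
        place = places_by_country[home][
            rng.integers(len(places_by_country[home]))]
        tmpl = _REPORT_TEMPLATES[rng.integers(len(_REPORT_TEMPLATES))]
        ts = start + dt.timedelta(days=int(rng.integers(cfg.n_days)))
        docs.append(Document(id=f"s{doc_i:06d}", timestamp=ts,
                             source="reddit_comment",
                             body=tmpl.format(place=place),
                             author_id=author))
        doc_i += 1
        if rng.random() < gc.inconsistency_rate:
            other = countries[rng.integers(len(countries))]
            while other == home:
                other = countries[rng.integers(len(countries))]
            place2 = places_by_country[other][
                rng.integers(len(places_by_country[other]))]
            docs.append(Document(id=f"s{doc_i:06d}", timestamp=ts,
                                 source="reddit_comment",
                                 body=f"I live in {place2} right now.",
                                 author_id=author))
            doc_i += 1
            truth[author] = None
        else:
            truth[author] = home
    return Corpus(docs), truth


def gen_citation_corpus(rng: np.random.Generator,
                        home_places: list[str],
                        foreign_places: list[str],
                        split_date: dt.date,
                        window: tuple[dt.date, dt.date],
                        n_docs: int = 2000,
                        before_home_rate: float = 0.29,
                        after_home_rate: float = 0.74) -> tuple[Corpus, dict]:
    """News corpus with a planted shift in home-country mention share.

    Each document mentions one place.  Documents are split evenly between
    the two partitions and within each partition exactly
    ``round(rate * n)`` documents mention a home-country location (the rest
    a foreign one), so the planted shares are exact up to rounding;
    timestamps and place choices are randomized.
    """
    t0, tf = window
    if not (t0 < split_date <= tf):
        raise ValueError("split date outside the corpus window")
    n_before = n_docs // 2
    plan = []
    for period, n_part, rate in (("before", n_before, before_home_rate),
                                 ("after", n_docs - n_before,
                                  after_home_rate)):
        n_home = int(round(rate * n_part))
        flags = np.zeros(n_part, dtype=bool)
        flags[:n_home] = True
        rng.shuffle(flags)
        plan.append((period, flags))
    docs = []
    i = 0
    for period, flags in plan:
        if period == "before":
            lo, span = 0, (split_date - t0).days
        else:
            lo, span = (split_date - t0).days, \
                (tf - split_date).days + 1
        for is_home in flags:
            ts = t0 + dt.timedelta(days=lo + int(rng.integers(span)))
            pool = home_places if is_home else foreign_places
            place = pool[rng.integers(len(pool))]
            docs.append(Document(id=f"c{i:06d}", timestamp=ts,
                                 source="news",
                                 body=f"Officials in {place} reported "
                                      f"new measures today."))
            i += 1
    truth = {"before_home_rate": before_home_rate,
             "after_home_rate": after_home_rate}
    return Corpus(docs), truth


def simulate(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Run every generator and write CSV/JSONL fixtures plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    incidence = gen_incidence(cfg)
    global_inc = gen_incidence(cfg, global_curve=True)
    news = gen_news(incidence, cfg, rng, global_incidence=global_inc)
    attention, att_truth = gen_attention(news, cfg, rng)
    write_timeseries(incidence, out / "incidence.csv")
    write_timeseries(global_inc, out / "global_incidence.csv")
    write_timeseries(news, out / "news.csv")
    write_timeseries(attention, out / "attention.csv")

    corpus_news, corpus_reddit, topic_truth = gen_topic_corpus(cfg, rng)
    write_corpus(corpus_news, out / "corpus_news.jsonl")
    write_corpus(corpus_reddit, out / "corpus_reddit.jsonl")

    truth = {
        "seed": cfg.seed,
        "attention": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in att_truth.items()},
        "topics": {
            "centers": topic_truth["centers"].tolist(),
            "affinity": topic_truth["affinity"].tolist(),
            "labels": topic_truth["labels"].tolist(),
            "expected_share_sign":
                topic_truth["expected_share_sign"].tolist(),
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
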