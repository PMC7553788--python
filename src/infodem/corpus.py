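"""Document corpora: JSON-Lines I/O, keyword relevance filters and Reddit cleaning.

A :class:`Document` is one timestamped record (news article, YouTube video,
Reddit submission or comment).  Corpora are exchanged as JSON-Lines, one
record per line, with ISO-8601 dates.  The filters implement the relevance
and quality rules used when assembling a pandemic discussion data set:
keyword relevance on titles/bodies, a vote-score floor for submissions, and
length / duplicate rules that strip automated moderator messages from
comment streams.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

SOURCE_KINDS = ("news", "reddit_submission", "reddit_comment", "youtube")

#: keyword list used to select relevant news articles
NEWS_KEYWORDS = ["coronavirus", "covid19", "covid-19", "ncov-19", "sars-cov-2"]
#: keyword list used to select relevant YouTube videos
YOUTUBE_KEYWORDS = ["coronavirus", "virus", "covid", "covid19", "sars",
                    "sars-cov-2", "sarscov2"]

# word tokens: alphanumeric runs, keeping internal hyphens so "covid-19"
# survives as a single token
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; internal hyphens are part of the token."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Document:
    id: str
    timestamp: dt.date
    source: str
    title: str = ""
    body: str = ""
    score: int = 0
    comment_count: int = 0
    author_id: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.source!r}")
        if self.comment_count < 0:
            raise ValueError("comment_count must be >= 0")

    def to_record(self) -> dict:
        rec = self.__dict__.copy()
        rec["timestamp"] = self.timestamp.isoformat()
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        return cls(
            id=str(rec["id"]),
            timestamp=dt.date.fromisoformat(str(rec["timestamp"])[:10]),
            source=str(rec["source"]),
            title=str(rec.get("title", "")),
            body=str(rec.get("body", "")),
            score=int(rec.get("score", 0)),
            comment_count=int(rec.get("comment_count", 0)),
            author_id=str(rec.get("author_id", "")),
        )


@dataclass
class Corpus:
    """An ordered collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)
    n_skipped: int = 0  # malformed records dropped while reading

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1][:3]
            raise ValueError(f"duplicate document ids in corpus: {dup}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def subset(self, keep: Iterable[Document]) -> "Corpus":
        keep = list(keep)
        return Corpus(documents=keep)


def read_corpus(path: str | Path, source_kind: str | None = None) -> Corpus:
    """Read a JSON-Lines corpus.

    Malformed lines are skipped and counted on the returned corpus; more
    than 50% malformed lines raises (the file is likely not in the expected
    format).  ``source_kind``, when given, overrides the per-record field.
    """
    path = Path(path)
    docs: list[Document] = []
    skipped = 0
    total = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            total += 1
            try:
                rec = json.loads(line)
                if source_kind is not None:
                    rec["source"] = source_kind
                docs.append(Document.from_record(rec))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError):
                skipped += 1
    if total == 0:
        logger.warning("corpus file %s is empty", path)
    elif skipped * 2 > total:
        raise ValueError(
            f"{path}: {skipped}/{total} records malformed; wrong format?")
    if skipped:
        logger.warning("corpus file %s: skipped %d malformed records",
                       path, skipped)
    corpus = Corpus(documents=docs)
    corpus.n_skipped = skipped
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc.to_record(), sort_keys=True) + "\n")


@dataclass
class KeywordFilterSpec:
    """Case-insensitive whole-token keyword relevance filter."""

    keywords: Sequence[str]
    fields_searched: Sequence[str] = ("title", "body")

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be non-empty")
        bad = set(self.fields_searched) - {"title", "body"}
        if bad:
            raise ValueError(f"unknown searchable fields: {sorted(bad)}")
        self.keywords = [k.lower() for k in self.keywords]


def filter_by_keywords(corpus: Corpus, spec: KeywordFilterSpec) -> Corpus:
    """Retain documents citing at least one keyword as a token.

    Matching is case-insensitive on word tokens (hyphenated terms count as
    one token), over the fields named in ``spec``; document order is kept.
    """
    kw = set(spec.keywords)
    kept = []
    for doc in corpus:
        tokens: set[str] = set()
        for f in spec.fields_searched:
            tokens.update(tokenize(getattr(doc, f)))
        if tokens & kw:
            kept.append(doc)
    return corpus.subset(kept)


def clean_reddit(
    submissions: Corpus,
    comments: Corpus,
    min_score: int = 2,
    min_chars: int = 10,
    max_duplicates: int = 3,
) -> tuple[Corpus, Corpus, dict]:
    """Apply the Reddit quality rules.

    Submissions with vote score <= 1 (i.e. below ``min_score``) are dropped
    as likely spam.  Comments shorter than ``min_chars`` code points (after
    stripping surrounding whitespace) are dropped, and any comment body
    occurring more than ``max_duplicates`` times has *all* its occurrences
    dropped — repeated identical bodies are automated moderator messages.
    Returns the filtered corpora and a removal-count dict.
    """
    subs_kept = [d for d in submissions if d.score >= min_score]

    long_enough = [d for d in comments if len(d.body.strip()) >= min_chars]
    body_counts = Counter(d.body for d in comments)
    com_kept = [d for d in long_enough
                if body_counts[d.body] <= max_duplicates]

    counts = {
        "submissions_removed": len(submissions) - len(subs_kept),
        "comments_removed_short": len(comments) - len(long_enough),
        "comments_removed_duplicate": len(long_enough) - len(com_kept),
    }
    return submissions.subset(subs_kept), comments.subset(com_kept), counts
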