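"""User geolocation from self-report phrases and gazetteer citation counts.

Discussion platforms rarely expose user locations, but users volunteer them
in text ("I live in Toronto, so ...").  Trigger phrases are matched
case-insensitively, the short span that follows is looked up in a bundled
gazetteer (country names, demonyms and major cities of the study countries
plus China), and a user is assigned a country only when every resolved
self-report agrees — inconsistent self-reporting yields no assignment.

The same gazetteer supports a location-citation statistic: the share of
home-country versus foreign-country place mentions in news text, split at a
reference date (e.g. the first domestic death), which captures how coverage
pivots from the global to the domestic outbreak.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import Corpus

_ISO2_RE = re.compile(r"^[A-Z]{2}$")

TRIGGER_PHRASES = ("i am from", "i'm from", "i live in")
_TRIGGER_RE = re.compile(r"\b(?:i am from|i'm from|i live in)\b\s+",
                         re.IGNORECASE)
# candidate span: up to 4 word tokens, stopping at punctuation
_SPAN_RE = re.compile(r"([^\W_]+(?:[ \t][^\W_]+){0,3})", re.UNICODE)


@dataclass
class Gazetteer:
    """Lowercase surface form -> ISO-3166 alpha-2 country code."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for surface, code in self.entries.items():
            if surface != surface.lower():
                raise ValueError(f"surface form not lowercase: {surface!r}")
            if not _ISO2_RE.match(code):
                raise ValueError(f"bad country code {code!r} for {surface!r}")

    @property
    def codes(self) -> set[str]:
        return set(self.entries.values())

    def lookup(self, phrase: str) -> str | None:
        return self.entries.get(phrase.lower().strip())


def load_gazetteer(path: str | Path | None = None) -> Gazetteer:
    """Load a two-column ``surface_form,country`` CSV.

    Defaults to the bundled gazetteer.  Surface forms mapping to more than
    one country are dropped (precision over recall).
    """
    if path is None:
        src = resources.files("infodem.data").joinpath("gazetteer.csv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    seen: dict[str, set[str]] = defaultdict(set)
    for row in csv.DictReader(text.splitlines()):
        seen[row["surface_form"].strip().lower()].add(row["country"].strip())
    entries = {s: next(iter(c)) for s, c in seen.items() if len(c) == 1}
    return Gazetteer(entries=entries)


def extract_self_reports(corpus: Corpus) -> list[tuple[str, str]]:
    """Find (author_id, candidate place phrase) pairs.

    After each trigger phrase the following tokens are captured, up to the
    next punctuation mark or four tokens, whichever comes first; candidates
    are lowercased.
    """
    out = []
    for doc in corpus:
        text = doc.title + " " + doc.body
        for m in _TRIGGER_RE.finditer(text):
            span = _SPAN_RE.match(text, m.end())
            if span:
                out.append((doc.author_id, span.group(1).lower()))
    return out


@dataclass
class UserLocation:
    author_id: str
    country: str | None
    evidence: list = field(default_factory=list)


def _resolve_candidate(candidate: str, gaz: Gazetteer) -> str | None:
    """Gazetteer lookup, trying the longest leading token span first and
    ignoring a leading article."""
    tokens = candidate.split()
    if tokens and tokens[0] == "the":
        tokens = tokens[1:]
    for k in range(min(4, len(tokens)), 0, -1):
        code = gaz.lookup(" ".join(tokens[:k]))
        if code is not None:
            return code
    return None


def resolve_user_country(candidates: list[tuple[str, str]],
                         gaz: Gazetteer) -> list[UserLocation]:
    """Assign a country per user from resolved self-report candidates.

    Unresolvable candidates are ignored; users whose resolved candidates
    disagree get no country (inconsistent self-reporting is removed).
    """
    by_user: dict[str, list[str]] = defaultdict(list)
    resolved: dict[str, list[str]] = defaultdict(list)
    for author, cand in candidates:
        by_user[author].append(cand)
        code = _resolve_candidate(cand, gaz)
        if code is not None:
            resolved[author].append(code)
    out = []
    for author in sorted(by_user):
        codes = set(resolved.get(author, []))
        if len(codes) == 1:
            out.append(UserLocation(author, codes.pop(),
                                    evidence=by_user[author]))
        else:
            out.append(UserLocation(author, None, evidence=[]))
    return out


def _mention_regex(gaz: Gazetteer) -> re.Pattern:
    forms = sorted(gaz.entries, key=len, reverse=True)
    return re.compile(r"\b(" + "|".join(re.escape(f) for f in forms) + r")\b")


@dataclass
class CitationShares:
    """Home-country share of (home + foreign) place mentions, per period."""

    before: float | None
    after: float | None
    counts: dict = field(default_factory=dict)


def citation_shares(corpus: Corpus, gaz: Gazetteer, home_country: str,
                    foreign_country: str,
                    split_date: dt.date) -> CitationShares:
    """Share of home vs foreign location citations before/after a date.

    Counts gazetteer surface-form occurrences in document bodies that map
    to either country; documents dated strictly before ``split_date`` fall
    in the "before" partition.  A partition with zero mentions has an
    undefined (None) share.
    """
    pat = _mention_regex(gaz)
    counts = Counter()
    for doc in corpus:
        period = "before" if doc.timestamp < split_date else "after"
        for m in pat.finditer(doc.body.lower()):
            code = gaz.entries[m.group(1)]
            if code == home_country:
                counts[(period, "home")] += 1
            elif code == foreign_country:
                counts[(period, "foreign")] += 1

    def share(period: str) -> float | None:
        h = counts[(period, "home")]
        f = counts[(period, "foreign")]
        return h / (h + f) if h + f > 0 else None

    return CitationShares(before=share("before"), after=share("after"),
                          counts=dict(counts))
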