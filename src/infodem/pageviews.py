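"""Country attribution of per-article page views.

Page-view APIs report raw daily visits to an article from a whole language
project (e.g. an English-language encyclopedia edition), not from a country.
Daily article views are therefore weighted by the country's share of the
project's *monthly* traffic:

    v_{a,p,c}(d) = S_{a,p}(d) * views_c(p, month(d)) / views_total(p, month(d))

and the per-country daily attention volume is the sum of these weighted
views over all articles and projects.  The weight lies in [0, 1], so a
country is never attributed more views than the article received.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import make_series

TOTAL_COUNTRY = "__total__"


@dataclass(frozen=True)
class ArticleDailyViews:
    article: str
    project: str
    date: dt.date
    views: int

    def __post_init__(self) -> None:
        if self.views < 0:
            raise ValueError("views must be >= 0")


class MonthlyProjectViews:
    """Monthly per-country and total view counts per project.

    Backed by a ``project,country,month,views`` table where rows with
    ``country == "__total__"`` carry the project-wide monthly totals used
    as normalization denominators.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"project", "country", "month", "views"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"monthly table missing columns {sorted(missing)}")
        t = table.copy()
        t["month"] = t["month"].astype(str).str[:7]  # YYYY-MM
        if (t["views"] < 0).any():
            raise ValueError("monthly views must be >= 0")
        self._by_key = {(r.project, r.country, r.month): float(r.views)
                        for r in t.itertuples()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "MonthlyProjectViews":
        return cls(pd.read_csv(path))

    def weight(self, project: str, month: str, country: str) -> float:
        """Country share of the project's monthly views, in [0, 1]."""
        total = self._by_key.get((project, TOTAL_COUNTRY, month))
        if total is None or total <= 0:
            raise ValueError(
                f"no positive monthly total for project={project!r} "
                f"month={month}")
        share = self._by_key.get((project, country, month), 0.0)
        if share > total:
            raise ValueError(
                f"country views exceed project total for {project!r} {month}")
        return share / total


def _month_key(date: dt.date) -> str:
    return f"{date.year:04d}-{date.month:02d}"


def normalize_article_views(rec: ArticleDailyViews,
                            monthly: MonthlyProjectViews,
                            country: str) -> float:
    """Weight one article-day view count by the country's monthly share of
    the article's project.  Result lies in [0, rec.views]."""
    w = monthly.weight(rec.project, _month_key(rec.date), country)
    return rec.views * w


def country_daily_volume(records: list[ArticleDailyViews],
                         monthly: MonthlyProjectViews,
                         country: str,
                         window: tuple[dt.date, dt.date] | None = None,
                         ) -> pd.Series:
    """Per-country daily attention volume: the sum of country-weighted views
    over all articles and projects.  Days without records are 0."""
    if window is None:
        if not records:
            raise ValueError("empty record list requires an explicit window")
        dates = [r.date for r in records]
        window = (min(dates), max(dates))
    idx = pd.date_range(window[0], window[1], freq="D")
    values = pd.Series(0.0, index=idx)
    for rec in records:
        values[pd.Timestamp(rec.date)] += normalize_article_views(
            rec, monthly, country)
    out = make_series(values.to_numpy(), idx, country=country,
                      kind="pageviews")
    return out


def read_article_views(path: str | Path) -> list[ArticleDailyViews]:
    df = pd.read_csv(path, parse_dates=["date"])
    return [ArticleDailyViews(article=str(r.article), project=str(r.project),
                              date=r.date.date(), views=int(r.views))
            for r in df.itertuples()]
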