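"""Date-indexed signal handling: CSV interchange, z-scoring, weekly binning.

Series are plain :class:`pandas.Series` with a ``DatetimeIndex``; the country
and signal kind ("incidence", "news", "attention", "pageviews") travel in
``Series.attrs`` and in the CSV interchange format
``date,country,kind,value``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def make_series(values, index, country: str = "", kind: str = "") -> pd.Series:
    s = pd.Series(np.asarray(values, dtype=float),
                  index=pd.DatetimeIndex(index))
    s.attrs["country"] = country
    s.attrs["kind"] = kind
    return s


def read_timeseries(path: str | Path, country: str | None = None,
                    kind: str | None = None) -> pd.Series:
    """Read one ``date,country,kind,value`` series; filters are optional but
    the remaining rows must form a single (country, kind) pair."""
    df = pd.read_csv(path, parse_dates=["date"])
    if country is not None:
        df = df[df["country"] == country]
    if kind is not None:
        df = df[df["kind"] == kind]
    if df.empty:
        raise ValueError(f"{path}: no rows match country={country} kind={kind}")
    pairs = df[["country", "kind"]].drop_duplicates()
    if len(pairs) > 1:
        raise ValueError(f"{path}: multiple series present; pass country/kind")
    df = df.sort_values("date")
    return make_series(df["value"].to_numpy(), df["date"],
                       country=str(df["country"].iloc[0]),
                       kind=str(df["kind"].iloc[0]))


def write_timeseries(series: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({
        "date": series.index.strftime("%Y-%m-%d"),
        "country": series.attrs.get("country", ""),
        "kind": series.attrs.get("kind", ""),
        "value": series.to_numpy(),
    })
    df.to_csv(path, index=False)


def zscore(series):
    """Standardize to sample mean 0 and sample sd 1 (ddof=1).

    Accepts a pandas Series or a numpy array and returns the same type.
    Raises on length < 2 or zero variance.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("z-score undefined for a constant series")
    z = (x - x.mean()) / sd
    if isinstance(series, pd.Series):
        out = pd.Series(z, index=series.index)
        out.attrs.update(series.attrs)
        return out
    return z


def weekly_aggregate(series: pd.Series) -> pd.Series:
    """Sum a daily series over ISO weeks (Monday-anchored).

    The output is labeled by each week's Monday.  Total mass is conserved.
    Partial weeks at either edge of the window are kept and listed in
    ``attrs["partial_weeks"]``.
    """
    if len(series) == 0:
        out = pd.Series(dtype=float)
        out.attrs.update(series.attrs)
        out.attrs["partial_weeks"] = []
        return out
    idx = pd.DatetimeIndex(series.index)
    mondays = idx - pd.to_timedelta(idx.weekday, unit="D")
    out = series.groupby(mondays).sum()
    out.index.name = None
    counts = pd.Series(1, index=idx).groupby(mondays).sum()
    out.attrs.update(series.attrs)
    out.attrs["partial_weeks"] = [d.date().isoformat()
                                  for d in counts.index[counts < 7]]
    return out
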