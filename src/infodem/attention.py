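"""Collective-attention regression: memory kernel, Models I-III, model tests.

The public response ``y_t`` (discussion-comment volume or page-view volume)
is regressed on epidemic incidence and/or media coverage:

    Model I:    y_t = a1 * incidence_t            + u_t
    Model II:   y_t = a1 * news_t                 + u_t
    Model III:  y_t = a1 * news_t + a2 * newsMEM_t + u_t

where ``newsMEM_t = sum_{t' < t} news_{t'} exp(-(t - t')/tau)`` is an
exponentially decayed cumulative news exposure with memory time scale
``tau`` (days).  ``tau`` is tuned over an integer grid (default 1..45) by
maximizing the adjusted coefficient of determination of Model III.  A
negative ``a2`` is the signature of attention saturation: the public
response declines while coverage remains high.

Model III is compared against Model II with the exact F test for nested
OLS models, and against Model I with the classical Cox test for non-nested
linear regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .timeseries import zscore

MODEL_REGRESSORS = {
    "I": ["incidence"],
    "II": ["news"],
    "III": ["news", "newsMEM"],
}

DEFAULT_TAU_GRID = tuple(range(1, 46))


def build_memory_series(news, tau: float, include_current_day: bool = False):
    """Exponentially decayed cumulative news exposure.

    ``mem_t = sum over past t' of news_{t'} * exp(-(t - t')/tau)``, where the
    sum runs over strictly past steps by default (``mem_0 = 0``); with
    ``include_current_day`` the current step enters with weight 1.  The
    series index/length is preserved.  Linear in the input.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.asarray(news, dtype=float)
    n = x.size
    lag = np.arange(n)[:, None] - np.arange(n)[None, :]
    keep = lag > 0 if not include_current_day else lag >= 0
    W = np.where(keep, np.exp(-np.where(keep, lag, 0) / float(tau)), 0.0)
    mem = W @ x
    if isinstance(news, pd.Series):
        out = pd.Series(mem, index=news.index)
        out.attrs.update(news.attrs)
        return out
    return mem


@dataclass
class RegressionFit:
    """OLS fit of one attention model (no intercept)."""

    model_id: str
    regressors: list[str]
    coefficients: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]
    residuals: np.ndarray
    rss: float
    n: int
    p: int
    r2: float
    r2_adj: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.conf_intervals.items():
            b = self.coefficients[name]
            if not (lo <= b <= hi):
                raise ValueError(f"CI for {name} does not bracket estimate")


def _design(y, covariates: Mapping[str, object], names: Sequence[str],
            standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    yv = np.asarray(y, dtype=float)
    cols = []
    for name in names:
        if name not in covariates:
            raise ValueError(f"missing covariate {name!r}")
        col = np.asarray(covariates[name], dtype=float)
        if col.size != yv.size:
            raise ValueError(f"covariate {name!r} length mismatch")
        cols.append(zscore(col) if standardize else col)
    X = np.column_stack(cols)
    return yv, X


def ols_fit(y, covariates: Mapping[str, object],
            standardize: bool = False,
            model_id: str = "custom") -> RegressionFit:
    """No-intercept OLS on an arbitrary named design.

    The core behind :func:`fit_model`: classical 95% t-intervals from the
    OLS coefficient covariance, RSS, and adjusted R² computed against the
    centered total sum of squares.
    """
    names = list(covariates)
    yv, X = _design(y, covariates, names, standardize)
    return _ols(yv, X, names, model_id)


def fit_model(y, model_id: str, covariates: Mapping[str, object],
              standardize: bool = True) -> RegressionFit:
    """Fit one of Models I-III by OLS without an intercept.

    ``standardize`` z-scores each regressor (the response is taken as given;
    normalize it upstream with :func:`infodem.timeseries.zscore` when
    standardized coefficients are wanted).  Confidence intervals are the
    classical 95% t-intervals from the OLS coefficient covariance.
    """
    if model_id not in MODEL_REGRESSORS:
        raise ValueError(f"unknown model {model_id!r}")
    names = MODEL_REGRESSORS[model_id]
    yv, X = _design(y, covariates, names, standardize)
    return _ols(yv, X, names, model_id)


def _ols(yv: np.ndarray, X: np.ndarray, names: Sequence[str],
         model_id: str) -> RegressionFit:
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient design; collinear regressors "
                         f"among {names}")
    res = sm.OLS(yv, X).fit()
    ci = res.conf_int(alpha=0.05)
    tss = float(((yv - yv.mean()) ** 2).sum())
    rss = float(res.ssr)
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return RegressionFit(
        model_id=model_id,
        regressors=list(names),
        coefficients={nm: float(b) for nm, b in zip(names, res.params)},
        conf_intervals={nm: (float(ci[i, 0]), float(ci[i, 1]))
                        for i, nm in enumerate(names)},
        residuals=np.asarray(res.resid, dtype=float),
        rss=rss, n=n, p=p, r2=r2, r2_adj=r2_adj,
    )


def model_iii_covariates(news, tau: float,
                         include_current_day: bool = False) -> dict:
    """Standardized news plus the memory series built from standardized news.

    The memory term is computed on the z-scored news signal so that its
    scale is comparable across countries; it is itself z-scored again inside
    :func:`fit_model` when ``standardize`` is on.
    """
    news_z = zscore(news)
    mem = build_memory_series(news_z, tau, include_current_day)
    return {"news": news_z, "newsMEM": mem}


@dataclass
class TauProfile:
    tau_best: float
    fits: dict
    r2_adj: dict


def tune_tau(y, news, grid: Iterable[float] = DEFAULT_TAU_GRID,
             include_current_day: bool = False,
             standardize: bool = True) -> TauProfile:
    """Tune the memory time scale by maximizing Model III's adjusted R².

    Fits Model III at every grid value; ties go to the smallest tau (the
    shortest memory consistent with the data).  The full profile is returned
    for diagnostics.
    """
    grid = list(grid)
    if not grid or any(t <= 0 for t in grid) or \
            any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("tau grid must be non-empty, positive, increasing")
    fits = {}
    best_tau, best_r2 = None, -np.inf
    for tau in grid:
        cov = model_iii_covariates(news, tau, include_current_day)
        fit = fit_model(y, "III", cov, standardize=standardize)
        fits[tau] = fit
        if fit.r2_adj > best_r2:
            best_tau, best_r2 = tau, fit.r2_adj
    return TauProfile(tau_best=best_tau, fits=fits,
                      r2_adj={t: f.r2_adj for t, f in fits.items()})


@dataclass
class ModelComparison:
    test: str
    statistic: float
    p_value: float
    winner: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def f_test_nested(fit_restricted: RegressionFit,
                  fit_full: RegressionFit,
                  alpha: float = 0.05) -> ModelComparison:
    """Exact F test of a restricted OLS model against a nesting full model.

    F = ((RSS_r - RSS_f)/(p_f - p_r)) / (RSS_f/(n - p_f)), with p-value from
    F(p_f - p_r, n - p_f).
    """
    if not set(fit_restricted.regressors) < set(fit_full.regressors):
        raise ValueError("models are not nested")
    if fit_restricted.n != fit_full.n:
        raise ValueError("fits use different sample sizes")
    n = fit_full.n
    dp = fit_full.p - fit_restricted.p
    dfe = n - fit_full.p
    num = (fit_restricted.rss - fit_full.rss) / dp
    den = fit_full.rss / dfe
    F = num / den if den > 0 else np.inf
    F = max(F, 0.0)
    p = float(stats.f.sf(F, dp, dfe))
    winner = fit_full.model_id if p < alpha else None
    return ModelComparison(test="f_nested", statistic=float(F), p_value=p,
                           winner=winner)


def _ols_fit_resid(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return fitted, y - fitted


def _cox_direction(y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Cox statistic for H0: the X regression is the true model.

    Classical variance-comparison form for two non-nested linear
    regressions: the difference of fitted log-variances is centered by its
    estimated expectation under H0 and studentized; asymptotically N(0, 1).
    """
    n = y.size
    fit_x, res_x = _ols_fit_resid(y, X)
    _, res_z = _ols_fit_resid(y, Z)
    s2x = res_x @ res_x / n
    s2z = res_z @ res_z / n
    # part of the X-fit that the Z regression cannot reproduce
    _, err_zx = _ols_fit_resid(fit_x, Z)
    s2zx = s2x + err_zx @ err_zx / n
    c01 = 0.5 * n * (np.log(s2z) - np.log(s2zx))
    _, err_xzx = _ols_fit_resid(err_zx, X)
    v01 = s2x * (err_xzx @ err_xzx) / s2zx ** 2
    q = c01 / np.sqrt(v01)
    p = float(2.0 * stats.norm.sf(abs(q)))
    return float(q), p


@dataclass
class CoxTestResult:
    """Cox non-nested comparison run in both directions."""

    stat_1_null: float
    p_1_null: float
    stat_2_null: float
    p_2_null: float
    winner: str | None = None

    def as_comparisons(self) -> tuple[ModelComparison, ModelComparison]:
        return (ModelComparison("cox_nonnested", self.stat_1_null,
                                self.p_1_null, self.winner),
                ModelComparison("cox_nonnested", self.stat_2_null,
                                self.p_2_null, self.winner))


def cox_test_nonnested(y, X1, X2, alpha: float = 0.05,
                       names: tuple[str, str] = ("model1", "model2"),
                       ) -> CoxTestResult:
    """Cox test for two non-nested linear regressions, both directions.

    Raises if either design spans the other (use :func:`f_test_nested`).
    The ``winner`` is the model not rejected at ``alpha`` when exactly one
    of the two null hypotheses is rejected.
    """
    yv = np.asarray(y, dtype=float)
    A = np.atleast_2d(np.asarray(X1, dtype=float))
    B = np.atleast_2d(np.asarray(X2, dtype=float))
    if A.shape[0] != yv.size:
        A = A.T
    if B.shape[0] != yv.size:
        B = B.T
    rank_a = np.linalg.matrix_rank(A)
    rank_b = np.linalg.matrix_rank(B)
    rank_ab = np.linalg.matrix_rank(np.hstack([A, B]))
    if rank_ab == rank_a or rank_ab == rank_b:
        raise ValueError("designs are nested or identical; "
                         "use f_test_nested for nested models")
    q1, p1 = _cox_direction(yv, A, B)
    q2, p2 = _cox_direction(yv, B, A)
    winner = None
    if p1 < alpha and p2 >= alpha:
        winner = names[1]
    elif p2 < alpha and p1 >= alpha:
        winner = names[0]
    return CoxTestResult(stat_1_null=q1, p_1_null=p1,
                         stat_2_null=q2, p_2_null=p2, winner=winner)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
        raise ValueError("Pearson correlation undefined for constant series")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


class AttentionRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the attention models.

    Parameters
    ----------
    model : {"I", "II", "III"}
        Which regression to fit.  Model III adds the exponential-memory
        covariate derived from the news series.
    tau : float or None
        Memory time scale (days).  ``None`` (Model III only) tunes tau over
        ``tau_grid`` by adjusted R².
    tau_grid : iterable of float
        Candidate time scales, default integers 1..45.
    include_current_day : bool
        Whether the memory sum includes the current step (default strictly
        past).
    standardize : bool
        Z-score regressors before fitting (no intercept is used).

    ``fit(X, y)`` accepts a DataFrame (or dict of 1-d arrays) with columns
    among {"incidence", "news"}.  Fitted attributes: ``coef_``,
    ``conf_int_``, ``tau_``, ``fit_`` (the full :class:`RegressionFit`),
    ``r2_adj_``, ``profile_`` (tau tuning diagnostics, Model III only).
    """

    def __init__(self, model: str = "III", tau: float | None = None,
                 tau_grid: Iterable[float] = DEFAULT_TAU_GRID,
                 include_current_day: bool = False,
                 standardize: bool = True):
        self.model = model
        self.tau = tau
        self.tau_grid = tau_grid
        self.include_current_day = include_current_day
        self.standardize = standardize

    def _covariates(self, X, tau: float | None) -> dict:
        cols = dict(X) if not isinstance(X, pd.DataFrame) else \
            {c: X[c] for c in X.columns}
        if self.model == "III":
            if "news" not in cols:
                raise ValueError("Model III needs a 'news' column")
            return model_iii_covariates(cols["news"], tau,
                                        self.include_current_day)
        return cols

    def fit(self, X, y):
        if self.model not in MODEL_REGRESSORS:
            raise ValueError(f"unknown model {self.model!r}")
        self.profile_ = None
        if self.model == "III" and self.tau is None:
            cols = dict(X) if not isinstance(X, pd.DataFrame) else \
                {c: X[c] for c in X.columns}
            self.profile_ = tune_tau(y, cols["news"], list(self.tau_grid),
                                     self.include_current_day,
                                     self.standardize)
            self.tau_ = self.profile_.tau_best
            self.fit_ = self.profile_.fits[self.tau_]
        else:
            self.tau_ = self.tau
            cov = self._covariates(X, self.tau_)
            self.fit_ = fit_model(y, self.model, cov, self.standardize)
        self.coef_ = np.array([self.fit_.coefficients[nm]
                               for nm in self.fit_.regressors])
        self.conf_int_ = self.fit_.conf_intervals
        self.r2_adj_ = self.fit_.r2_adj
        self._y_train = np.asarray(y, dtype=float)
        return self

    def predict(self, X):
        cov = self._covariates(X, self.tau_)
        names = MODEL_REGRESSORS[self.model]
        ydummy = np.zeros(len(np.asarray(cov[names[0]], dtype=float)))
        _, Xm = _design(ydummy, cov, names, self.standardize)
        return Xm @ self.coef_


def country_report(bundle: Mapping[str, object],
                   tau_grid: Iterable[float] = DEFAULT_TAU_GRID,
                   standardize: bool = True) -> dict[str, pd.DataFrame]:
    """Correlation, model-fit and coefficient tables for one country.

    ``bundle`` maps series names to aligned daily/weekly series and must
    contain ``incidence``, ``news`` and ``response`` (the attention signal);
    ``global_incidence`` is optional and joins the correlation table.
    Returns DataFrames ``correlations``, ``model_r2``, ``coefficients`` and
    ``comparisons`` — every number traceable to the operations above.
    """
    required = ["incidence", "news", "response"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise ValueError(f"bundle missing series: {missing}")

    corr_rows = []
    pairs = [("news", "incidence"), ("news", "response"),
             ("incidence", "response")]
    if "global_incidence" in bundle:
        pairs += [("news", "global_incidence"),
                  ("global_incidence", "response")]
    for a, b in pairs:
        r, p = pearson_with_p(bundle[a], bundle[b])
        corr_rows.append({"x": a, "y": b, "r": r, "p_value": p})

    y = bundle["response"]
    fit1 = fit_model(y, "I", {"incidence": bundle["incidence"]}, standardize)
    fit2 = fit_model(y, "II", {"news": bundle["news"]}, standardize)
    profile = tune_tau(y, bundle["news"], list(tau_grid),
                       standardize=standardize)
    fit3 = profile.fits[profile.tau_best]

    r2_rows = [{"model": "I", "r2_adj": fit1.r2_adj, "tau": np.nan},
               {"model": "II", "r2_adj": fit2.r2_adj, "tau": np.nan},
               {"model": "III", "r2_adj": fit3.r2_adj,
                "tau": profile.tau_best}]

    coef_rows = []
    for fit in (fit1, fit2, fit3):
        for nm in fit.regressors:
            lo, hi = fit.conf_intervals[nm]
            coef_rows.append({"model": fit.model_id, "regressor": nm,
                              "estimate": fit.coefficients[nm],
                              "ci_low": lo, "ci_high": hi})

    ftest = f_test_nested(fit2, fit3)
    cov3 = model_iii_covariates(bundle["news"], profile.tau_best)
    _, X1 = _design(np.asarray(y, float), {"incidence": bundle["incidence"]},
                    ["incidence"], standardize)
    _, X3 = _design(np.asarray(y, float), cov3, ["news", "newsMEM"],
                    standardize)
    cox = cox_test_nonnested(y, X1, X3, names=("I", "III"))
    cmp_rows = [
        {"test": "f_nested_II_vs_III", "statistic": ftest.statistic,
         "p_value": ftest.p_value, "winner": ftest.winner},
        {"test": "cox_I_null_vs_III", "statistic": cox.stat_1_null,
         "p_value": cox.p_1_null, "winner": cox.winner},
        {"test": "cox_III_null_vs_I", "statistic": cox.stat_2_null,
         "p_value": cox.p_2_null, "winner": cox.winner},
    ]

    return {
        "correlations": pd.DataFrame(corr_rows),
        "model_r2": pd.DataFrame(r2_rows),
        "coefficients": pd.DataFrame(coef_rows),
        "comparisons": pd.DataFrame(cmp_rows),
    }
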