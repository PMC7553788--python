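# infodem

Tools for analyzing how media coverage and epidemic incidence drive
collective online attention during a health emergency, and how the topics
covered by news outlets compare — in volume and in timing — with the topics
the public actually discusses.

The package is aimed at computational epidemiologists and infodemiology
researchers working with heterogeneous digital traces: news article and
video metadata, discussion-platform submissions and comments, and
encyclopedia page-view counts, alongside reported disease incidence.

## What it computes

**Attention regression with memory effects.** The public response `y_t`
(comment volume or page-view volume) is modelled by three nested/non-nested
ordinary least squares regressions without intercept:

    Model I:    y_t = α₁ · incidence_t              + u_t
    Model II:   y_t = α₁ · news_t                   + u_t
    Model III:  y_t = α₁ · news_t + α₂ · newsMEM_t  + u_t

where the memory covariate is an exponentially decayed cumulative news
exposure,

    newsMEM_t = Σ_{t' < t} news_{t'} · exp(−(t − t')/τ),

with the memory time scale τ tuned over the integers 1…45 by maximizing
Model III's adjusted R². A negative α₂ is the signature of *attention
saturation*: the public response declines while coverage stays high.
Model III is compared with Model II by the exact F test for nested models
and with Model I by the classical Cox test for non-nested linear
regressions; per-country correlation tables use Pearson's r with t-test
p-values.

**Page-view country attribution.** Raw daily article views from a language
project are attributed to a country by its share of the project's monthly
traffic, `v = S_p(d) · views_c(p, m) / views_total(p, m)`, and summed over
articles and projects into a daily national attention volume.

**Dynamic topic analysis.** A reference corpus is turned into a TF-IDF
matrix and factorized as `X ≈ W H` (`W, H ≥ 0`, K = 64 topics by default)
by minimizing the Frobenius reconstruction error with an alternating
projected-gradient solver; the fixed basis `H` then projects other corpora
onto the same topics. Per-topic dynamics follow: strength
`s_k(t) = Σ_{i∈D(t)} w_i W_ik` (comment-weighted for discussion corpora),
relevance `R_k = Σ_t s_k(t)`, the half-relevance time `t_half` (earliest
day the cumulative strength reaches `R_k/2`), and interest shares
`100 · R_k / Σ R` whose per-topic difference across sources measures
attention mismatch in percentage points.

**Corpus filtering and geolocation.** Keyword relevance filters,
submission-score and comment length/duplicate cleaning rules, self-report
geolocation ("I live in …") against a bundled gazetteer, and
location-citation shares before/after a reference date.

**Synthetic data with planted truth.** Every input the analysis consumes
can be generated with known ground truth: a deterministic SIR incidence
curve (plus an earlier-peaking global curve), news driven by the two
incidence curves, attention generated by Model III with known
(α₁, α₂, τ), planted-topic corpora with temporal bumps and per-topic
comment affinities, and self-report/citation corpora.

## Worked example

```python
import numpy as np
import infodem

cfg = infodem.SimConfig(seed=42)
incidence = infodem.gen_incidence(cfg)
global_inc = infodem.gen_incidence(cfg, global_curve=True)
rng = np.random.default_rng(cfg.seed)
news = infodem.gen_news(incidence, cfg, rng, global_incidence=global_inc)
attention, truth = infodem.gen_attention(news, cfg, rng)  # α₁=1, α₂=−0.45, τ=10

tables = infodem.country_report({"incidence": incidence, "news": news,
                                 "response": attention})
print(tables["model_r2"].to_string(index=False))
```

prints

```
model    r2_adj  tau
    I -0.006578  NaN
   II  0.798595  NaN
  III  0.983014 10.0
```

— incidence alone explains nothing, news explains most of the response,
and adding the memory term (at the correctly recovered τ = 10) captures the
rest. The Model III coefficients bracket the planted values:

```
model regressor  estimate    ci_low   ci_high
  III      news  1.008232  0.980142  1.036322
  III   newsMEM -0.459486 -0.487575 -0.431396
```

and the model comparisons agree (F test II vs III: p ≈ 1.4e−53; Cox test
rejects Model I as null, does not reject Model III).

The same estimator is available in scikit-learn form:

```python
est = infodem.AttentionRegressor(model="III")   # tau=None -> tuned over 1..45
est.fit({"news": news}, attention)
est.tau_, est.coef_    # (10, array([ 1.008..., -0.459...]))
```

A command-line interface mirrors the library (`infodem simulate`,
`infodem filter`, `infodem clean-reddit`, `infodem pageviews`,
`infodem attention`, `infodem topics fit/transform/dynamics`,
`infodem geolocate`, `infodem citation-shares`).

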