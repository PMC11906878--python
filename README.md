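# anthropause

Tools for quantifying how an abrupt mobility shock — the first COVID-19
lockdown, March 15 to May 1, 2020 — changed the volume and geography of
biodiversity data collection, built for biodiversity informaticians and
ecologists who work with Darwin-Core-style occurrence tables (GBIF
snapshots, eBird extracts) and their citizen-science observer streams.

## What it computes

**Per-country change in collection effort.** For matched 48-day windows in
2019 (t0) and 2020 (t1),

```
Change_records (%) = (N_t1 − N_t0) / N_t0 × 100
```

computed per country code after restricting to georeferenced human
observations and excluding high-seas records. The regression response is
`log10(Change_records + 100)`, which symmetrises the heavy right skew of
percent changes.

**Trend anomalies.** Yearly window counts 2010–2023 are smoothed with a
cubic smoothing spline (penalised least squares, spar-style smoothing
parameter; the study design uses spar = 0.4, 0.5, 0.6). The 2020 count is
classified `below` / `within` / `above` the spline's 95% Bayesian pointwise
interval — falling outside is the "significantly different from trend at
p < 0.05" statement.

**Drivers of the change.** A linear model

```
log10(Change_records + 100) ~ Stringency_index + Change_park_visitors
                              + log10(Population_size) + Economic_class
```

is extended by generalised least squares with a distinct residual variance
per economic class (varIdent-style structure, reference class "developed"
fixed at multiplier 1), estimated by ML or REML with a blockwise profile
ascent. Model comparison against the stringency × class interaction uses a
chi-square likelihood-ratio test on ML log-likelihoods; per-term marginal
(Wald) F tests, conditional-effect profiles and a Brown–Forsythe/Levene
heteroscedasticity diagnostic round out the inference. The engine matches
R's `nlme::gls(weights = varIdent(...))` to ~1e-6 on coefficients and
log-likelihood (checked in the test suite).

**Observer analytics.** Per country: active observers (unique ids), the 30
most active observers of 2019 (most distinct recording days; ties by record
count, then id), each observer's activity range as the minimum convex
polygon around their records with its area computed on the authalic sphere
(R = 6371.0088 km, antimeridian-safe), a two-sample Kolmogorov–Smirnov
contraction test between years (exact permutation p when n·m ≤ 10 000),
and a lockdown migration status per observer: `returned` (recorded again in
the selection country — takes precedence even if they also recorded
elsewhere), `migrated` (only elsewhere), `inactive` (nowhere).

**Synthetic worlds.** A generator emits occurrence tables, observer
populations and covariate tables with a declared ground-truth ledger:
Poisson counts around exponential growth, per-class lockdown multipliers,
observers with homes, travel and bounded random walks, a borders
open/closed switch, and covariates tied to the true effects through
Gaussian copulas. Every analysis stage is testable against the ledger
without downloading anything.

## Worked example

Generate a 40-country lockdown world (closed borders, developing-class
collection rates at 0.6× trend) and run the full pipeline:

```
$ anthropause synth --n-countries 40 --seed 7 --out-dir world
332912 records, 40 countries -> world
$ anthropause run --config pipeline.yaml     # paths + output dir
report written to report
```

From `report/gls_fit.json` (REML coefficients):

```
intercept                          +2.0407  (p=0.0000)
stringency_index                   -0.0004  (p=0.5785)
change_park_visitors               +0.0025  (p=0.0000)
log10_population_size              +0.0065  (p=0.3639)
economic_class[emerging]           -0.0361  (p=0.1116)
economic_class[developing]         -0.1726  (p=0.0000)
economic_class[least_developed]    -0.1932  (p=0.0000)
variance multipliers: developed 1.00, emerging 0.96,
                      developing 1.68, least_developed 1.47
LR base vs interaction: statistic 6.94, df 3, p 0.074
```

Read: park visitation tracks collection effort (+0.0025 per percentage
point on the log10 response), developing and least-developed countries lost
significantly more records than developed ones at equal covariates, and the
stringency × class interaction is not supported. `report/trend_anomaly.csv`
flags lockdown-hit countries `below` trend at all three smoothing
parameters, e.g.:

```
country_code  smoothing_param  year  observed  fitted   ci_low  ci_high  anomaly_class
AR            0.4              2020  430.0     517.0    456.4   577.7    below
```

and `report/observer_summary.csv` shows the activity-range contraction
(KS p < 0.05 in most countries), with the migration matrix
(`report/migration_matrix.csv`) counting returned / migrated / inactive
top observers per origin class.

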