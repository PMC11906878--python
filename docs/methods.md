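# Methods

This note records the models, the defaults and the numerical choices behind
`anthropause`, and what the synthetic-data studies do and do not establish.

## Change metric and response transform

`Change_records = (N_t1 − N_t0)/N_t0 × 100` is computed from window totals
over the closed calendar window March 15 – May 1 (48 days in both 2019 and
2020; with equal-length windows this equals the mean-daily-count phrasing).
Both endpoints are included — "between March 15th and May 1st" is read
inclusively. The statistic is undefined for countries with an empty
baseline window; those are excluded and reported. The modelling response is
`log10(Change_records + 100)`, undefined at exactly −100 (no lockdown
records at all); such countries are excluded from the regression with a
logged warning rather than patched with an epsilon, which would silently
distort the response scale.

Country identity is always the record's country-code field (as occurrence
aggregators assign it), never re-derived from coordinates. The recognised
universe is the 249 ISO 3166-1 alpha-2 codes plus `XK` (Kosovo) and `ZZ`
(high seas); `ZZ` records are dropped before any analysis. Parsing filters
(georeferenced, human observation, recognised code) report every rejected
row by reason so the funnel is auditable.

## Smoothing-spline trend anomaly

Yearly window counts are fitted on the raw count scale (a log-scale option
exists behind a flag) with a natural cubic smoothing spline in the
Green–Silverman form: knot values minimise
`‖y − f‖² + λ f′K f` with `K = Q R⁻¹ Qᵀ`, years rescaled to [0, 1]. The
user-facing smoothing parameter follows the classical spar convention
`λ = r · 256^(3·spar − 1)`; we take `r = n / tr(K)`, the trace ratio of the
(identity) fidelity matrix to the penalty matrix. This differs from the
B-spline-basis trace ratio used by some reference implementations by a
constant factor — it relabels the spar axis but spans the same family of
fits, and at a *fixed* λ our fitted values agree with R's
`smooth.spline(all.knots=TRUE, lambda=...)` to ~1e-6 relative (the
penalised criterion has a unique minimiser; this is one of the test-suite
oracles). Affine data is reproduced exactly at any spar (penalty null
space); spar → 1 approaches the least-squares line.

The 95% interval is the Wahba-type Bayesian pointwise interval
`f̂_i ± z₀.₉₇₅ · σ̂ · √(S_ii)` with `S = (I + λK)⁻¹` and
`σ̂² = RSS/(n − tr S)`. The focal-year (2020) observation is classified
`below`/`within`/`above` this interval; the focal year is *included* in the
fit by default (an `--exclude-focal` flag fits without it and predicts it
from the interpolating natural spline, with interval width interpolated
between bracketing knots — an approximation, flagged as such). Years with
zero records are retained as zeros, not dropped. Fewer than four distinct
years is an error; all-equal counts yield the constant fit with a
zero-width interval.

**Calibration caveat (measured, not assumed).** The classifier compares an
*observation* against a *mean* interval. The variance of `y_i − f̂_i` is
`σ²[(I−S)²]_ii`, while the band's halfwidth is `σ̂√(S_ii)`; the two agree
only when `S_ii` is large, i.e. for flexible fits. Consequently, under the
no-shock generator the "within" rate sits near 0.95 only at the flexible
end of the spar range and falls as the spline stiffens (our acceptance run
measures ≈ 0.91 / 0.76 / 0.59 at spar 0.4 / 0.5 / 0.6 with 14 yearly
points). This is a property of the interval construction itself — the same
construction used by the standard spline tooling — not of this
implementation; the stiffer settings over-report anomalies under the null.
Detection of genuine collapses is unaffected: a 6-residual-SD 2020 drop is
flagged `below` at *all three* spar values in ≥ 99% of runs. Users who
need a calibrated null should prefer the flexible end of the spar range or
treat the three-spar agreement as the decision rule (as the sensitivity
design intends).

## Covariates and collinearity screen

The regression frame is the inner join of the change table with per-country
covariates: stringency index (0–100), percent change in park visitors and
in time at home versus a pre-pandemic baseline (accepted as pre-aggregated
national values; baselines are not recomputed from daily series),
population (log10-transformed), and the four-level economic class ordered
developed < emerging < developing < least developed with "developed" the
reference level. Rows with any missing covariate are dropped and listed.
Spearman rank correlation screens every continuous pair at |ρ| ≥ 0.7
(configurable); time-at-home is the member dropped when its pairing with
park visitors trips the screen, matching the study design. Constant columns
yield an undefined ρ, reported as such.

## Heteroscedastic GLS

Residual diagnostics of the OLS fit motivate a per-class variance:
`Var(ε_i) = σ² δ²_{g(i)}`, `δ_developed ≡ 1`. ML estimation is a blockwise
profile ascent: given multipliers, coefficients come from weighted least
squares; given coefficients, the multipliers' closed form is the per-group
RMS residual. Each step maximises the same Gaussian likelihood, so the
log-likelihood trace is non-decreasing (asserted in tests); convergence is
|Δ log L| < 1e-8, at most 200 iterations, with an informative error
carrying the trace otherwise. REML profiles β and σ² analytically and
optimises the (G−1) log-multipliers numerically (Nelder–Mead, warm-started
at the ML solution); the log-scale parameterisation enforces positivity.
Reported log-likelihoods include the −n/2·log 2π constant and match
`nlme::gls` for both ML and REML.

Inference conventions: the coefficient covariance uses the
(n − p)-denominator residual scale even under ML (the small-sample GLS
convention, matching the reference tooling); coefficient p-values use the t
distribution with n − p df. Model comparison (LR test, per-term ANOVA) uses
ML fits; coefficient reporting defaults to REML. The per-term ANOVA is the
marginal (Wald) F test from the coefficient covariance, interaction tested
last; all-zero design columns are dropped with a warning and terms left
with no estimable column are excluded with a notice. The LR test for the
stringency × class interaction has 3 df (one slope per non-reference
class). Conditional-effect profiles hold other continuous covariates at
their means and weight categorical levels by observed frequencies, with
bands from the coefficient covariance. The heteroscedasticity diagnostic is
Levene's test, median-centred by default (Brown–Forsythe; mean-centring by
flag), on the OLS residuals grouped by class.

With n_g comparable to the parameter count the profile likelihood can be
unbounded (a group near-interpolates and its variance collapses); the
engine raises a convergence error rather than returning a degenerate fit.
The study scale (≈ 129 countries, 7–10 parameters, 4 groups) is
unproblematic.

## Observer analytics

Activity is counted in distinct recording days; the top-30 ranking breaks
ties by total records, then lexicographic observer id (deterministic
output). Activity ranges are convex hulls of record locations; areas are
spherical polygon areas on the authalic sphere (R = 6371.0088 km) via the
van Oosterom–Strackee signed-excess formula — exact for great-circle
edges, within 0.5% of a planar equal-area computation at activity-range
scales (measured ≤ 0.14% over random sub-degree hulls), with no
projection-zone bookkeeping; an equal-area projected backend could be
plugged in where absolute areas matter. Longitudes are unwrapped about
their circular mean before hull construction so antimeridian-straddling
observers get sensible hulls; an unwrapped spread above 180° is an error.
Observers with one distinct location (or collinear points) keep area 0 and
stay in the sample — dropping them would bias the contraction test toward
the null. The 2020 range of a selected observer uses their records in any
country (the pipeline's `restrict_origin` option confines it to the
origin country).

The cross-year contraction test is the two-sided two-sample KS test. For
n·m ≤ 10 000 the p-value is the exact conditional permutation value,
computed by integer lattice-path counting over tie blocks (we found the
library exact method silently falls back to the asymptotic one on some
inputs, so exactness is guaranteed by our own count, verified against full
enumeration); larger samples use the asymptotic distribution.

Migration status: `inactive` (no lockdown records), `returned` (origin
country among the lockdown countries — precedence over any additional
countries), `migrated` (records only elsewhere). Destination economic
classes are resolved per lockdown country.

## Synthetic worlds

The generator emulates the joint structure of the study's data sources:

* **Counts**: per-country Poisson with mean `λ₀(1+g)^(year−2010)`; λ₀
  log-uniform (defaults 80–400 for full worlds, 200–5000 for the
  129-country regression worlds) and g = 0.15/yr, a growth rate in the
  range occurrence archives have exhibited. In 2020 the mean is multiplied
  by the country's lockdown multiplier: class levels developed 1.1,
  emerging 0.9, developing 0.6, least developed 0.5, with mean-corrected
  lognormal country heterogeneity (log-SD 0.15). Effects are multiplicative
  on Poisson means, matching percent-change semantics.
* **Observers**: per-country populations with Gamma(0.8) activity weights;
  window counts are allocated multinomially among observers present, so
  inactivity arises naturally. Travel probability 0.15 toward destinations
  weighted toward developing/least-developed classes (birding tourism); a
  single borders switch zeroes 2020 travel in the closed scenario — the
  central disrupted-visitor mechanism. Positions follow bounded random
  walks (30 km step scale, 15 km in 2020).
* **Covariates**: stringency per class (means 55/70/80/75, SD 12, clipped
  to [0, 100]); park-visitor change tied to the realised multiplier through
  a Gaussian copula (ρ = 0.6) around class means `100·(m_class − 1)`;
  time-at-home copula-correlated with park visitors at ρ = −0.74;
  populations log-uniform 10⁵–10⁸·⁵. An optional missingness fraction
  masks mobility covariates to exercise the exclusion funnel.
* **Ledger**: per-country rates and multipliers, per-observer itineraries
  and realised record locations — every downstream assertion (expected
  counts, migration statuses, high-seas bookkeeping) is decidable from the
  ledger alone. Identical (config, seed) gives byte-identical outputs.

What the generator does **not** emulate: taxonomic composition, spatial
clustering beyond bounding boxes, checklist-effort structure (duration or
distance protocols), within-country heterogeneity of lockdown rules, or
reporting latency. Passing tests therefore establish the correctness and
calibration of the estimators under the declared generating model, not the
field accuracy of any particular empirical estimate.

## Problem sizes and replication defaults

The replicate studies behind `scripts/acceptance.py` and the acceptance
tests use: 200 replicates at 4 × 500 observations for GLS recovery and
coverage; 1 000 series (per spar) for interval calibration and 200 for
shock detection; 200 random hulls for the geometry check; full enumeration
up to n = m = 7 for KS exactness; 10 000 observers for migration agreement;
and 200 replicate 129-country worlds (class sizes 36/30/43/20) for the
contrast-recovery study. These sizes keep each study's Monte-Carlo error
well below the margins being asserted.

## Known limitations

* The trend-anomaly interval under-covers the observation at stiff spar
  settings (see the calibration caveat); the package reports all three
  spar fits so users can require agreement.
* REML multiplier optimisation is derivative-free; with many variance
  groups a gradient-based scheme would scale better.
* eBird "records" are treated as occurrence rows; checklist-level
  semantics are not modelled.
* The `exclude_focal` spline variant interpolates the interval width at
  the held-out year rather than propagating full uncertainty.
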