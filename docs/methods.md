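# Methods

## Frequency chronologies

For a site×species group and calendar year, `N` counts cores whose ring
carries an IADF and `n` counts cores whose ring has a readable flag.  Rings
with an unreadable flag (NA) are excluded from both counts: an unreadable
ring is not evidence of absence.  The four response variants are

* `F = N/n` — the relative frequency; undefined (missing) when `n = 0`;
* `f = F·√n` — stabilized frequency.  Binomial noise in `F` has variance
  `p(1−p)/n`; multiplying by `√n` makes the noise variance depth-independent,
  so chronology variance is not dominated by the shallow-depth early years;
* residuals of `F` from a Weibull-type peak curve
  `w(x; A, b, c) = A·(x/b)^(c−1)·exp(−(x/b)^c)` in the mean cambial age of
  the contributing rings, and from a Chapman–Richards curve
  `c(x; a, b, c) = a·(1 − exp(−b·x))^c` in the mean ring width.  Detrending
  is by subtraction, not division, because `F` is exactly zero in many years.

The curve families are named in the dendro literature without fixed
formulas; the two parameterizations above are the common usage and are the
package's choice.  Curves are fitted at chronology level (per-year means of
age and width), by multi-start nonlinear least squares: 20 starting points
from a coarse log-grid over the parameters, fixed shuffle, best SSE wins;
the `converged` flag reports the optimizer status of the winning start.
Cambial age of ring *i* of a core is `pith_offset + i + 1`.

## Climate and SPEI-6

Annual summaries are the mean of the 12 monthly mean temperatures and the
sum of the 12 monthly precipitation totals; incomplete years are dropped.
Potential evapotranspiration uses the Thornthwaite formulation (monthly
temperature and latitude only, day-length and month-length corrected, zero
for sub-zero months, high-temperature polynomial above 26.5 °C), the only
PET variant computable from the pipeline's inputs.  The drought index is
SPEI at a 6-month scale: the climatic water balance `D = prcp − PET` is
summed over backward 6-month windows labelled by their final month; for
each calendar month a 3-parameter log-logistic distribution is fitted to
the calibration-period window sums via unbiased probability-weighted
moments, and SPEI is the standard-normal quantile of the fitted CDF,
clipped to ±4.75 (CDF ∈ [1e−6, 1−1e−6]).  When the L-moment fit is invalid
(shape ≤ 1 or origin not below the data) the month falls back to
empirical-quantile standardization with Hazen plotting positions, flagged
in the output.  The annual mean SPEI is the mean of a year's 12 monthly
values.  Exact numerical agreement with hosted SPEI databases is not a
goal: those use different PET formulations and reference periods.

## Site clustering

Features per site: 12-month climatologies of mean/min/max temperature and
precipitation over the common period (48 columns) plus raw latitude and
longitude, each column z-scored across sites; Euclidean distances.  Monthly
precipitation climatologies (not one annual total) are used because the
clusters are characterized by seasonal precipitation patterns; a config
flag restores the single-total reading.  Coordinates enter unweighted after
z-scoring.

PAM (k-medoids) is implemented directly: greedy BUILD seeding followed by
steepest-descent SWAP until no single medoid↔non-medoid exchange improves
the total distance to nearest medoid.  A single BUILD seeding can strand
SWAP in a local optimum (measurably so on small unstructured instances, for
this and for reference implementations alike), so BUILD is restarted
deterministically from every possible first medoid and the best final
objective is kept — still fully deterministic, and exhaustive enumeration
on all instances small enough to enumerate has found no counterexample.
The number of clusters is chosen by maximizing the mean silhouette
`s = (b − a)/max(a, b)` over k ∈ 2..10, ties to the smaller k; singleton
clusters and fully degenerate points score 0.

## The zero-adjusted gamma model

The response (default: the stabilized frequency `f`) is non-negative with
exact zeros.  The ZAGA distribution is a hurdle: `P(Y = 0) = ν`, and
`Y | Y > 0 ~ Gamma` with mean `μ` and squared coefficient of variation
`σ²`.  The likelihood factorizes, so the two parts are fitted separately:

* **ν part** — intercept-only Bernoulli (logit link) by default, i.e. the
  weighted share of zero responses.  The residual-detrended response
  variants can be negative and are rejected as ZAGA responses with a clear
  error.
* **μ part** — gamma regression with log link on the positive rows:
  altitude linear, P-spline smooths in latitude and mean ring width,
  species fixed effects, species-specific slopes for annual precipitation,
  mean temperature and annual SPEI (main effect + interaction, R-style
  `tp*species` semantics), and cluster fixed effects.  Climate covariates
  and altitude are centered for numerical stability (slopes unchanged).

Smooths are Eilers–Marx P-splines: cubic B-splines on 20 uniformly spaced
knots extended at uniform spacing beyond the data range (so a second-order
difference penalty is exactly zero on linear functions), with a sum-to-zero
constraint absorbing the constant direction that would alias the intercept.
No extrapolation: prediction outside the training span raises.  Smoothing
parameters are selected by GCV on a 13-point log grid (10⁻⁴..10⁶),
coordinate-wise inside the penalized IRLS loop ("performance iteration"),
and frozen once the GCV choice stops changing so the IRLS can converge on
a fixed objective (criterion: max relative coefficient change < 1e−8,
cap 200 iterations, honest `converged` flag).  For the gamma log link the
IRLS working weights are the prior weights, so `X'WX` is constant and each
step is a single Cholesky solve.

Aliased parametric columns (e.g. a species occurring in only one cluster)
are detected by weighted pivoted QR and dropped with a warning naming them.
Dispersion `σ²` is the Pearson statistic over `n − edf`; the coefficient
covariance is the Bayesian `σ²(X'WX + S)⁻¹` customary for penalized GAMs.
Species-specific slopes in the effect table are reference slope +
interaction, with SEs from that covariance; Wald two-sided p-values at
α = 0.05, no multiple-testing correction.  The reported R² is explicitly
the squared Pearson correlation between the fitted unconditional mean
`(1 − ν)μ` and the observed response (other R² conventions exist; this one
is labelled in the output).  Observation weights are supported with two
presets: none (default) and inverse cluster share, a coarse correction for
geographically unbalanced networks.

Diagnostics: randomized quantile residuals (normal quantile of the fitted
ZAGA CDF; the point mass at zero broken uniformly at random, seeded) and a
composite-normality Cramér–von Mises test with the standard
modified-statistic p-value approximation for estimated parameters.

## Synthetic network generator

The generator emulates the structure the analysis assumes, at a scale small
enough for routine testing: **12 sites per archetype × 4 climate
archetypes** (humid-Atlantic; dry-warm; mild-winter Mediterranean, the only
one with warm wet winters; continental, the only one with sub-zero winter
normals and a summer precipitation maximum), 3 species per archetype with
three pines shared across ≥ 2 archetypes so species and cluster effects
stay jointly identifiable, 15 trees per site, 60-year series ending in
2000 with staggered recruitment (a realistic sample-depth ramp).

Monthly climate is archetype normals minus a 0.0065 °C/m lapse-rate offset,
plus Gaussian interannual noise; precipitation is gamma-distributed around
monthly normals.  Ring widths follow a negative-exponential age curve
modulated multiplicatively by a standardized annual climate score and
lognormal noise, quantized to the 0.01 mm resolution of the Tucson format.
IADF occurrence is Bernoulli per ring with

    logit p = b0 + b_rw1·rw + b_rw2·rw² + b_age·max(0, age − 30)
              + b_temp·ΔT + b_prcp·ΔP + b_spei·SPEI

with `b_rw2 < 0` (concave width response) and a hinge age effect at 30
years — deliberately simpler than the Weibull curve the estimator fits, so
detrending is tested against a model it does not nest.  Climate enters as
within-site annual anomalies (°C, 100 mm) so species effects and site
effects are separable.  Species defaults encode the qualitative pattern a
continental network shows: temperature slopes positive for most species
(zero for the boreal/temperate `PISY`, `LADE`, `QURO` and for `QUIL`),
precipitation negative for the drought-avoiding `ARUN` and `PIAB`, positive
with a positive SPEI slope for the drought-tolerant bimodal growers `PIPI`,
`PIPN` and `QUIL`.  Juvenile widths are set so the typical ring lies on the
rising branch of the width response (wider rings carry more IADFs), and
intercepts are calibrated once (by bisection against the generator itself)
so species mean frequencies span ~10 % (montane conifers) to ~47 %
(`PIPI`) and ~64 % (`ERAR`), with a network-wide proportion near a quarter
of rings.  Everything is driven by `numpy` `SeedSequence` spawning:
bit-identical output per seed.

What the generator does **not** emulate: spatial autocorrelation between
sites, within-ring IADF position classes, daily-resolution climate,
process-based xylogenesis, crossdating error.  Passing tests therefore
demonstrate the correctness of the estimators under the stated generative
model, not their performance on any real network.

## Known limitations and numerical notes

* The chronology response is an aggregated binomial proportion and hence
  discrete, with support coarsest where sample depth is shallow.  The ZAGA
  model treats positives as continuous gamma; on the default synthetic
  network the residual Cramér–von Mises test has enough power at ~1000
  chronology-years to detect this granularity (p ≈ 0.01), while data
  simulated directly from the ZAGA model pass the same test in ≥ 90 % of
  replicates.  The diagnostic is reported as computed.
* The effect-sign table recovers the generating signs for all strongly
  expressed effects; cells with weak true slopes are reported `n.s.` at the
  default scale — a power statement, not an error.
* GCV occasionally selects the grid boundary smoothing value for a smooth
  with little curvature; the fitted curve is then near-linear, which is the
  intended shrinkage limit of a second-order penalty.
* Simulation sizes in the test suite (e.g. 300 replicates of n = 2000 for
  the calibration study; 10⁴ rings for the generator-realism checks; a
  48-site network for cluster recovery) were chosen so binomial/Monte-Carlo
  noise is small relative to each check's margin.
* `relative_frequency` returns NaN (flagged missing), not an error, for
  `n = 0`; all derived per-year quantities propagate that missingness.
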