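# Methods

## Model

Daily death counts `y_t` in one city are modelled as overdispersed
Poisson with log link:

```
log μ_t = α + s(x_t, ℓ; β) + γ·inc_t + δ·dec_t + φ·hot_t + ϑ·cold_t + Σ f(z_t; θ)
```

`x_t` is mean daily temperature (°C). `s(x, ℓ; β)` is a distributed-lag
non-linear (cross-basis) term: the exposure–lag–response surface is the
tensor product of an exposure basis `b_j(x)` and a lag basis `c_k(ℓ)`,
so the design column for the pair (j, k) on day t is
`Σ_{ℓ=0..21} b_j(x_{t−ℓ}) c_k(ℓ)`. The four variation indices enter
linearly at lag 0 only. `f(z; θ)` collects the confounder controls.

Assumptions worth stating explicitly:

- risk depends on temperature only through the last 22 days of mean
  temperature plus same-day variation indices;
- the exposure–lag surface is smooth in both dimensions (spline spaces
  below) and constant over the study period;
- counts are conditionally independent given the covariates, with
  variance proportional to the mean (quasi-Poisson); no residual
  autocorrelation correction is applied beyond the seasonal spline.

## Bases and their parameters

- Exposure–response: quadratic B-spline, internal knots at the
  10th/75th/90th percentiles of observed `tmean` (linear-interpolation
  quantiles over all non-missing days), boundary knots at the observed
  min/max, no intercept column (the model has its own). An
  equally-spaced-knot alternative is available for sensitivity work.
- Lag–response: natural cubic spline on integer lags 0..21, boundary
  knots 0 and 21, three interior knots at equal steps on the log-lag
  scale anchored at lag 1 (`21^{1/4}, 21^{1/2}, 21^{3/4}` ≈ 2.14, 4.58,
  9.81), with an explicit intercept column. The log anchor at lag 1 is
  forced by log 0 being undefined while the lag range starts at 0.
- Seasonal trend: natural cubic spline of the sequential day index with
  `round(8 × study years)` columns (6 or 10 per year as sensitivity
  variants), interior knots equally spaced over the used rows.
- Day of week: six indicators, Monday as the (arbitrary, fixed)
  reference.
- Humidity (optional): natural cubic spline with 3 df, i.e. two interior
  knots at the terciles of observed humidity. Three degrees of freedom is
  the target quantity; the tercile placement follows the usual
  df-driven natural-spline convention.

Natural cubic bases are built as cubic B-splines projected (via QR of
the boundary second-derivative constraints) onto the subspace that is
linear at and beyond the boundary knots; evaluation outside the
boundaries extends linearly with the exact boundary value and slope.
The quadratic exposure basis extends its end polynomial segments
outside the boundary knots, with a warning, so prediction grids may
exceed the fitting range.

The cross-basis is deliberately *not* centered at construction: the
design matrix never depends on the reference temperature, and all
referencing happens in the cumulative-curve contrasts
`Σ β_jk [b_j(x) − b_j(x_ref)] Σ_ℓ c_k(ℓ)`. Standard errors come from the
delta method (quadratic form of the contrast vector with the
dispersion-scaled covariance); confidence intervals are Wald on the
log-RR scale with z = 1.959964.

## Two-step procedure

Step 1 fits the model without the variation terms and locates the MMT as
the argmin of the overall cumulative curve on a search grid spanning the
empirical 1st–99th percentiles of `tmean` at 0.1 °C steps (grid trimming
avoids the unstable curve tails; ties break toward the grid value
nearest the median temperature; a curve whose total range is below
`flat_tol` = 1e-6 log units is flagged flat). Step 2 computes the four
indices from that MMT — day 0 of the series, which has no predecessor,
scores zero on both interday indices; a day with `tmean` exactly at the
MMT (probability zero in continuous data, fixed for determinism)
contributes to neither intraday index — and refits the full model. Both
steps share one cross-basis object, so knots are computed once.

Because the step-1 model omits the index terms, their average elevation
on the hot side (φ·E[DTR | hot]) exceeds the cold side's, which pulls
the estimated MMT slightly below the truth on simulated data; the
downstream consequence is a mild dilution of φ toward ϑ through
hot/cold misclassification of days between the estimated and true MMT.
This is a property of the two-step design itself (the indices are
defined by an estimated quantity), quantified by the recovery study in
the acceptance tests, not a numerical artifact.

## Estimation

Quasi-Poisson fitting is iteratively reweighted least squares on the
Poisson log-likelihood: working response `z = η + (y − μ)/μ`, weights μ,
normal equations solved by Cholesky factorization, convergence when the
relative deviance change is below 1e-9 (at most 100 iterations; the
linear predictor is clipped to ±30 to keep early iterations finite).
Rank deficiency is diagnosed by the QR of the weighted design and
reported with the offending column names. The dispersion is the Pearson
statistic over `n − p`; the covariance is dispersion × inverse Fisher
information, so standard errors are exactly `sqrt(dispersion)` times
their Poisson counterparts. Step 2 warm-starts from the step-1
coefficients. statsmodels' Poisson GLM is used in the test suite as an
independent oracle for the same solution, never as the fitting path.

Rows are used only when complete: the likelihood drops any day whose
0–21-day window of mean temperatures has a gap, or whose response or
covariates are missing (complete-lag-window rule — deterministic, no
imputation). Calendar gaps in input files are filled with missing-value
rows at read time so positional lags equal day lags.

## Effect measures

- Heat/cold: cumulative RR at the empirical 99th/1st percentile of
  `tmean` versus the MMT, read off a prediction grid that spans the
  1st–99th percentile range at 0.1 °C steps with the exact percentile
  temperatures and the MMT inserted.
- Indices: RR per change equal to the median of the *nonzero* daily
  index values. Zero days are structural (the index is inactive), so the
  nonzero-day median matches the convention used for the index
  distribution tables; a config switch (`median_rule="all"`) computes
  the all-days variant because the choice changes the RR scale.
- Correlations among {tmean, inc, dec, hot, cold} are Pearson over all
  days, zeros included.

## Synthetic-data generator

The generator emulates a mid-latitude city at daily resolution:

- `tmean`: annual sinusoid (default mean 12 °C, amplitude 8 °C, summer
  peak mid-July) plus stationary AR(1) anomalies with lag-1 coefficient
  0.85 and innovation sd 2.0 °C (marginal anomaly sd ≈ 3.8 °C). The
  persistence matters scientifically: synoptic-scale anomalies lasting
  several days are what identifies the temperature effect once the
  seasonal spline has absorbed the annual cycle, and observed daily
  temperature anomalies have lag-1 autocorrelation near 0.85.
- DTR: mean 8 °C with a 2 °C summer-peaking seasonal modulation and
  1.5 °C noise, floored at 0.5 °C; `tmin/tmax = tmean ∓ DTR/2`. The
  season–DTR coupling makes the hot/cold DTR indices realistically
  asymmetric.
- Deaths: baseline 80/day, winter-peaking seasonal log-amplitude 0.10,
  small weekend effects; a V-shaped cumulative curve with vertex at the
  true MMT (19 °C) and slopes 0.015 (heat) / 0.010 (cold) per °C,
  distributed over lags by normalized geometric weights (ratio 0.8; an
  optional separate cold-side decay generates truths outside the
  single-surface model class); index effects γ=0.005, δ=0.003, φ=0.002,
  ϑ=0.001 per °C computed from the *true* MMT; overdispersion 1.3 via a
  gamma-mixed Poisson whose shape is set from the realized mean
  intensity so the Pearson dispersion of a correctly specified fit is
  centered at the target.

Everything is a deterministic function of (config, seed). The first 21
days use truncated, renormalized lag weights; those rows never enter a
fitted likelihood. What the generator does **not** emulate: heat-wave
clustering, humidity–temperature dependence beyond a noisy linear
trend, demographic drift, reporting artifacts, or cause-of-death
structure — so passing recovery tests demonstrates statistical
correctness of the estimator under the model's assumptions, not
robustness to everything real mortality series contain.

## Problem sizes in the shipped checks

The recovery study uses 200 replicates of 20 simulated years; the
quasi-Poisson calibration check uses 100 Poisson simulations at
n = 5000; the sensitivity-stability check uses one 10-year fixture; unit
fixtures are 2–4 years. These sizes give Monte-Carlo standard errors
small enough to detect biases of a few percent of each effect while the
whole suite stays in the order of a minute.

## Known limitations

- The MMT search returns a grid point (0.1 °C resolution) and reports no
  uncertainty for the MMT itself; downstream intervals are conditional
  on the estimated MMT, as in the two-step design.
- The φ attenuation described above is intrinsic to the two-step
  procedure whenever index effects of the generated kind exist; users
  comparing hot/cold DTR coefficients should keep the MMT estimation
  error in mind.
- No meta-analytic pooling across cities, no attributable-fraction
  computation, and no penalized/automatic knot selection: knots are
  fixed by the stated percentile rules.
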