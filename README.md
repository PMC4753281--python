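# tempmort

Temperature–mortality time-series modelling that separates the effect of
*mean daily temperature* from the effects of *temperature variation*
between and within days.

## The problem

Daily death counts respond to ambient temperature non-linearly and with
delay: heat kills over a few days, cold over up to three weeks, and both
relative to a city-specific comfort point — the minimum-mortality
temperature (MMT). A separate literature links mortality to temperature
*change*: the day-to-day swing in mean temperature and the diurnal
temperature range (DTR = tmax − tmin). Entering absolute temperature and
temperature change together in one regression is not identifiable without
constraints, because a change score is a linear combination of the
absolute values on neighboring days.

`tempmort` implements a modelling strategy that makes the decomposition
identifiable by defining four variation indices relative to the MMT:

- interday increase `inc_t = max(x_t − max(x_{t−1}, MMT), 0)`
- interday decrease `dec_t = max(min(x_{t−1}, MMT) − x_t, 0)`
- intraday hot `hot_t = tmax_t − tmin_t` if `x_t > MMT`, else 0
- intraday cold `cold_t = tmax_t − tmin_t` if `x_t < MMT`, else 0

where `x_t` is mean daily temperature. A warm-up only counts insofar as
it ends above the MMT (18→25 °C with MMT 20 °C scores inc = 5 °C), a
cool-down insofar as it ends below it (16→10 °C scores dec = 6 °C).

The model for the expected death count μ_t is quasi-Poisson with

```
log μ_t = α + s(x_t, ℓ; β) + γ·inc_t + δ·dec_t + φ·hot_t + ϑ·cold_t + Σ f(z_t; θ)
```

where `s(x, ℓ; β)` is a distributed-lag non-linear cross-basis over lags
0–21 days (quadratic B-spline in temperature with knots at the
10th/75th/90th percentiles; natural cubic spline in lag with knots
equally spaced on the log-lag scale, plus intercept), and `f(z; θ)` are a
natural spline of time (8 df per study year), day-of-week indicators, and
optionally a 3-df humidity spline. The analysis is two-step: step 1 fits
the cross-basis-only model and takes the MMT as the argmin of the overall
cumulative exposure–response curve; step 2 computes the indices from that
MMT and refits the full model.

Reported measures: cumulative relative risks for heat and cold (99th and
1st temperature percentile vs the MMT) and, for each index, the RR per
median nonzero change, all with 95 % Wald intervals. A ground-truth
synthetic-data generator and a six-variant sensitivity suite make every
stage testable without any data download.

## Worked example

```python
import tempmort as tm

config = tm.SynthConfig(n_years=10, seed=1)      # truth: MMT 19 °C, dispersion 1.3
series = tm.simulate_city(config)
results = tm.run_city_analysis(series)
print(results.rr_table[["label", "rr", "ci_low", "ci_high"]].round(3))
```

prints

```
        label    rr  ci_low  ci_high
         heat 1.137   1.047    1.235
         cold 1.271   1.187    1.360
 interday_inc 1.009   0.999    1.019
 interday_dec 1.004   0.998    1.010
 intraday_hot 1.011   0.981    1.043
intraday_cold 0.999   0.979    1.020
```

with `results.mmt.mmt` = 17.7 °C (78th percentile; the simulated truth
is 19 °C) and Pearson dispersion 1.30. Heat row: on days at the 99th
temperature percentile, mortality cumulated over the following 0–21 days
is 13.7 % above its MMT reference. The index rows are per-median-change
RRs — e.g. `interday_inc` 1.009 means a median-sized warm-up past the
MMT (~1.2 °C here) raises same-day mortality by 0.9 %.

The scripts in `examples/` walk through simulation, the indices, the
two-step analysis, and the sensitivity suite; `tempmort --help` exposes
the same pipeline as a command line (`simulate`, `analyze`,
`sensitivity`) for CSV series.

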