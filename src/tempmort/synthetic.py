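"""Synthetic daily temperature-mortality series with known ground truth.

The generator emulates a mid-latitude city: a seasonal sinusoid with
AR(1) noise for mean temperature, a diurnal range (DTR) process with a
summer-peaking seasonal modulation, and overdispersed daily death counts
from a log-linear model containing

* a V-shaped cumulative temperature effect ``g(x)`` centered at a true
  minimum-mortality temperature, distributed over lags 0..21 by
  normalized geometric weights,
* the four variation indices computed from the *true* MMT, entering
  linearly at lag 0 (so the fitted two-step pipeline, which must estimate
  the MMT, is tested against MMT-estimation error), and
* seasonal (winter-peaking) and day-of-week baseline modulation.

Overdispersion is introduced as a gamma-mixed Poisson whose shape is
chosen from the realized mean intensity so the Pearson dispersion of a
correctly specified fit is centered at the configured factor.  All
output is a deterministic function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .indices import interday_indices, intraday_indices
from .timeseries import DailySeries

__all__ = ["ClimateConfig", "DTRConfig", "MortalityConfig", "SynthConfig",
           "generate_weather", "generate_deaths", "simulate_city",
           "true_log_rr", "true_cumulative_rr", "lag_weights"]

_DAYS_PER_YEAR = 365.25
_SUMMER_PEAK_DOY = 196      # mid-July
_WINTER_PEAK_DOY = 15       # mid-January


@dataclass(frozen=True)
class ClimateConfig:
    """Mean-temperature process: seasonal sinusoid plus AR(1) noise."""
    annual_mean: float = 12.0       # degC
    annual_amplitude: float = 8.0   # degC, summer peak minus annual mean
    ar1: float = 0.85               # anomaly persistence, synoptic scale
    noise_sd: float = 2.0           # degC, AR(1) innovation sd

    def __post_init__(self):
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class DTRConfig:
    """Diurnal-range process; larger range in summer, floored above zero."""
    mean: float = 8.0               # degC
    seasonal_amplitude: float = 2.0  # degC, summer-peaking
    noise_sd: float = 1.5           # degC
    floor: float = 0.5              # degC, hard lower bound

    def __post_init__(self):
        if self.floor <= 0:
            raise ValueError("DTR floor must be > 0")


@dataclass(frozen=True)
class MortalityConfig:
    """Log-linear death-count model around a true V-shaped risk curve."""
    baseline: float = 80.0               # deaths/day at reference conditions
    seasonal_amplitude: float = 0.10     # log scale, winter-peaking
    dow_effects: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, 0.01)  # Mon..Sun, log
    heat_slope: float = 0.015            # log-RR per degC above the MMT
    cold_slope: float = 0.010            # log-RR per degC below the MMT
    lag_decay: float = 0.8               # geometric ratio of lag weights
    gamma_inc: float = 0.005             # per degC, interday increase
    delta_dec: float = 0.003             # per degC, interday decrease
    phi_hot: float = 0.002               # per degC, DTR on hot days
    theta_cold: float = 0.001            # per degC, DTR on cold days
    overdispersion: float = 1.3          # target Pearson dispersion (>= 1)
    lag_decay_cold: float | None = None  # optional separate cold-side decay

    def __post_init__(self):
        if self.overdispersion < 1:
            raise ValueError("overdispersion factor must be >= 1")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects needs 7 values (Mon..Sun)")


@dataclass(frozen=True)
class SynthConfig:
    n_years: int = 20
    seed: int = 0
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    dtr: DTRConfig = field(default_factory=DTRConfig)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    true_mmt: float = 19.0
    max_lag: int = 21
    start_date: str = "2001-01-01"
    humidity: bool = True

    @property
    def n_days(self) -> int:
        return int(round(self.n_years * _DAYS_PER_YEAR))

    def to_dict(self) -> dict:
        return asdict(self)


def _seasonal(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2 * np.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def lag_weights(decay: float, max_lag: int) -> np.ndarray:
    """Normalized geometric lag weights ``w_l ~ decay**l`` over 0..max_lag."""
    w = decay ** np.arange(max_lag + 1, dtype=float)
    return w / w.sum()


def true_log_rr(config: SynthConfig, x) -> np.ndarray:
    """Closed-form cumulative log-RR ``g(x)``: a V with vertex at the
    true MMT and the configured heat/cold slopes."""
    x = np.asarray(x, dtype=float)
    m = config.mortality
    return np.where(x >= config.true_mmt,
                    m.heat_slope * (x - config.true_mmt),
                    m.cold_slope * (config.true_mmt - x))


def true_cumulative_rr(config: SynthConfig, x):
    """``exp(g(x))`` — the target for curve-recovery checks."""
    return np.exp(true_log_rr(config, x))


def generate_weather(config: SynthConfig) -> DailySeries:
    """Temperatures (and humidity) only; deaths left unset.

    ``tmean`` is the annual sinusoid plus stationary AR(1) noise;
    ``tmin``/``tmax`` are ``tmean -/+ DTR/2`` with the DTR floored.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days
    dates = pd.date_range(config.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    cl = config.climate

    e = np.empty(n)
    marg_sd = cl.noise_sd / np.sqrt(1 - cl.ar1 ** 2) if cl.noise_sd else 0.0
    innov = rng.standard_normal(n)
    e[0] = marg_sd * innov[0]
    for t in range(1, n):
        e[t] = cl.ar1 * e[t - 1] + cl.noise_sd * innov[t]
    tmean = cl.annual_mean + cl.annual_amplitude * _seasonal(
        doy, _SUMMER_PEAK_DOY) + e

    d = config.dtr
    dtr = (d.mean + d.seasonal_amplitude * _seasonal(doy, _SUMMER_PEAK_DOY)
           + d.noise_sd * rng.standard_normal(n))
    dtr = np.maximum(dtr, d.floor)

    humidity = None
    if config.humidity:
        humidity = np.clip(
            70.0 - 0.8 * (tmean - cl.annual_mean)
            + 5.0 * rng.standard_normal(n), 20.0, 100.0)

    return DailySeries(dates=dates, tmean=tmean, tmin=tmean - dtr / 2,
                       tmax=tmean + dtr / 2, humidity=humidity,
                       city_label=f"synthetic(seed={config.seed})")


def _lagged_effect(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """``sum_l w_l g_{t-l}`` with truncated, renormalized windows at the
    start of the series (those rows never enter a fitted likelihood,
    which drops incomplete lag windows)."""
    n, L = g.size, w.size - 1
    out = np.zeros(n)
    wsum = np.zeros(n)
    for lag in range(L + 1):
        out[lag:] += w[lag] * g[: n - lag]
        wsum[lag:] += w[lag]
    return out / wsum


def generate_deaths(weather: DailySeries, config: SynthConfig) -> DailySeries:
    """Add overdispersed death counts to a weather series."""
    m = config.mortality
    rng = np.random.default_rng((config.seed, 0x5EED))
    doy = weather.dates.dayofyear.to_numpy(dtype=float)

    g = true_log_rr(config, weather.tmean)
    w_heat = lag_weights(m.lag_decay, config.max_lag)
    if m.lag_decay_cold is None:
        lag_term = _lagged_effect(g, w_heat)
    else:
        w_cold = lag_weights(m.lag_decay_cold, config.max_lag)
        g_heat = np.where(weather.tmean >= config.true_mmt, g, 0.0)
        g_cold = np.where(weather.tmean < config.true_mmt, g, 0.0)
        lag_term = (_lagged_effect(g_heat, w_heat)
                    + _lagged_effect(g_cold, w_cold))

    inc, dec = interday_indices(weather.tmean, config.true_mmt)
    hot, cold = intraday_indices(weather.tmin, weather.tmax, weather.tmean,
                                 config.true_mmt)
    log_mu = (np.log(m.baseline)
              + m.seasonal_amplitude * _seasonal(doy, _WINTER_PEAK_DOY)
              + np.asarray(m.dow_effects)[weather.day_of_week]
              + lag_term
              + m.gamma_inc * inc + m.delta_dec * dec
              + m.phi_hot * hot + m.theta_cold * cold)
    mu = np.exp(log_mu)

    if m.overdispersion > 1:
        # Poisson mixed over gamma(k, 1/k): Var = mu + mu^2/k, so the
        # Pearson dispersion is centered near 1 + E[mu]/k
        k = float(np.mean(mu)) / (m.overdispersion - 1.0)
        mu = mu * rng.gamma(shape=k, scale=1.0 / k, size=mu.size)
    deaths = rng.poisson(mu).astype(float)

    return DailySeries(dates=weather.dates, tmean=weather.tmean,
                       tmin=weather.tmin, tmax=weather.tmax,
                       deaths=deaths, humidity=weather.humidity,
                       city_label=weather.city_label)


def simulate_city(config: SynthConfig) -> DailySeries:
    """Weather plus deaths in one call."""
    return generate_deaths(generate_weather(config), config)
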