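"""Minimum-mortality temperature and the four temperature-variation indices.

Mean daily temperature, interday change and intraday change (DTR) cannot
all enter a regression freely without identifiability problems, so the
variation indices are defined *relative to the minimum-mortality
temperature* (MMT), the mean temperature at which the overall cumulative
temperature-mortality curve attains its minimum:

* interday increase:  ``inc_t = max(tmean_t - max(tmean_{t-1}, MMT), 0)``
* interday decrease:  ``dec_t = max(min(tmean_{t-1}, MMT) - tmean_t, 0)``
* intraday hot:       ``hot_t  = tmax_t - tmin_t`` if ``tmean_t > MMT`` else 0
* intraday cold:      ``cold_t = tmax_t - tmin_t`` if ``tmean_t < MMT`` else 0

so a temperature rise only counts as an "increase" insofar as it ends
above the MMT, a drop only as a "decrease" below it, and the diurnal
range is split into its hot-day and cold-day components.  At most one of
each pair is nonzero on any day, and ``hot + cold`` reconstructs the DTR
except on days whose mean is exactly at the MMT (both zero then, a
deterministic convention for a probability-zero event).

The MMT itself comes from a first-step model containing only the
temperature cross-basis (plus seasonal and day-of-week control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossbasis import CrossBasis, CumulativeCurve, cumulative_curve
from .timeseries import DailySeries, ValidationError

__all__ = ["MMTResult", "VariationIndices", "estimate_mmt",
           "interday_indices", "intraday_indices", "compute_indices",
           "restrict_to_extremes", "summarize_indices", "mmt_search_grid"]

INDEX_NAMES = ("interday_inc", "interday_dec", "intraday_hot", "intraday_cold")


@dataclass
class MMTResult:
    """Estimated minimum-mortality temperature and its provenance."""

    mmt: float
    mmt_percentile: float
    search_grid: np.ndarray
    curve: CumulativeCurve
    flat: bool = False           # True when the curve range is below tolerance
    fit: object = None           # step-1 FitResult
    crossbasis: CrossBasis | None = None


@dataclass
class VariationIndices:
    """The four daily variation-index vectors and the MMT that defined them."""

    interday_inc: np.ndarray
    interday_dec: np.ndarray
    intraday_hot: np.ndarray
    intraday_cold: np.ndarray
    mmt_used: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: getattr(self, n) for n in INDEX_NAMES})

    def __post_init__(self) -> None:
        for n in INDEX_NAMES:
            v = np.asarray(getattr(self, n), dtype=float)
            setattr(self, n, v)
            obs = np.isfinite(v)
            if np.any(v[obs] < 0):
                raise ValidationError(f"{n} has negative entries")


def interday_indices(tmean, mmt: float) -> tuple[np.ndarray, np.ndarray]:
    """Interday increase/decrease indices (degC/day).

    Day 0 has no predecessor and is set to 0 for both.  Days where today
    or yesterday is missing are NaN.
    """
    x = np.asarray(tmean, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 days for interday indices")
    prev = np.empty_like(x)
    prev[0] = np.nan
    prev[1:] = x[:-1]
    inc = np.maximum(x - np.maximum(prev, mmt), 0.0)
    dec = np.maximum(np.minimum(prev, mmt) - x, 0.0)
    inc[0] = dec[0] = 0.0
    miss = ~(np.isfinite(x) & np.isfinite(prev))
    miss[0] = False
    inc[miss] = np.nan
    dec[miss] = np.nan
    return inc, dec


def intraday_indices(tmin, tmax, tmean, mmt: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Intraday (DTR) indices on hot and cold days (degC).

    A day with ``tmean`` exactly at the MMT contributes to neither index.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    tmean = np.asarray(tmean, dtype=float)
    both = np.isfinite(tmin) & np.isfinite(tmax)
    if np.any(tmin[both] > tmax[both]):
        raise ValidationError("tmin > tmax")
    dtr = tmax - tmin
    hot = np.where(tmean > mmt, dtr, 0.0)
    cold = np.where(tmean < mmt, dtr, 0.0)
    miss = ~(both & np.isfinite(tmean))
    hot = np.where(miss, np.nan, hot)
    cold = np.where(miss, np.nan, cold)
    return hot, cold


def compute_indices(series: DailySeries, mmt: float) -> VariationIndices:
    """All four indices for a series, from a single MMT value."""
    inc, dec = interday_indices(series.tmean, mmt)
    if series.tmin is None or series.tmax is None:
        raise ValidationError("intraday indices require tmin and tmax")
    hot, cold = intraday_indices(series.tmin, series.tmax, series.tmean, mmt)
    return VariationIndices(inc, dec, hot, cold, mmt_used=float(mmt))


def restrict_to_extremes(index, pct: float = 95.0) -> np.ndarray:
    """Keep only extreme variation days.

    Entries at or below the ``pct``-th percentile of the *nonzero* values
    are zeroed; entries above it are retained unchanged.  Used by the
    sensitivity analysis probing whether only large day-to-day or
    within-day swings matter.
    """
    v = np.asarray(index, dtype=float).copy()
    obs = np.isfinite(v)
    nz = v[obs & (v > 0)]
    if nz.size == 0:
        warnings.warn("index has no nonzero days; returned unchanged",
                      stacklevel=2)
        return v
    cut = np.percentile(nz, pct)
    v[obs & (v <= cut)] = 0.0
    return v


def summarize_indices(indices: VariationIndices) -> pd.DataFrame:
    """Nonzero-day counts and quartiles per index.

    Days with a zero index value are excluded from the distributional
    summaries, mirroring the convention of reporting DTR statistics over
    the days on which the DTR component is active.
    """
    rows = []
    for name in INDEX_NAMES:
        v = np.asarray(getattr(indices, name), dtype=float)
        obs = v[np.isfinite(v)]
        nz = obs[obs > 0]
        row = {"index": name, "n_nonzero": int(nz.size),
               "pct_nonzero": 100.0 * nz.size / obs.size if obs.size else np.nan}
        for lab, q in (("min", 0), ("q25", 25), ("median", 50),
                       ("q75", 75), ("max", 100)):
            row[lab] = float(np.percentile(nz, q)) if nz.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")


def mmt_search_grid(tmean, *, pct_lo: float = 1.0, pct_hi: float = 99.0,
                    step: float = 0.1) -> np.ndarray:
    """Temperature grid for the MMT search: the empirical 1st-99th
    percentile range of mean temperature at 0.1 degC resolution (both
    percentile endpoints included)."""
    v = np.asarray(tmean, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = np.percentile(v, [pct_lo, pct_hi])
    grid = np.arange(lo, hi, step)
    return np.append(grid, hi)


def estimate_mmt(series: DailySeries, config=None) -> MMTResult:
    """Two-step procedure, step 1: estimate the MMT.

    Fits the model with only the temperature cross-basis plus seasonal
    trend and day-of-week (no variation terms), computes the overall
    cumulative curve over the search grid, and takes the argmin.  Ties
    are broken toward the grid value nearest the series median
    temperature.  A curve whose total range is below ``config.flat_tol``
    is flagged flat (the reported MMT is then arbitrary within the grid).
    """
    from .pipeline import AnalysisConfig          # circular at import time
    from .regression import build_design, fit_quasipoisson

    config = config or AnalysisConfig()
    cb = config.make_crossbasis(series)
    design = build_design(series, cb, indices=None, config=config)
    fit = fit_quasipoisson(design.y, design.X, roles=design.roles)

    grid = mmt_search_grid(series.tmean, step=config.mmt_grid_step)
    med = float(np.nanmedian(series.tmean))
    # reference only shifts the curve; argmin is reference-free
    curve0 = cumulative_curve(fit, cb, grid, ref_temp=med)
    lo = curve0.log_rr.min()
    ties = np.flatnonzero(curve0.log_rr == lo)
    pick = ties[np.argmin(np.abs(grid[ties] - med))]
    mmt = float(grid[pick])
    flat = bool(curve0.log_rr.max() - lo < config.flat_tol)
    if flat:
        warnings.warn("cumulative temperature-mortality curve is flat; "
                      "MMT is not meaningful", stacklevel=2)
    v = series.tmean[np.isfinite(series.tmean)]
    pctl = 100.0 * float(np.mean(v <= mmt))
    curve = cumulative_curve(fit, cb, grid, ref_temp=mmt)
    return MMTResult(mmt=mmt, mmt_percentile=pctl, search_grid=grid,
                     curve=curve, flat=flat, fit=fit, crossbasis=cb)
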