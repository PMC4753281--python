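"""Effect-measure summaries: heat/cold relative risks, per-median index
relative risks, and the correlation structure of the temperature measures.

The association with mean daily temperature is summarized as the overall
cumulative relative risk at the 99th (heat) and 1st (cold) empirical
temperature percentiles, with the minimum-mortality temperature as the
reference.  Each variation index's association is expressed as the
relative risk per change equal to the median of its *nonzero* daily
values (days on which the index is zero are excluded from that median,
consistent with how the index distributions themselves are summarized;
an all-days variant is available via ``median_rule``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbasis import CumulativeCurve
from .indices import VariationIndices
from .regression import FitResult

__all__ = ["RRSummary", "heat_cold_rr", "rr_per_median",
           "temperature_correlations", "Z975"]

Z975 = 1.959964


@dataclass
class RRSummary:
    """One reported effect: relative risk with 95% Wald bounds."""

    label: str
    rr: float
    ci_low: float
    ci_high: float
    contrast: str

    def __post_init__(self) -> None:
        if np.isfinite(self.rr) and not (
                0 < self.ci_low <= self.rr + 1e-12 and
                self.rr <= self.ci_high + 1e-12):
            raise ValueError(f"inconsistent CI for {self.label}")

    def as_dict(self) -> dict:
        return {"label": self.label, "rr": self.rr, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "contrast": self.contrast}


def _curve_at(curve: CumulativeCurve, temp: float) -> tuple[float, float]:
    i = int(np.argmin(np.abs(curve.grid - temp)))
    gap = abs(float(curve.grid[i]) - temp)
    if gap > 0.051:
        warnings.warn(
            f"target temperature {temp:.2f} is {gap:.2f} degC from the "
            "nearest curve grid point; extend the prediction grid",
            stacklevel=3)
    return float(curve.log_rr[i]), float(curve.se_log_rr[i])


def heat_cold_rr(curve: CumulativeCurve, tmean, *,
                 pct_heat: float = 99.0, pct_cold: float = 1.0
                 ) -> tuple[RRSummary, RRSummary]:
    """Overall cumulative RR for heat (99th pct) and cold (1st pct) vs MMT."""
    v = np.asarray(tmean, dtype=float)
    v = v[np.isfinite(v)]
    t_heat, t_cold = np.percentile(v, [pct_heat, pct_cold])
    out = []
    for label, temp, pct in (("heat", t_heat, pct_heat),
                             ("cold", t_cold, pct_cold)):
        lrr, se = _curve_at(curve, float(temp))
        out.append(RRSummary(
            label=label,
            rr=float(np.exp(lrr)),
            ci_low=float(np.exp(lrr - Z975 * se)),
            ci_high=float(np.exp(lrr + Z975 * se)),
            contrast=f"{pct:g}th pct ({temp:.1f} degC) vs MMT "
                     f"({curve.ref_temp:.1f} degC)"))
    return out[0], out[1]


def rr_per_median(fit: FitResult, index_name: str,
                  indices: VariationIndices, *,
                  median_rule: str = "nonzero") -> RRSummary:
    """RR per change equal to the median index value.

    ``rr = exp(coef * m)`` with ``m`` the median of the nonzero daily
    values (or of all days with ``median_rule="all"``); the CI scales the
    coefficient's Wald bounds by the same ``m``.
    """
    if index_name not in fit.coef.index:
        raise KeyError(f"{index_name} not among fitted coefficients")
    v = np.asarray(getattr(indices, index_name), dtype=float)
    v = v[np.isfinite(v)]
    if median_rule == "nonzero":
        v = v[v > 0]
    elif median_rule != "all":
        raise ValueError(f"unknown median_rule {median_rule!r}")
    if v.size == 0:
        return RRSummary(index_name, np.nan, np.nan, np.nan,
                         "undefined: index is zero on every day")
    m = float(np.median(v))
    b = float(fit.coef[index_name])
    se = float(fit.se[index_name])
    lo, hi = sorted(((b - Z975 * se) * m, (b + Z975 * se) * m))
    return RRSummary(
        label=index_name,
        rr=float(np.exp(b * m)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        contrast=f"per median nonzero change of {m:.2f} degC"
        if median_rule == "nonzero" else f"per median change of {m:.2f} degC")


def temperature_correlations(tmean, indices: VariationIndices) -> pd.DataFrame:
    """Pearson correlations among the five temperature measures.

    Computed over all study days, zeros included (structural zeros are
    part of each index's distribution).  Constant columns yield NaN rows
    with a warning.
    """
    df = pd.DataFrame({
        "tmean": np.asarray(tmean, dtype=float),
        "interday_inc": indices.interday_inc,
        "interday_dec": indices.interday_dec,
        "intraday_hot": indices.intraday_hot,
        "intraday_cold": indices.intraday_cold,
    }).dropna()
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant columns give undefined correlations: {const}",
                      stacklevel=2)
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
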