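"""Two-step city analysis and the sensitivity suite.

Step 1 fits a model with only the temperature cross-basis (plus seasonal
trend and day-of-week) and locates the minimum-mortality temperature
(MMT) on the overall cumulative curve.  Step 2 computes the four
variation indices from that MMT, adds them to the model, refits, and
summarizes: heat/cold cumulative relative risks at the 99th/1st
temperature percentiles, per-median RRs for the four indices, the index
distribution table, and the correlation matrix of the five temperature
measures.  Both steps share the same cross-basis object, so basis knots
are computed once.

The sensitivity suite re-runs the analysis under the standard variants
(seasonal-control df 6 and 10 per year, equally spaced exposure knots,
no variation terms, extreme-day-restricted indices, humidity
adjustment) and flags any variant whose heat or cold RR moves by more
than a configured threshold.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .crossbasis import (CrossBasis, CumulativeCurve, build_crossbasis,
                         cumulative_curve, default_lag_spec, default_var_spec)
from .indices import (INDEX_NAMES, MMTResult, VariationIndices,
                      compute_indices, estimate_mmt, restrict_to_extremes,
                      summarize_indices)
from .regression import FitResult, build_design, fit_quasipoisson
from .summaries import (RRSummary, heat_cold_rr, rr_per_median,
                        temperature_correlations)
from .timeseries import DailySeries

__all__ = ["AnalysisConfig", "CityResults", "run_city_analysis",
           "run_sensitivity_suite", "SENSITIVITY_VARIANTS"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All model options; the defaults reproduce the main analysis."""

    knot_percentiles: tuple = (10.0, 75.0, 90.0)
    knot_mode: str = "percentile"        # or "equal"
    max_lag: int = 21
    lag_knots: int = 3
    trend_df_per_year: float = 8.0
    include_variation_terms: bool = True
    include_humidity: bool = False
    humidity_df: int = 3
    extreme_restriction: bool = False
    extreme_pct: float = 95.0
    report_pct_heat: float = 99.0
    report_pct_cold: float = 1.0
    mmt_grid_step: float = 0.1
    flat_tol: float = 1e-6
    median_rule: str = "nonzero"         # RR-per-median scaling rule
    seed: int = 0

    def make_crossbasis(self, series: DailySeries) -> CrossBasis:
        var_spec = default_var_spec(series.tmean,
                                    percentiles=self.knot_percentiles,
                                    knot_mode=self.knot_mode)
        lag_spec = default_lag_spec(self.max_lag, self.lag_knots)
        return build_crossbasis(series.tmean, var_spec, lag_spec,
                                self.max_lag)

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12]}


@dataclass
class CityResults:
    """Everything a city run reports."""

    config: AnalysisConfig
    mmt: MMTResult
    indices: VariationIndices | None
    fit: FitResult
    curve: CumulativeCurve
    rr_summaries: list[RRSummary]
    index_summary: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def rr_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_dict() for s in self.rr_summaries])


def _report_grid(tmean, mmt: float, *, pct_lo: float, pct_hi: float,
                 step: float = 0.1) -> np.ndarray:
    """Prediction grid: 1st-99th percentile range at 0.1 degC steps, with
    the exact report percentiles and the MMT inserted."""
    v = np.asarray(tmean, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = np.percentile(v, [pct_lo, pct_hi])
    grid = np.arange(lo, hi, step)
    grid = np.union1d(grid, [lo, hi, mmt])
    return grid


def run_city_analysis(series: DailySeries,
                      config: AnalysisConfig | None = None) -> CityResults:
    """The full two-step analysis for one city."""
    config = config or AnalysisConfig()

    step1 = estimate_mmt(series, config)
    cb = step1.crossbasis

    indices = None
    if config.include_variation_terms:
        indices = compute_indices(series, step1.mmt)
        if config.extreme_restriction:
            for name in INDEX_NAMES:
                setattr(indices, name,
                        restrict_to_extremes(getattr(indices, name),
                                             config.extreme_pct))
        design = build_design(series, cb, indices, config)
        pad = np.zeros(design.X.shape[1])
        shared = [i for i, c in enumerate(design.X.columns)
                  if c in step1.fit.coef.index]
        pad[shared] = step1.fit.coef.loc[
            [design.X.columns[i] for i in shared]].to_numpy()
        fit = fit_quasipoisson(design.y, design.X, roles=design.roles,
                               start=pad)
    elif config.include_humidity:
        design = build_design(series, cb, None, config)
        fit = fit_quasipoisson(design.y, design.X, roles=design.roles)
    else:
        fit = step1.fit

    grid = _report_grid(series.tmean, step1.mmt,
                        pct_lo=config.report_pct_cold,
                        pct_hi=config.report_pct_heat,
                        step=config.mmt_grid_step)
    curve = cumulative_curve(fit, cb, grid, ref_temp=step1.mmt)

    heat, cold = heat_cold_rr(curve, series.tmean,
                              pct_heat=config.report_pct_heat,
                              pct_cold=config.report_pct_cold)
    rrs = [heat, cold]
    if indices is not None:
        for name in INDEX_NAMES:
            rrs.append(rr_per_median(fit, name, indices,
                                     median_rule=config.median_rule))
        index_summary = summarize_indices(indices)
        correlations = temperature_correlations(series.tmean, indices)
    else:
        index_summary = pd.DataFrame()
        correlations = pd.DataFrame()

    manifest = config.manifest()
    manifest.update({
        "city": series.city_label,
        "n_days": len(series),
        "n_obs": fit.n_obs,
        "mmt": step1.mmt,
        "mmt_percentile": step1.mmt_percentile,
        "exposure_knots": list(cb.var_spec.internal_knots),
        "lag_knots": list(cb.lag_spec.internal_knots),
        "dispersion": fit.dispersion,
        "irls_iterations": fit.n_iter,
    })
    return CityResults(config=config, mmt=step1, indices=indices, fit=fit,
                       curve=curve, rr_summaries=rrs,
                       index_summary=index_summary,
                       correlations=correlations, manifest=manifest)


SENSITIVITY_VARIANTS: dict[str, dict] = {
    "trend_df6": {"trend_df_per_year": 6.0},
    "trend_df10": {"trend_df_per_year": 10.0},
    "equal_knots": {"knot_mode": "equal"},
    "no_variation_terms": {"include_variation_terms": False},
    "extreme_indices": {"extreme_restriction": True},
    "humidity": {"include_humidity": True},
}


def run_sensitivity_suite(series: DailySeries,
                          config: AnalysisConfig | None = None,
                          *, flag_threshold: float = 0.05
                          ) -> pd.DataFrame:
    """Main analysis plus the six standard variants, as a tidy table.

    One row per (variant, effect measure); ``flagged`` marks RRs that
    moved by more than ``flag_threshold`` from the main analysis.  The
    humidity variant is skipped with a warning when the series has no
    humidity column.
    """
    config = config or AnalysisConfig()
    runs: dict[str, CityResults] = {"main": run_city_analysis(series, config)}
    for name, delta in SENSITIVITY_VARIANTS.items():
        if name == "humidity" and series.humidity is None:
            warnings.warn("series has no humidity column; skipping the "
                          "humidity variant", stacklevel=2)
            continue
        runs[name] = run_city_analysis(series, replace(config, **delta))

    main_rr = {s.label: s.rr for s in runs["main"].rr_summaries}
    rows = []
    for vname, res in runs.items():
        for s in res.rr_summaries:
            rows.append({
                "variant": vname, "label": s.label, "rr": s.rr,
                "ci_low": s.ci_low, "ci_high": s.ci_high,
                "delta_vs_main": s.rr - main_rr.get(s.label, np.nan),
                "flagged": bool(abs(s.rr - main_rr.get(s.label, np.nan))
                                > flag_threshold),
            })
    return pd.DataFrame(rows)
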