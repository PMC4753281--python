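"""Relative-risk summaries and temperature correlations."""

import numpy as np
import pandas as pd
import pytest

import tempmort as tm
from tempmort.crossbasis import build_crossbasis, cumulative_curve, \
    default_lag_spec, default_var_spec
from tempmort.regression import build_design, fit_quasipoisson
from tempmort.summaries import (Z975, heat_cold_rr, rr_per_median,
                                temperature_correlations)

from conftest import fake_fit

RNG = np.random.default_rng(42)


def _null_curve(tmean):
    vs = default_var_spec(tmean)
    cb = build_crossbasis(tmean, vs, default_lag_spec(21, 3), 21)
    fit = fake_fit(cb, np.zeros(cb.matrix.shape[1]),
                   np.eye(cb.matrix.shape[1]) * 1e-4)
    grid = np.linspace(np.percentile(tmean, 1), np.percentile(tmean, 99), 400)
    return cumulative_curve(fit, cb, grid, ref_temp=float(np.median(tmean)))


def test_null_fit_gives_unit_heat_and_cold_rr():
    tmean = RNG.uniform(-5, 30, 600)
    heat, cold = heat_cold_rr(_null_curve(tmean), tmean)
    assert heat.rr == pytest.approx(1.0)
    assert cold.rr == pytest.approx(1.0)
    assert heat.ci_low <= 1.0 <= heat.ci_high


def test_rr_per_median_direct_arithmetic():
    fit = tm.FitResult(
        coef=pd.Series({"interday_inc": 0.01}),
        vcov=pd.DataFrame([[0.002 ** 2]], index=["interday_inc"],
                          columns=["interday_inc"]),
        dispersion=1.0, n_obs=100, column_roles={})
    idx = tm.VariationIndices(
        interday_inc=np.array([0.0, 5.0, 5.0, 0.0, 5.0]),
        interday_dec=np.zeros(5), intraday_hot=np.zeros(5),
        intraday_cold=np.zeros(5), mmt_used=20.0)
    s = rr_per_median(fit, "interday_inc", idx)
    assert s.rr == pytest.approx(np.exp(0.05), abs=1e-12)
    assert s.ci_low == pytest.approx(np.exp(0.05 - Z975 * 0.01), abs=1e-12)
    assert s.ci_high == pytest.approx(np.exp(0.05 + Z975 * 0.01), abs=1e-12)


def test_zero_coefficient_gives_unit_rr():
    fit = tm.FitResult(
        coef=pd.Series({"intraday_hot": 0.0}),
        vcov=pd.DataFrame([[1e-6]], index=["intraday_hot"],
                          columns=["intraday_hot"]),
        dispersion=1.0, n_obs=10, column_roles={})
    idx = tm.VariationIndices(
        interday_inc=np.zeros(3), interday_dec=np.zeros(3),
        intraday_hot=np.array([0.0, 4.0, 8.0]), intraday_cold=np.zeros(3),
        mmt_used=15.0)
    assert rr_per_median(fit, "intraday_hot", idx).rr == 1.0


def test_all_zero_index_reported_undefined():
    fit = tm.FitResult(
        coef=pd.Series({"interday_dec": 0.1}),
        vcov=pd.DataFrame([[1e-4]], index=["interday_dec"],
                          columns=["interday_dec"]),
        dispersion=1.0, n_obs=10, column_roles={})
    idx = tm.VariationIndices(
        interday_inc=np.zeros(3), interday_dec=np.zeros(3),
        intraday_hot=np.zeros(3), intraday_cold=np.zeros(3), mmt_used=15.0)
    s = rr_per_median(fit, "interday_dec", idx)
    assert np.isnan(s.rr) and "undefined" in s.contrast


def test_rr_per_median_invariant_to_index_rescaling(small_series):
    """Doubling an index column halves its coefficient and doubles its
    median, leaving the per-median RR unchanged (refit oracle)."""
    s = small_series
    cfg = tm.AnalysisConfig()
    cb = cfg.make_crossbasis(s)
    idx = tm.compute_indices(s, mmt=15.0)
    d = build_design(s, cb, idx, cfg)
    fit = fit_quasipoisson(d.y, d.X, roles=d.roles)

    idx2 = tm.VariationIndices(
        interday_inc=idx.interday_inc * 2, interday_dec=idx.interday_dec,
        intraday_hot=idx.intraday_hot, intraday_cold=idx.intraday_cold,
        mmt_used=idx.mmt_used)
    d2 = build_design(s, cb, idx2, cfg)
    fit2 = fit_quasipoisson(d2.y, d2.X, roles=d2.roles)

    assert fit2.coef["interday_inc"] == pytest.approx(
        fit.coef["interday_inc"] / 2, rel=1e-6)
    a = rr_per_median(fit, "interday_inc", idx)
    b = rr_per_median(fit2, "interday_inc", idx2)
    assert b.rr == pytest.approx(a.rr, rel=1e-8)
    assert b.ci_low == pytest.approx(a.ci_low, rel=1e-8)


def test_heat_cold_rr_invariant_to_dow_recoding(small_series):
    """Swapping the day-of-week reference category spans the same model
    space, so the cumulative curve contrasts must not move."""
    s = small_series
    cfg = tm.AnalysisConfig()
    cb = cfg.make_crossbasis(s)
    d = build_design(s, cb, None, cfg)
    fit = fit_quasipoisson(d.y, d.X, roles=d.roles)

    X2 = d.X.copy()
    dow_cols = [c for c in X2.columns if c.startswith("dow_")]
    sun = X2["dow_Sun"].to_numpy().copy()
    mon = 1.0 - X2[dow_cols].sum(axis=1).to_numpy()
    X2 = X2.drop(columns=["dow_Sun"])
    X2["dow_Mon"] = mon                     # Sunday becomes the reference
    fit2 = fit_quasipoisson(d.y, X2, roles=d.roles)

    grid = np.linspace(*np.percentile(s.tmean, [1, 99]), 200)
    c1 = tm.cumulative_curve(fit, cb, grid, ref_temp=15.0)
    c2 = tm.cumulative_curve(fit2, cb, grid, ref_temp=15.0)
    h1, co1 = heat_cold_rr(c1, s.tmean)
    h2, co2 = heat_cold_rr(c2, s.tmean)
    assert h2.rr == pytest.approx(h1.rr, rel=1e-7)
    assert co2.rr == pytest.approx(co1.rr, rel=1e-7)


class TestCorrelations:

    def _indices(self, n=500):
        s = tm.simulate_city(tm.SynthConfig(n_years=2, seed=13))
        return s.tmean, tm.compute_indices(s, mmt=15.0)

    def test_matches_textbook_pearson_formula(self):
        tmean, idx = self._indices()
        corr = temperature_correlations(tmean, idx)
        a, b = tmean, idx.intraday_hot
        expect = (np.mean((a - a.mean()) * (b - b.mean()))
                  / (a.std() * b.std()))
        assert corr.loc["tmean", "intraday_hot"] == pytest.approx(
            expect, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        tmean, idx = self._indices()
        corr = temperature_correlations(tmean, idx)
        v = corr.to_numpy()
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 1.0)
        assert np.nanmax(np.abs(v)) <= 1.0 + 1e-12

    def test_disjoint_supports_make_inc_dec_nonpositive(self):
        tmean, idx = self._indices()
        corr = temperature_correlations(tmean, idx)
        assert corr.loc["interday_inc", "interday_dec"] <= 0.05
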