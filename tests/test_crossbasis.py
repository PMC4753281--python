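"""Cross-basis construction and cumulative curves vs brute-force oracles."""

import numpy as np
import pytest

import tempmort as tm
from tempmort.basis import spline_basis
from tempmort.crossbasis import (build_crossbasis, cumulative_curve,
                                 default_lag_spec, default_var_spec)

from conftest import fake_fit

RNG = np.random.default_rng(77)


def naive_crossbasis(x, var_spec, lag_spec, max_lag):
    """Independent triple loop over (t, j*k, l)."""
    B = spline_basis(x, var_spec)
    C = spline_basis(np.arange(max_lag + 1, dtype=float), lag_spec)
    n, J, K = len(x), B.shape[1], C.shape[1]
    out = np.full((n, J * K), np.nan)
    for t in range(max_lag, n):
        col = 0
        for j in range(J):
            for k in range(K):
                out[t, col] = sum(B[t - l, j] * C[l, k]
                                  for l in range(max_lag + 1))
                col += 1
    return out


def random_series(n, rng):
    return rng.uniform(-5, 30, size=n)


def test_crossbasis_matches_naive_double_sum():
    for _ in range(3):
        x = random_series(200, RNG)
        vs = default_var_spec(x)
        ls = default_lag_spec(21, 3)
        cb = build_crossbasis(x, vs, ls, 21)
        expect = naive_crossbasis(x, vs, ls, 21)
        ok = cb.valid_rows
        assert not ok[:21].any() and ok[21:].all()
        assert np.abs(cb.matrix[ok] - expect[ok]).max() <= 1e-10
        assert np.isnan(cb.matrix[~ok]).all()


def test_constant_series_gives_identical_valid_rows():
    x = np.full(100, 17.3)
    vs = tm.SplineSpec("quadratic-bspline", (16.0,), (10.0, 25.0))
    cb = build_crossbasis(x, vs, default_lag_spec(21, 3), 21)
    rows = cb.matrix[cb.valid_rows]
    assert np.abs(rows - rows[0]).max() == 0.0


def test_zero_lag_degenerates_to_exposure_basis():
    x = random_series(50, RNG)
    vs = default_var_spec(x)
    cb = build_crossbasis(x, vs, None, 0)
    assert np.abs(cb.matrix - spline_basis(x, vs)).max() == 0.0


def test_series_shorter_than_window_rejected():
    with pytest.raises(ValueError):
        build_crossbasis(np.ones(21), default_var_spec(np.arange(30.0)),
                         default_lag_spec(21, 3), 21)


def test_missing_days_invalidate_their_windows():
    x = random_series(120, RNG)
    x[60] = np.nan
    cb = build_crossbasis(x, default_var_spec(x[np.isfinite(x)]),
                          default_lag_spec(21, 3), 21)
    assert not cb.valid_rows[60:82].any()
    assert cb.valid_rows[59] and cb.valid_rows[82]


class TestCumulativeCurve:

    def _setup(self, n=260):
        x = random_series(n, RNG)
        vs = default_var_spec(x)
        cb = build_crossbasis(x, vs, default_lag_spec(21, 3), 21)
        p = cb.matrix.shape[1]
        beta = RNG.normal(0, 0.02, p)
        a = RNG.normal(0, 0.1, (p, p))
        vcov = a @ a.T * 1e-4
        return cb, fake_fit(cb, beta, vcov)

    def test_reference_point_has_zero_logrr_and_se(self):
        cb, fit = self._setup()
        grid = np.array([0.0, 12.5, 25.0])
        curve = cumulative_curve(fit, cb, grid, ref_temp=12.5)
        assert curve.log_rr[1] == 0.0 and curve.se_log_rr[1] == 0.0
        assert np.all(curve.se_log_rr >= 0)

    def test_null_coefficients_give_flat_curve(self):
        cb, _ = self._setup()
        fit = fake_fit(cb, np.zeros(cb.matrix.shape[1]),
                       np.eye(cb.matrix.shape[1]))
        curve = cumulative_curve(fit, cb, np.linspace(0, 25, 40), 10.0)
        assert np.abs(curve.log_rr).max() == 0.0

    def test_matches_per_lag_summation_oracle(self):
        cb, fit = self._setup()
        grid = np.linspace(-2, 28, 37)
        ref = 15.0
        curve = cumulative_curve(fit, cb, grid, ref)
        B = cb.exposure_basis(grid) - cb.exposure_basis([ref])
        C = cb.lag_basis()
        beta = fit.coef.loc[cb.column_names].to_numpy().reshape(
            cb.n_var, cb.n_lag)
        expect = np.zeros(grid.size)
        for l in range(cb.max_lag + 1):
            expect += B @ (beta @ C[l])
        assert np.abs(curve.log_rr - expect).max() <= 1e-10

    def test_grid_refinement_preserves_shared_points(self):
        cb, fit = self._setup()
        coarse = np.linspace(0, 25, 26)
        fine = np.sort(np.concatenate([coarse, coarse[:-1] + 0.5]))
        c1 = cumulative_curve(fit, cb, coarse, 10.0)
        c2 = cumulative_curve(fit, cb, fine, 10.0)
        shared = np.searchsorted(fine, coarse)
        # identical inputs; only BLAS blocking differs between the two
        # evaluation lengths, so agreement is to a few ulps
        assert np.abs(c1.log_rr - c2.log_rr[shared]).max() <= 1e-14

    def test_missing_coefficients_rejected(self):
        cb, fit = self._setup()
        fit.coef = fit.coef.iloc[:-2]
        with pytest.raises(ValueError):
            cumulative_curve(fit, cb, [10.0], 10.0)


def test_curve_invariant_to_centering_reparameterization(small_series):
    """Centering the cross-basis columns only shifts the intercept; the
    cumulative curve, built from basis contrasts, must not move."""
    import pandas as pd
    from tempmort.regression import build_design, fit_quasipoisson

    s = small_series
    cfg = tm.AnalysisConfig()
    cb = cfg.make_crossbasis(s)
    design = build_design(s, cb, None, cfg)
    fit = fit_quasipoisson(design.y, design.X, roles=design.roles)

    Xc = design.X.copy()
    names = cb.column_names
    center = Xc[names].mean()
    Xc[names] = Xc[names] - center
    fit_c = fit_quasipoisson(design.y, Xc, roles=design.roles)

    grid = np.linspace(*np.percentile(s.tmean, [2, 98]), 30)
    a = cumulative_curve(fit, cb, grid, ref_temp=15.0)
    b = cumulative_curve(fit_c, cb, grid, ref_temp=15.0)
    assert np.abs(a.log_rr - b.log_rr).max() <= 1e-6
    assert np.abs(a.se_log_rr - b.se_log_rr).max() <= 1e-6
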