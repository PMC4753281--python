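"""Bidimensional exposure-lag cross-basis and cumulative risk curves.

The cross-basis expresses a smooth exposure-lag-response surface
``s(x, l)`` as a tensor product of an exposure basis ``b_j`` (quadratic
B-spline of mean temperature) and a lag basis ``c_k`` (natural cubic
spline of lag, with intercept).  Row ``t``, column ``(j, k)`` holds

    sum_{l=0..L} b_j(x_{t-l}) * c_k(l)

so the fitted surface coefficients enter an ordinary (quasi-)Poisson
design matrix as L+1-day moving tensor sums.  The basis is deliberately
NOT centered at construction; all referencing to the minimum-mortality
temperature happens afterwards, in :func:`cumulative_curve`, through
basis differences.  This keeps the design matrix independent of the
later-estimated reference temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import (NATURAL_CUBIC, QUADRATIC_BSPLINE, SplineSpec,
                    log_lag_knots, spline_basis)

__all__ = ["CrossBasis", "CumulativeCurve", "build_crossbasis",
           "cumulative_curve", "default_var_spec", "default_lag_spec"]


@dataclass
class CrossBasis:
    """Cross-basis design block plus the metadata needed to predict from it.

    Attributes
    ----------
    matrix
        ``(n_days, J*K)`` array; rows with incomplete lag windows are NaN.
    var_spec, lag_spec
        The exposure and lag spline specifications.
    max_lag
        Largest lag in days (the window is lags ``0..max_lag``).
    column_index
        For each column, its ``(j, k)`` pair of exposure/lag basis indices.
    valid_rows
        Boolean mask of rows whose whole lag window is observed.
    """

    matrix: np.ndarray
    var_spec: SplineSpec
    lag_spec: SplineSpec | None
    max_lag: int
    column_index: list[tuple[int, int]]
    valid_rows: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.column_names:
            self.column_names = [f"cb_v{j}l{k}" for j, k in self.column_index]

    @property
    def n_var(self) -> int:
        return self.var_spec.ndim

    @property
    def n_lag(self) -> int:
        return 1 if self.lag_spec is None else self.lag_spec.ndim

    def exposure_basis(self, x) -> np.ndarray:
        """Exposure basis ``b_j`` evaluated at arbitrary temperatures."""
        return spline_basis(np.asarray(x, dtype=float), self.var_spec)

    def lag_basis(self) -> np.ndarray:
        """Lag basis ``c_k`` at the integer lags ``0..max_lag``."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        if self.lag_spec is None:
            return np.ones((1, 1))
        return spline_basis(lags, self.lag_spec)


@dataclass
class CumulativeCurve:
    """Overall (lag-cumulated) log relative risk over a temperature grid."""

    grid: np.ndarray
    log_rr: np.ndarray
    se_log_rr: np.ndarray
    ref_temp: float

    def rr(self, z: float = 1.959964) -> pd.DataFrame:
        """RR and Wald 95% bounds, ``exp(log_rr +/- z * se)``."""
        return pd.DataFrame({
            "temperature": self.grid,
            "rr": np.exp(self.log_rr),
            "rr_low": np.exp(self.log_rr - z * self.se_log_rr),
            "rr_high": np.exp(self.log_rr + z * self.se_log_rr),
        })


def default_var_spec(tmean, *, percentiles=(10, 75, 90),
                     knot_mode: str = "percentile") -> SplineSpec:
    """Exposure-response spec: quadratic B-spline, knots at the 10th/75th/
    90th percentiles of observed mean temperature (or equally spaced over
    its range), boundary knots at the observed min/max."""
    v = np.asarray(tmean, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = float(v.min()), float(v.max())
    if knot_mode == "percentile":
        knots = tuple(float(np.percentile(v, p)) for p in percentiles)
    elif knot_mode == "equal":
        knots = tuple(np.linspace(lo, hi, len(percentiles) + 2)[1:-1])
    else:
        raise ValueError(f"unknown knot_mode {knot_mode!r}")
    return SplineSpec(QUADRATIC_BSPLINE, knots, (lo, hi), with_intercept=False)


def default_lag_spec(max_lag: int = 21, n_knots: int = 3) -> SplineSpec:
    """Lag-response spec: natural cubic spline over lags 0..max_lag with
    interior knots equally spaced on the log scale, and an intercept."""
    knots = tuple(log_lag_knots(max_lag, n_knots))
    return SplineSpec(NATURAL_CUBIC, knots, (0.0, float(max_lag)),
                      with_intercept=True)


def build_crossbasis(tmean, var_spec: SplineSpec,
                     lag_spec: SplineSpec | None = None,
                     max_lag: int = 21) -> CrossBasis:
    """Build the cross-basis matrix for a daily temperature series.

    The first ``max_lag`` rows have incomplete lag windows and are flagged
    invalid (NaN), as is any row whose window covers a missing temperature.
    ``max_lag=0`` degenerates to the plain same-day exposure basis.
    """
    x = np.asarray(tmean, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError(
            f"series length {n} must exceed max_lag {max_lag}")
    if max_lag > 0 and lag_spec is None:
        lag_spec = default_lag_spec(max_lag)
    if max_lag == 0:
        lag_spec = None

    bx = spline_basis(x, var_spec)            # (n, J); NaN rows for NaN x
    cb_meta = CrossBasis(matrix=np.empty(0), var_spec=var_spec,
                         lag_spec=lag_spec, max_lag=max_lag,
                         column_index=[], valid_rows=np.empty(0, bool))
    cl = cb_meta.lag_basis()                  # (L+1, K)
    J, K = bx.shape[1], cl.shape[1]

    mat = np.zeros((n, J * K))
    obs = np.isfinite(x)
    for lag in range(max_lag + 1):
        shifted = np.full_like(bx, np.nan)
        shifted[lag:] = bx[: n - lag]
        mat += (shifted[:, :, None] * cl[lag][None, None, :]).reshape(n, J * K)

    valid = np.ones(n, dtype=bool)
    for lag in range(max_lag + 1):
        w = np.zeros(n, dtype=bool)
        w[lag:] = obs[: n - lag]
        valid &= w
    mat[~valid] = np.nan

    cb_meta.matrix = mat
    cb_meta.column_index = [(j, k) for j in range(J) for k in range(K)]
    cb_meta.valid_rows = valid
    cb_meta.column_names = [f"cb_v{j}l{k}" for j, k in cb_meta.column_index]
    return cb_meta


def cumulative_curve(fit, cb: CrossBasis, grid, ref_temp: float,
                     *, range_tol: float = 5.0) -> CumulativeCurve:
    """Overall cumulative exposure-response curve with delta-method SEs.

    For each grid temperature ``x`` the contrast against the reference is

        log RR(x) = sum_{j,k} beta_{jk} [b_j(x) - b_j(ref)] S_k,
        S_k = sum_{l=0..L} c_k(l),

    with the standard error from the quadratic form of the contrast vector
    and the fitted (dispersion-scaled) covariance.  ``fit`` must expose
    ``coef``/``vcov`` indexed by the cross-basis column names.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    names = cb.column_names
    missing = [nm for nm in names if nm not in fit.coef.index]
    if missing:
        raise ValueError(f"fit lacks cross-basis coefficients: {missing[:3]}")
    beta = fit.coef.loc[names].to_numpy()
    vcov = fit.vcov.loc[names, names].to_numpy()

    lo, hi = cb.var_spec.boundary_knots
    if not (lo - range_tol <= ref_temp <= hi + range_tol):
        warnings.warn(
            f"reference temperature {ref_temp:.2f} lies far outside the "
            f"fitted exposure range [{lo:.2f}, {hi:.2f}]", stacklevel=2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # grid may legitimately extend past fit range
        bdiff = cb.exposure_basis(grid) - cb.exposure_basis([ref_temp])
    s_k = cb.lag_basis().sum(axis=0)                        # (K,)
    contrast = (bdiff[:, :, None] * s_k[None, None, :]).reshape(
        grid.size, len(names))
    log_rr = contrast @ beta
    var = np.einsum("gi,ij,gj->g", contrast, vcov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    # the contrast at x == ref_temp is identically zero; make it exact
    at_ref = grid == ref_temp
    log_rr[at_ref] = 0.0
    se[at_ref] = 0.0
    return CumulativeCurve(grid=grid, log_rr=log_rr, se_log_rr=se,
                           ref_temp=float(ref_temp))
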