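"""Design-matrix assembly and overdispersed Poisson fitting.

The full model for the expected death count on day ``t`` is

    log mu_t = alpha + s(tmean_t, lag; beta)
               + gamma*inc_t + delta*dec_t + phi*hot_t + theta_w*cold_t
               + ns(time; 8 df per study year) + day-of-week
               [+ ns(humidity; 3 df)]

with the cross-basis ``s`` spanning lags 0..21 and the four variation
indices entering linearly at lag 0 only.  Estimation is quasi-Poisson:
point estimates are the Poisson maximum-likelihood solution (log link,
iteratively reweighted least squares); the covariance is the inverse
Fisher information scaled by the Pearson dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .crossbasis import CrossBasis
from .basis import NATURAL_CUBIC, SplineSpec, natural_cubic_basis
from .timeseries import DailySeries, ValidationError

__all__ = ["FitResult", "Design", "build_design", "fit_quasipoisson",
           "FitError"]

DOW_NAMES = ("Tue", "Wed", "Thu", "Fri", "Sat", "Sun")   # Monday = reference


class FitError(RuntimeError):
    """Fitter failed to converge or the design is unusable."""


@dataclass
class FitResult:
    """Quasi-Poisson fit: coefficients, scaled covariance, bookkeeping."""

    coef: pd.Series
    vcov: pd.DataFrame
    dispersion: float
    n_obs: int
    column_roles: dict[str, str]
    n_iter: int = 0
    deviance: float = np.nan

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())),
                         index=self.coef.index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.coef,
            "se": self.se,
            "role": pd.Series(self.column_roles),
        })


@dataclass
class Design:
    """Assembled regression inputs: complete-case rows only."""

    X: pd.DataFrame
    y: np.ndarray
    mask: np.ndarray            # over the original daily rows
    roles: dict[str, str]


def _trend_spline(n: int, mask: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline of the sequential day index, ``df`` columns,
    interior knots equally spaced over the used rows."""
    idx = np.arange(n, dtype=float)
    used = idx[mask]
    lo, hi = used[0], used[-1]
    interior = tuple(np.linspace(lo, hi, df + 1)[1:-1]) if df > 1 else ()
    spec = SplineSpec(NATURAL_CUBIC, interior, (lo, hi), with_intercept=False)
    return natural_cubic_basis(idx, spec)


def _humidity_spline(humidity: np.ndarray, df: int = 3) -> np.ndarray:
    v = humidity[np.isfinite(humidity)]
    probs = np.linspace(0, 100, df + 1)[1:-1]
    interior = tuple(np.percentile(v, probs))
    spec = SplineSpec(NATURAL_CUBIC, interior,
                      (float(v.min()), float(v.max())), with_intercept=False)
    return natural_cubic_basis(humidity, spec)


def build_design(series: DailySeries, cb: CrossBasis, indices=None,
                 config=None) -> Design:
    """Assemble the design matrix, response and row mask.

    Columns: intercept; cross-basis block; the four variation indices
    (when given); seasonal trend spline with ``round(8 * study_years)``
    degrees of freedom (configurable per year); six day-of-week
    indicators (Monday reference); optional humidity spline.  Rows with
    an incomplete lag window, missing response, or any missing covariate
    are masked out (complete-lag-window rule).
    """
    from .pipeline import AnalysisConfig
    config = config or AnalysisConfig()
    n = len(series)
    if series.deaths is None:
        raise ValidationError("series has no death counts to fit")

    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    roles: dict[str, str] = {"const": "intercept"}

    for name, col in zip(cb.column_names, cb.matrix.T):
        cols[name] = col
        roles[name] = "crossbasis"

    if indices is not None:
        if getattr(indices, "mmt_used", None) is None:
            raise ValidationError("indices lack their defining MMT")
        for name in ("interday_inc", "interday_dec",
                     "intraday_hot", "intraday_cold"):
            cols[name] = getattr(indices, name)
            roles[name] = "variation_index"

    mask = cb.valid_rows & np.isfinite(series.deaths)
    for v in cols.values():
        mask &= np.isfinite(v)

    df_trend = int(round(config.trend_df_per_year * series.n_years))
    trend = _trend_spline(n, mask, df_trend)
    for i in range(trend.shape[1]):
        cols[f"trend{i + 1}"] = trend[:, i]
        roles[f"trend{i + 1}"] = "trend"

    dow = series.day_of_week
    for i, name in enumerate(DOW_NAMES, start=1):
        cols[f"dow_{name}"] = (dow == i).astype(float)
        roles[f"dow_{name}"] = "day_of_week"

    if config.include_humidity:
        if series.humidity is None:
            raise ValidationError("humidity adjustment requested but the "
                                  "series has no humidity column")
        hum = _humidity_spline(series.humidity, config.humidity_df)
        for i in range(hum.shape[1]):
            cols[f"humid{i + 1}"] = hum[:, i]
            roles[f"humid{i + 1}"] = "humidity"
        mask &= np.isfinite(series.humidity)

    X = pd.DataFrame(cols)
    Xm = X.loc[mask]
    y = series.deaths[mask]
    return Design(X=Xm.reset_index(drop=True), y=y, mask=mask, roles=roles)


def _diagnose_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    tol = d.max() * X.shape[0] * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(d < tol)]


def fit_quasipoisson(y, X: pd.DataFrame, *, roles: dict[str, str] | None = None,
                     tol: float = 1e-9, max_iter: int = 100,
                     start: np.ndarray | None = None) -> FitResult:
    """Quasi-Poisson GLM via iteratively reweighted least squares.

    Point estimates solve the Poisson score equations (log link);
    convergence is declared when the relative deviance change falls below
    ``tol`` (default 1e-9) within ``max_iter`` iterations.  The Pearson
    dispersion ``X2 / (n - p)`` scales the inverse Fisher information to
    give the quasi-likelihood covariance, so standard errors are exactly
    ``sqrt(dispersion)`` times their Poisson counterparts.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    A = np.ascontiguousarray(X.to_numpy(dtype=float))
    n, p = A.shape
    if n <= p:
        raise FitError(f"{n} rows for {p} parameters")
    if np.all(y == y[0]):
        raise FitError("zero-variance response")

    if start is not None:
        beta = np.asarray(start, dtype=float)
        eta = A @ beta
        mu = np.exp(eta)
    else:
        mu = y + np.mean(y) * 0.1 + 0.1
        eta = np.log(mu)
        beta = None

    def deviance(mu_: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu_), 0.0)
        return 2.0 * float(np.sum(term - (y - mu_)))

    dev = deviance(mu)
    trace = [dev]
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        sw = np.sqrt(mu)
        Aw = A * sw[:, None]
        bw = z * sw
        xtx = Aw.T @ Aw
        xty = Aw.T @ bw
        try:
            c, low = linalg.cho_factor(xtx, check_finite=False)
            beta = linalg.cho_solve((c, low), xty, check_finite=False)
        except np.linalg.LinAlgError:
            bad = _diagnose_collinear(Aw, names)
            raise FitError(f"design is rank deficient; collinear columns: "
                           f"{bad or 'unidentified'}") from None
        eta = A @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = deviance(mu)
        trace.append(new_dev)
        if abs(new_dev - dev) / (abs(dev) + 0.1) < tol:
            dev = new_dev
            break
        dev = new_dev
    else:
        raise FitError(f"IRLS did not converge in {max_iter} iterations; "
                       f"deviance trace tail {trace[-4:]}")

    pearson = float(np.sum((y - mu) ** 2 / mu))
    dispersion = pearson / (n - p)
    xtwx = (A * mu[:, None]).T @ A
    info_inv = linalg.inv(xtwx, check_finite=False)
    info_inv = (info_inv + info_inv.T) / 2.0
    vcov = dispersion * info_inv
    return FitResult(
        coef=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        dispersion=dispersion,
        n_obs=n,
        column_roles=dict(roles or {}),
        n_iter=it,
        deviance=dev,
    )
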