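"""One-dimensional spline bases.

Two families are used throughout the temperature-mortality models:

* quadratic B-splines for the exposure-response dimension of the
  cross-basis (degree 2, internal knots at chosen percentiles of mean
  temperature), and
* natural cubic splines for the lag-response dimension, the seasonal
  trend, and the humidity adjustment (cubic B-splines projected onto the
  subspace with zero second derivative at and beyond the boundary knots,
  the same construction as R's ``splines::ns``).

Basis matrices are plain ``numpy`` arrays with one row per evaluation
point.  Construction is fully deterministic: identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineSpec",
    "bspline_basis",
    "natural_cubic_basis",
    "spline_basis",
    "log_lag_knots",
    "natural_spec_from_df",
]

QUADRATIC_BSPLINE = "quadratic-bspline"
NATURAL_CUBIC = "natural-cubic"


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a univariate spline basis.

    Parameters
    ----------
    family
        ``"quadratic-bspline"`` or ``"natural-cubic"``.
    internal_knots
        Strictly increasing knots, all strictly inside the boundary
        interval.  May be empty.
    boundary_knots
        Pair ``(lo, hi)`` with ``lo < hi``.
    with_intercept
        Whether the basis keeps its intercept-complete form.  When
        ``False`` the first column is dropped (the usual choice when the
        regression model carries its own intercept).
    """

    family: str
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    with_intercept: bool = False

    def __post_init__(self) -> None:
        if self.family not in (QUADRATIC_BSPLINE, NATURAL_CUBIC):
            raise ValueError(f"unknown spline family {self.family!r}")
        object.__setattr__(self, "internal_knots",
                           tuple(float(k) for k in self.internal_knots))
        lo, hi = (float(b) for b in self.boundary_knots)
        object.__setattr__(self, "boundary_knots", (lo, hi))
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lo < hi")
        ik = np.asarray(self.internal_knots)
        if ik.size:
            if np.any(np.diff(ik) <= 0):
                raise ValueError("internal knots must be strictly increasing")
            if ik[0] <= lo or ik[-1] >= hi:
                raise ValueError(
                    "internal knots must lie strictly inside the boundary interval")

    @property
    def ndim(self) -> int:
        """Number of basis columns."""
        n_int = len(self.internal_knots)
        if self.family == QUADRATIC_BSPLINE:
            full = n_int + 3          # degree 2: internal + degree + 1
        else:
            full = n_int + 2          # cubic B-spline cols minus 2 constraints
        return full if self.with_intercept else full - 1


def _eval_bspline(x: np.ndarray, knots: np.ndarray, degree: int,
                  deriv: int = 0, extrapolate: bool = False) -> np.ndarray:
    """Dense design matrix of all B-spline basis functions at ``x``."""
    m = len(knots) - degree - 1
    spl = BSpline(knots, np.eye(m), degree, extrapolate=extrapolate)
    if deriv:
        spl = spl.derivative(deriv)
    return spl(x)


def bspline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Quadratic B-spline design matrix.

    Rows for values inside the boundary interval of the
    intercept-complete basis sum to exactly one (partition of unity).
    Values outside the boundary knots are evaluated by polynomial
    extension of the end segments, with a warning.
    """
    if spec.family != QUADRATIC_BSPLINE:
        raise ValueError("spec.family must be 'quadratic-bspline'")
    x = np.asarray(x, dtype=float)
    lo, hi = spec.boundary_knots
    finite = np.isfinite(x)
    if np.any((x[finite] < lo) | (x[finite] > hi)):
        warnings.warn(
            "evaluating quadratic B-spline basis outside its boundary knots; "
            "end segments are extended polynomially", stacklevel=2)
    t = np.concatenate([[lo] * 3, spec.internal_knots, [hi] * 3])
    out = np.full((x.size, len(t) - 3), np.nan)
    if finite.any():
        out[finite] = _eval_bspline(x[finite], t, 2, extrapolate=True)
    if not spec.with_intercept:
        out = out[:, 1:]
    return out


def _natural_projector(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Clamped cubic knot vector and the null-space projector enforcing
    zero second derivative at both boundary knots (R ``ns`` construction:
    without intercept, the first B-spline column is dropped *before*
    projecting)."""
    lo, hi = spec.boundary_knots
    t = np.concatenate([[lo] * 4, spec.internal_knots, [hi] * 4])
    const = _eval_bspline(np.array([lo, hi]), t, 3, deriv=2)
    if not spec.with_intercept:
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return t, q[:, 2:]


def natural_cubic_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline design matrix.

    The basis is linear at and beyond the boundary knots; out-of-range
    points are evaluated by exact linear extension of the boundary value
    and slope.
    """
    if spec.family != NATURAL_CUBIC:
        raise ValueError("spec.family must be 'natural-cubic'")
    x = np.asarray(x, dtype=float)
    lo, hi = spec.boundary_knots
    t, proj = _natural_projector(spec)

    def inner(v: np.ndarray) -> np.ndarray:
        b = _eval_bspline(v, t, 3, extrapolate=False)
        if not spec.with_intercept:
            b = b[:, 1:]
        return b @ proj

    finite = np.isfinite(x)
    out = np.full((x.size, proj.shape[1]), np.nan)
    xin = np.clip(x[finite], lo, hi)
    out[finite] = inner(xin)
    below = finite.copy()
    below[finite] = x[finite] < lo
    above = finite.copy()
    above[finite] = x[finite] > hi
    if below.any() or above.any():
        bounds = np.array([lo, hi])
        db = _eval_bspline(bounds, t, 3, deriv=1)
        if not spec.with_intercept:
            db = db[:, 1:]
        slope = db @ proj
        base = inner(bounds)
        if below.any():
            out[below] = base[0] + np.outer(x[below] - lo, slope[0])
        if above.any():
            out[above] = base[1] + np.outer(x[above] - hi, slope[1])
    return out


def spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Dispatch on ``spec.family``."""
    if spec.family == QUADRATIC_BSPLINE:
        return bspline_basis(x, spec)
    return natural_cubic_basis(x, spec)


def log_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale.

    Returns ``n_knots`` values at the exponentials of equally spaced
    points spanning ``[log 1, log max_lag]``, excluding the endpoints, so
    successive ratios of the sequence ``1, k_1, ..., k_n, max_lag`` are
    all equal.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    pts = np.linspace(0.0, np.log(max_lag), n_knots + 2)
    return np.exp(pts[1:-1])


def natural_spec_from_df(values: np.ndarray, df: int, *,
                         knot_rule: str = "quantile") -> SplineSpec:
    """Natural cubic spec (no intercept) with ``df`` columns.

    ``df`` columns require ``df - 1`` interior knots.  ``knot_rule``
    places them at equally spaced quantiles of ``values`` (``"quantile"``,
    R's ``ns(x, df=)`` convention) or equally spaced over the observed
    range (``"equal"``).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = float(v.min()), float(v.max())
    n_int = df - 1
    if n_int == 0:
        knots: tuple[float, ...] = ()
    elif knot_rule == "quantile":
        probs = np.linspace(0, 100, n_int + 2)[1:-1]
        knots = tuple(np.percentile(v, probs))
    elif knot_rule == "equal":
        knots = tuple(np.linspace(lo, hi, n_int + 2)[1:-1])
    else:
        raise ValueError(f"unknown knot_rule {knot_rule!r}")
    return SplineSpec(NATURAL_CUBIC, knots, (lo, hi), with_intercept=False)
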