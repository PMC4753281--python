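"""Daily city series: validated container, CSV input, results output.

A :class:`DailySeries` holds one city's aligned daily records — date,
mean/min/max temperature (degC), death count, optional mean relative
humidity (%).  Dates are strictly consecutive calendar days; gaps in an
input file are filled with missing-value rows so that lag arithmetic can
rely on positional offsets being day offsets.

Missing-data policy: temperature or death gaps are carried as NaN, never
imputed; downstream regression drops any day whose 0..max_lag window of
mean temperatures is incomplete (complete-lag-window rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "ValidationError", "ConfigurationError",
           "read_daily_series", "write_results_tables"]

STANDARD_COLUMNS = ("date", "tmean", "tmin", "tmax", "deaths", "humidity")


class ValidationError(ValueError):
    """A series violates a physical or structural invariant."""


class ConfigurationError(ValueError):
    """The input file or column mapping is unusable."""


@dataclass
class DailySeries:
    """One city's daily mortality-weather records.

    Invariants (checked on construction): dates strictly consecutive
    calendar days; ``tmin <= tmean <= tmax`` wherever all three are
    observed; death counts non-negative integers wherever observed.
    """

    dates: pd.DatetimeIndex
    tmean: np.ndarray
    tmin: np.ndarray | None = None
    tmax: np.ndarray | None = None
    deaths: np.ndarray | None = None
    humidity: np.ndarray | None = None
    city_label: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        n = len(self.dates)
        for name in ("tmean", "tmin", "tmax", "deaths", "humidity"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValidationError(
                    f"{name} has length {v.shape}, expected ({n},)")
            setattr(self, name, v)
        if n == 0:
            raise ValidationError("empty series")
        step = np.diff(self.dates.to_numpy().astype("datetime64[D]"))
        if n > 1 and not np.all(step == np.timedelta64(1, "D")):
            bad = self.dates[1:][step != np.timedelta64(1, "D")]
            raise ValidationError(
                f"dates must be strictly consecutive days; first break at "
                f"{bad[0].date()}")
        if self.tmin is not None and self.tmax is not None:
            both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
            bad = both & (self.tmin > self.tmax)
            if bad.any():
                d = self.dates[bad][0].date()
                raise ValidationError(f"tmin > tmax on {d}")
            mid = both & np.isfinite(self.tmean)
            off = mid & ((self.tmean < self.tmin - 1e-9) |
                         (self.tmean > self.tmax + 1e-9))
            if off.any():
                d = self.dates[off][0].date()
                raise ValidationError(f"tmean outside [tmin, tmax] on {d}")
        if self.deaths is not None:
            obs = np.isfinite(self.deaths)
            if np.any(self.deaths[obs] < 0):
                raise ValidationError("negative death count")
            if np.any(self.deaths[obs] != np.round(self.deaths[obs])):
                raise ValidationError("non-integer death count")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_years(self) -> float:
        """Study length in years, from the calendar span."""
        return len(self) / 365.25

    @property
    def day_of_week(self) -> np.ndarray:
        """0=Monday .. 6=Sunday, derived from the calendar date."""
        return self.dates.dayofweek.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"date": self.dates}
        for name in ("tmean", "tmin", "tmax", "deaths", "humidity"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, city_label: str = "") -> "DailySeries":
        kw = {c: df[c].to_numpy(dtype=float)
              for c in ("tmean", "tmin", "tmax", "deaths", "humidity")
              if c in df.columns}
        return cls(dates=pd.DatetimeIndex(df["date"]),
                   city_label=city_label, **kw)

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False, float_format="%.6g")


def read_daily_series(path, column_map: dict[str, str] | None = None,
                      city_label: str | None = None) -> DailySeries:
    """Read and validate a daily series from CSV.

    ``column_map`` maps standard field names (``date``, ``tmean``,
    ``tmin``, ``tmax``, ``deaths``, ``humidity``) to the file's column
    names; identity by default.  Rows with unparseable dates are dropped
    with a warning, and calendar gaps are filled with missing-value rows.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    raw = pd.read_csv(path)
    cmap = dict(column_map or {})
    for std in STANDARD_COLUMNS:
        cmap.setdefault(std, std)
    if cmap["date"] not in raw.columns or cmap["tmean"] not in raw.columns:
        raise ConfigurationError(
            f"required columns {cmap['date']!r}/{cmap['tmean']!r} not in "
            f"{list(raw.columns)}")
    parsed = pd.to_datetime(raw[cmap["date"]], errors="coerce",
                            format="mixed")
    bad = parsed.isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with unparseable dates",
                      stacklevel=2)
    raw = raw.loc[~bad].copy()
    parsed = parsed[~bad]
    if raw.empty:
        raise ConfigurationError("no rows with valid dates")
    raw.index = pd.DatetimeIndex(parsed).normalize()
    if raw.index.has_duplicates:
        raise ValidationError("duplicate dates in input")
    raw = raw.sort_index()
    full = pd.date_range(raw.index[0], raw.index[-1], freq="D")
    raw = raw.reindex(full)

    kw: dict[str, np.ndarray] = {}
    for std in ("tmean", "tmin", "tmax", "deaths", "humidity"):
        col = cmap[std]
        if col in raw.columns:
            kw[std] = pd.to_numeric(raw[col], errors="coerce").to_numpy()
    return DailySeries(dates=full,
                       city_label=city_label if city_label is not None
                       else path.stem, **kw)


def write_results_tables(results, out_dir) -> dict[str, Path]:
    """Write a completed analysis's report tables as CSV.

    Emits the variation-index summary (nonzero-day counts and quartiles),
    the Pearson correlation matrix among the five temperature measures,
    and the relative-risk table (heat, cold, and the four indices with
    95% CIs).  ``results`` is the bundle from
    :func:`tempmort.pipeline.run_city_analysis`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rr = getattr(results, "rr_table", None)
    if rr is None or len(rr) == 0:
        raise ValidationError("results bundle has no RR rows to write")
    paths = {
        "rr": out_dir / "relative_risks.csv",
        "index_summary": out_dir / "index_summary.csv",
        "correlations": out_dir / "temperature_correlations.csv",
    }
    rr.to_csv(paths["rr"], index=False)
    results.index_summary.to_csv(paths["index_summary"], index=True)
    results.correlations.to_csv(paths["correlations"], index=True)
    return paths
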