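"""Annual domain-averaged series, trends, epoch comparisons, ensemble summaries.

The workflow mirrors standard climate-projection analysis: a monthly 2-D
field is averaged spatially over the analysis domain (area-weighted by
default) and then annually, producing one value per calendar year; on
those annual series we fit OLS linear trends, compare multi-decadal epoch
means with a Welch t-test, and summarise a small ensemble by its per-year
mean and standard deviation (the ensemble spread).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grid import ModelGrid

logger = logging.getLogger(__name__)

DEFAULT_WINDOW1 = (2000, 2030)
DEFAULT_WINDOW2 = (2070, 2100)


@dataclass
class AnnualSeries:
    """Yearly domain-averaged scalar metric with provenance."""

    years: np.ndarray
    values: np.ndarray
    metric: str = ""
    member: str = ""
    area_weighted: bool = True
    complete: np.ndarray | None = None  # per-year: all 12 months present

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.values.shape != self.years.shape:
            raise ValueError("one value per year required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "value": self.values,
             "metric": self.metric, "member": self.member}
        )

    def window(self, window: tuple[int, int]) -> np.ndarray:
        lo, hi = window
        sel = (self.years >= lo) & (self.years <= hi)
        vals = self.values[sel]
        return vals[np.isfinite(vals)]


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class EpochComparison:
    window1: tuple[int, int]
    window2: tuple[int, int]
    mean1: float
    mean2: float
    difference: float
    t_statistic: float
    p_value: float


@dataclass
class EnsembleSummary:
    years: np.ndarray
    ensemble_mean: np.ndarray
    ensemble_spread: np.ndarray
    metric: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "ensemble_mean": self.ensemble_mean,
                             "ensemble_spread": self.ensemble_spread, "metric": self.metric})


def spatial_mean(field: xr.DataArray, grid: ModelGrid, mask: np.ndarray,
                 weighting: str = "area") -> xr.DataArray:
    """Per-time spatial mean over masked, defined cells."""
    if weighting not in ("area", "none"):
        raise ValueError("weighting must be 'area' or 'none'")
    mask_da = xr.DataArray(np.asarray(mask, dtype=bool), dims=("y", "x"))
    if not mask_da.any():
        raise ValueError("mask is empty")
    vals = field.where(mask_da)
    if weighting == "area":
        w = xr.DataArray(grid.cell_area, dims=("y", "x")).where(mask_da)
        wsum = (w * vals.notnull()).sum(dim=("y", "x"))
        out = (vals * w).sum(dim=("y", "x")) / wsum.where(wsum > 0)
    else:
        out = vals.mean(dim=("y", "x"))
    return out


def annual_spatial_mean(field: xr.DataArray, grid: ModelGrid, mask: np.ndarray,
                        weighting: str = "area", metric: str = "", member: str = "") -> AnnualSeries:
    """Spatial mean over the domain, then calendar-year mean of the monthly values."""
    monthly = spatial_mean(field, grid, mask, weighting=weighting)
    t = pd.DatetimeIndex(monthly["time"].values)
    df = pd.DataFrame({"year": t.year, "value": monthly.values})
    grouped = df.groupby("year")["value"]
    annual = grouped.mean()
    n_months = grouped.count()
    complete = (n_months == 12).to_numpy()
    if np.any(~complete):
        logger.info("years with missing monthly values: %s",
                    annual.index[~complete].tolist())
    if annual.isna().any():
        logger.warning("years with no defined cells: %s", annual.index[annual.isna()].tolist())
    return AnnualSeries(years=annual.index.to_numpy(), values=annual.to_numpy(),
                        metric=metric, member=member,
                        area_weighted=(weighting == "area"), complete=complete)


def linear_trend(series: AnnualSeries) -> TrendResult:
    """OLS fit of value on year: slope (units/yr), intercept, R², two-sided p."""
    ok = np.isfinite(series.values)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing years for a trend")
    x = series.years[ok].astype(float)
    y = series.values[ok]
    if np.allclose(y, y[0]):
        return TrendResult(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    res = stats.linregress(x, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue**2), p_value=float(res.pvalue))


def epoch_means_ttest(series: AnnualSeries,
                      window1: tuple[int, int] = DEFAULT_WINDOW1,
                      window2: tuple[int, int] = DEFAULT_WINDOW2) -> EpochComparison:
    """Window means and a Welch (unequal-variance) two-sample t-test.

    Windows are closed year intervals and must not overlap.
    """
    if window1[1] >= window2[0] and window2[1] >= window1[0]:
        raise ValueError(f"epoch windows {window1} and {window2} overlap")
    v1 = series.window(window1)
    v2 = series.window(window2)
    if len(v1) < 3 or len(v2) < 3:
        raise ValueError("each epoch window needs at least 3 years of data")
    m1, m2 = float(v1.mean()), float(v2.mean())
    if v1.var(ddof=1) == 0 and v2.var(ddof=1) == 0:
        # degenerate windows: identical means are indistinguishable, any
        # difference is infinitely significant under the t model
        t_stat, p = (0.0, 1.0) if m1 == m2 else (np.inf * np.sign(m2 - m1), 0.0)
    else:
        t_stat, p = stats.ttest_ind(v2, v1, equal_var=False)
    return EpochComparison(window1=window1, window2=window2, mean1=m1, mean2=m2,
                           difference=m2 - m1, t_statistic=float(t_stat), p_value=float(p))


def ensemble_mean_spread(member_series: list[AnnualSeries], ddof: int = 1) -> EnsembleSummary:
    """Per-year ensemble mean and spread (standard deviation across members).

    The spread uses the sample standard deviation (divisor n−1) by
    default; pass ``ddof=0`` for the population form.
    """
    if len(member_series) < 2:
        raise ValueError("need at least 2 members")
    years = member_series[0].years
    for s in member_series[1:]:
        if not np.array_equal(s.years, years):
            raise ValueError("member series have mismatched year axes")
    vals = np.vstack([s.values for s in member_series])
    return EnsembleSummary(
        years=years,
        ensemble_mean=vals.mean(axis=0),
        ensemble_spread=vals.std(axis=0, ddof=ddof),
        metric=member_series[0].metric,
    )


def epoch_map_difference(field: xr.DataArray,
                         window1: tuple[int, int] = DEFAULT_WINDOW1,
                         window2: tuple[int, int] = DEFAULT_WINDOW2) -> xr.DataArray:
    """Per-cell (window2 mean − window1 mean) map.

    Negative values mean the quantity declined (e.g. meters of habitat
    lost when applied to vertical extent).  Cells undefined throughout
    either window come out NaN.
    """
    years = xr.DataArray(pd.DatetimeIndex(field["time"].values).year,
                         dims=("time",), coords={"time": field["time"]})
    def wmean(w):
        sub = field.where((years >= w[0]) & (years <= w[1]), drop=True)
        if sub.sizes.get("time", 0) == 0:
            raise ValueError(f"no time steps in window {w}")
        return sub.mean(dim="time", skipna=True)
    out = wmean(window2) - wmean(window1)
    out.attrs["long_name"] = f"epoch difference {window2[0]}-{window2[1]} minus {window1[0]}-{window1[1]}"
    return out
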