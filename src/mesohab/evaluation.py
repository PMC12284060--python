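"""Model-vs-observation evaluation.

Free-running projections are not in phase with observations, so they are
compared statistically: the model is first co-sampled at the locations
and times of the observations (nearest horizontal cell, linear in depth,
nearest month), both are aggregated to annual means, and the comparison
reports means, biases (absolute and as % of the observed mean), OLS
trends, a configurable sub-period trend (to probe trend sensitivity to
the analysis window), and the ensemble spread of the simulated annual
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grid import ModelGrid, haversine_km
from .series import AnnualSeries, linear_trend

logger = logging.getLogger(__name__)

OBS_COLUMNS = ("lat", "lon", "depth_m", "time", "variable", "value")


def read_observations(path) -> pd.DataFrame:
    """Read a flat observation table (CSV with named columns)."""
    df = pd.read_csv(path, parse_dates=["time"])
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation file missing columns: {sorted(missing)}")
    return df


def cosample(member: xr.Dataset, grid: ModelGrid, obs: pd.DataFrame) -> pd.DataFrame:
    """Sample the model at each observation's location and time.

    Horizontal matching is nearest wet cell center (no interpolation —
    observation positioning error dominates at km-scale grids); vertical
    is linear interpolation between levels; temporal is nearest month.
    Records that fall outside the model's space-time coverage, or below
    the local sea floor, are dropped with a logged count.

    Returns the observation table with a ``model_value`` column appended.
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    times = pd.DatetimeIndex(member["time"].values)
    z_levels = member["depth"].values
    wet_idx = np.argwhere(grid.water_mask)
    wet_lat = grid.lat[grid.water_mask]
    wet_lon = grid.lon[grid.water_mask]

    out = obs.copy().reset_index(drop=True)
    t = pd.DatetimeIndex(out["time"])
    in_time = (t >= times[0] - pd.Timedelta(days=31)) & (t <= times[-1] + pd.Timedelta(days=31))

    d = haversine_km(out["lat"].to_numpy()[:, None], out["lon"].to_numpy()[:, None],
                     wet_lat[None, :], wet_lon[None, :])
    nearest = d.argmin(axis=1)
    iy, ix = wet_idx[nearest, 0], wet_idx[nearest, 1]
    it = np.abs(t.values[:, None] - times.values[None, :]).argmin(axis=1)

    model_vals = np.full(len(out), np.nan)
    for var in out["variable"].unique():
        if var not in member:
            logger.warning("variable %r not in model output; records dropped", var)
            continue
        rows = np.flatnonzero((out["variable"] == var).to_numpy() & np.asarray(in_time))
        da = member[var]
        for r in rows:
            profile = da.isel(time=int(it[r]), y=int(iy[r]), x=int(ix[r])).values.astype(float)
            zobs = float(out.at[r, "depth_m"])
            if zobs < z_levels[0] or zobs > z_levels[-1]:
                continue
            model_vals[r] = np.interp(zobs, z_levels, profile)

    out["model_value"] = model_vals
    kept = np.isfinite(model_vals)
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("cosample: dropped %d/%d records outside model coverage",
                    n_dropped, len(out))
    out = out[kept].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no observations overlap the model space-time domain")
    return out


@dataclass
class VariableEvaluation:
    """Per-variable comparison of annual observed vs simulated series."""

    variable: str
    observed_mean: float
    simulated_mean: float
    bias: float
    bias_pct: float
    observed_trend: float
    simulated_trend: float
    sub_period: tuple[int, int] | None
    observed_sub_trend: float
    simulated_sub_trend: float
    ensemble_spread: float  # time-mean spread of simulated annual values


def _annual(years: np.ndarray, values: np.ndarray, metric: str, member: str = "") -> AnnualSeries:
    df = pd.DataFrame({"year": years, "value": values}).groupby("year")["value"].mean()
    return AnnualSeries(years=df.index.to_numpy(), values=df.to_numpy(),
                        metric=metric, member=member, area_weighted=False)


def _trend_or_nan(series: AnnualSeries) -> float:
    try:
        return linear_trend(series).slope
    except ValueError:
        return float("nan")


def evaluate(cosampled: dict[str, pd.DataFrame],
             sub_period: tuple[int, int] | None = (2000, 2013)) -> pd.DataFrame:
    """Evaluation report over one or more ensemble members.

    ``cosampled`` maps member id to the output of :func:`cosample` (all
    members co-sampled against the same observation set).  Means and
    biases use the full overlap window; trends are additionally
    recomputed on ``sub_period`` years only.  Returns one row per
    variable.
    """
    if not cosampled:
        raise ValueError("no members supplied")
    members = list(cosampled)
    variables = sorted(set().union(*(set(df["variable"].unique()) for df in cosampled.values())))
    rows = []
    for var in variables:
        first = cosampled[members[0]]
        sel = first[first["variable"] == var]
        if len(sel) == 0:
            continue
        years = pd.DatetimeIndex(sel["time"]).year.to_numpy()
        if len(np.unique(years)) < 3:
            raise ValueError(f"variable {var!r}: need at least 3 years of pairs")
        obs_annual = _annual(years, sel["value"].to_numpy(), var, "obs")

        sim_annuals = []
        for m in members:
            df = cosampled[m]
            s = df[df["variable"] == var]
            yrs = pd.DatetimeIndex(s["time"]).year.to_numpy()
            sim_annuals.append(_annual(yrs, s["model_value"].to_numpy(), var, m))
        common_years = obs_annual.years
        for s in sim_annuals:
            common_years = np.intersect1d(common_years, s.years)
        def restrict(s):
            sel_y = np.isin(s.years, common_years)
            return AnnualSeries(s.years[sel_y], s.values[sel_y], s.metric, s.member,
                                area_weighted=False)
        obs_annual = restrict(obs_annual)
        sim_annuals = [restrict(s) for s in sim_annuals]
        sim_stack = np.vstack([s.values for s in sim_annuals])
        ens_mean = AnnualSeries(common_years, sim_stack.mean(axis=0), var, "ensemble-mean",
                                area_weighted=False)
        spread = float(sim_stack.std(axis=0, ddof=1).mean()) if len(members) > 1 else float("nan")

        obs_mean = float(np.nanmean(obs_annual.values))
        sim_mean = float(np.nanmean(ens_mean.values))
        bias = sim_mean - obs_mean
        bias_pct = 100.0 * bias / abs(obs_mean) if obs_mean != 0 else float("nan")

        def sub(s):
            if sub_period is None:
                return None
            sel_y = (s.years >= sub_period[0]) & (s.years <= sub_period[1])
            if sel_y.sum() < 3:
                return None
            return AnnualSeries(s.years[sel_y], s.values[sel_y], s.metric, s.member,
                                area_weighted=False)
        obs_sub = sub(obs_annual)
        sim_sub = sub(ens_mean)

        rows.append(VariableEvaluation(
            variable=var,
            observed_mean=obs_mean,
            simulated_mean=sim_mean,
            bias=bias,
            bias_pct=bias_pct,
            observed_trend=_trend_or_nan(obs_annual),
            simulated_trend=_trend_or_nan(ens_mean),
            sub_period=sub_period,
            observed_sub_trend=_trend_or_nan(obs_sub) if obs_sub else float("nan"),
            simulated_sub_trend=_trend_or_nan(sim_sub) if sim_sub else float("nan"),
            ensemble_spread=spread,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
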