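"""Synthetic ensemble generator.

Produces gridded monthly fields (temperature, dissolved oxygen,
phytoplankton nitrogen, surface shortwave) for 2000-2100 on an idealised
eastern-boundary shelf grid, with the statistical structure the habitat
analysis assumes:

- exponential light decay whose bulk attenuation is driven by upper-ocean
  chlorophyll, placing the light threshold near a configurable initial
  depth (~187 m);
- a subsurface oxygen profile whose hypoxic (63 mmol/m³) isopleth sits
  near a configurable initial depth (~290 m), with a signed century-scale
  trend concentrated at depth (negative for the two deoxygenating
  members, positive for the analogue of the member with a strengthening
  equatorial undercurrent);
- century-scale warming and productivity trends, AR(1) interannual
  noise, seasonal cycles, and optional marine-heatwave years that
  suppress chlorophyll and warm the surface layer.

The emulation is statistical only: no advection or upwelling dynamics,
and the horizontal structure is a fixed smooth cross-shore pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import brentq

from .fields import OpticsParams, make_field
from .grid import ModelGrid, EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

START_YEAR = 2000
END_YEAR = 2100

# water-mass profile constants (°C, mmol/m³, m)
T_SURFACE = 15.0
T_DEEP = 4.0
T_AT_150 = 8.81
DO_SURFACE = 250.0
DO_DEEP = 10.0
WARMING_EFOLD_M = 300.0      # vertical decay scale of the warming signal
OXYGEN_TREND_SCALE_M = 150.0  # depth shape tanh(z/scale) of the oxygen trend
SEASONAL_T_AMPLITUDE = 1.5   # °C at the surface
SEASONAL_CHL_AMPLITUDE = 0.3  # fractional
OXYGEN_PATTERN_AMPLITUDE = 12.0  # mmol/m³ cross-shore range at depth; tilts the
                                 # hypoxic isopleth deeper offshore by ~±20 m
SHORTWAVE_MEAN = 180.0       # W/m²
SHORTWAVE_SEASONAL_AMPLITUDE = 60.0


def default_depth_levels() -> np.ndarray:
    """10-m levels to 400 m, 25-m levels to 1000 m."""
    return np.concatenate([np.arange(0.0, 400.0, 10.0), np.arange(400.0, 1000.1, 25.0)])


@dataclass
class ScenarioParams:
    """Per-member scenario: trends, initial boundary depths, noise, events.

    Rates are per century; ``oxygen_trend_at_300m`` is signed (negative
    for deoxygenating members, positive for an oxygenating one) and
    ``chl_trend`` is a fraction of the initial chlorophyll per century.
    """

    member: str = "member"
    surface_warming_rate: float = 1.8          # °C/century at 150 m
    oxygen_trend_at_300m: float = -25.0        # mmol/m³/century
    chl_trend: float = -0.29                   # fraction/century
    initial_hypoxic_depth: float = 290.0       # m
    initial_upper_light_depth: float = 187.0   # m
    hypoxic_threshold: float = 63.0            # mmol/m³
    light_threshold: float = 0.0217            # W/m²
    interannual_sd: dict = field(default_factory=lambda: {
        "temperature": 0.15, "oxygen": 2.0, "chl_frac": 0.06})
    ar1_rho: float = 0.5
    heatwave_years: tuple = ()
    chl_suppression_fraction: float = 0.3
    heatwave_temp_bump: float = 1.0            # °C at the surface
    seed: int = 0

    def __post_init__(self):
        for name in ("surface_warming_rate", "oxygen_trend_at_300m", "chl_trend"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0 < self.initial_hypoxic_depth < 1000):
            raise ValueError("initial_hypoxic_depth outside the vertical domain")
        if not (0 < self.initial_upper_light_depth < 1000):
            raise ValueError("initial_upper_light_depth outside the vertical domain")


def generate_grid(nx: int = 40, ny: int = 60, shelf_width_cells: int = 8,
                  max_depth_m: float = 3000.0,
                  lat_range: tuple[float, float] = (34.0, 40.5),
                  lon_range: tuple[float, float] = (-126.5, -121.0)) -> ModelGrid:
    """Idealised shelf grid: meridional coastline on the east edge.

    Bottom depth deepens monotonically offshore following a tanh
    shelf-slope profile and reaches ``max_depth_m`` in the offshore half;
    cell areas come from spherical geometry (so they shrink poleward with
    cos(latitude)).
    """
    if nx < 4 or ny < 4:
        raise ValueError("nx and ny must be at least 4")
    lat_1d = np.linspace(lat_range[0], lat_range[1], ny)
    lon_1d = np.linspace(lon_range[0], lon_range[1], nx)
    lon, lat = np.meshgrid(lon_1d, lat_1d)
    dlat = np.deg2rad(lat_1d[1] - lat_1d[0])
    dlon = np.deg2rad(lon_1d[1] - lon_1d[0])
    cell_area = (EARTH_RADIUS_KM ** 2) * dlat * dlon * np.cos(np.deg2rad(lat))

    cells_from_coast = (nx - 1) - np.arange(nx)  # coast = easternmost column
    depth_1d = max_depth_m * np.tanh(cells_from_coast / float(shelf_width_cells))
    bottom_depth = np.broadcast_to(depth_1d, (ny, nx)).copy()
    land_mask = np.zeros((ny, nx), dtype=bool)
    land_mask[:, -1] = True
    bottom_depth[land_mask] = 0.0
    return ModelGrid(lat=lat, lon=lon, bottom_depth=bottom_depth,
                     land_mask=land_mask, cell_area=cell_area)


# ---------------------------------------------------------------------------
# analytic base profiles (also used by tests as closed-form oracles)

def oxygen_profile_scale(params: ScenarioParams) -> float:
    """e-folding depth h of DO(z) = DO_deep + (DO_surf − DO_deep)·exp(−z/h),
    chosen so the base profile crosses the hypoxic threshold exactly at
    ``initial_hypoxic_depth``."""
    amp = DO_SURFACE - DO_DEEP
    return params.initial_hypoxic_depth / np.log(amp / (params.hypoxic_threshold - DO_DEEP))


def base_oxygen(z, params: ScenarioParams):
    h = oxygen_profile_scale(params)
    return DO_DEEP + (DO_SURFACE - DO_DEEP) * np.exp(-np.asarray(z, dtype=float) / h)


def oxygen_isopleth_gradient(params: ScenarioParams) -> float:
    """|dDO/dz| (mmol/m³ per m) of the base profile at the hypoxic isopleth."""
    return (params.hypoxic_threshold - DO_DEEP) / oxygen_profile_scale(params)


def oxygen_trend_shape(z) -> np.ndarray:
    """Depth shape of the oxygen trend, normalised to 1 at 300 m."""
    z = np.asarray(z, dtype=float)
    return np.tanh(z / OXYGEN_TREND_SCALE_M) / np.tanh(300.0 / OXYGEN_TREND_SCALE_M)


def hypoxic_isopleth_depth(t_years: float, params: ScenarioParams) -> float:
    """Depth where the noise-free DO field crosses the hypoxic threshold
    ``t_years`` after the start, solved from the analytic profile."""
    trend = params.oxygen_trend_at_300m * t_years / 100.0

    def f(z):
        return base_oxygen(z, params) + trend * float(oxygen_trend_shape(z)) - params.hypoxic_threshold

    lo, hi = 1.0, 999.0
    if f(lo) * f(hi) > 0:
        raise ValueError("hypoxic isopleth left the vertical domain")
    return brentq(f, lo, hi, xtol=1e-6)


def oxygen_trend_for_epoch_shoaling(shoaling_m: float, params: ScenarioParams | None = None,
                                    window1=(2000, 2030), window2=(2070, 2100)) -> float:
    """Oxygen trend (mmol/m³/century at 300 m) that shoals the hypoxic
    isopleth by ``shoaling_m`` meters between the two epoch-window centers.

    Inverts the analytic isopleth-depth relation, accounting for the
    steepening of the base profile as the isopleth shoals (so the result
    is not simply shoaling-rate × local gradient).
    """
    params = params or ScenarioParams()
    t1 = 0.5 * (window1[0] + window1[1]) - START_YEAR
    t2 = 0.5 * (window2[0] + window2[1]) - START_YEAR

    def shoaling(trend):
        p = ScenarioParams(**{**asdict(params), "oxygen_trend_at_300m": float(trend)})
        return hypoxic_isopleth_depth(t1, p) - hypoxic_isopleth_depth(t2, p)

    # bracket keeps the isopleth inside the vertical domain at both epochs
    return brentq(lambda tr: shoaling(tr) - shoaling_m, -120.0, 40.0, xtol=1e-8)


def base_chlorophyll(params: ScenarioParams, optics: OpticsParams | None = None,
                     surface_shortwave: float = SHORTWAVE_MEAN) -> float:
    """Upper-ocean chlorophyll (mg/m³) whose bulk attenuation places the
    light threshold at ``initial_upper_light_depth`` under mean surface
    shortwave.  Inverts k = ln(I0_PAR/threshold)/z through the k-Chl
    relation."""
    optics = optics or OpticsParams()
    i0 = optics.par_fraction_of_shortwave * surface_shortwave
    if i0 <= params.light_threshold:
        raise ValueError("surface PAR below the light threshold")
    k0 = np.log(i0 / params.light_threshold) / params.initial_upper_light_depth
    if k0 <= optics.k_chl_a:
        raise ValueError(
            "target upper-boundary depth needs attenuation below the pure-water term")
    return float(((k0 - optics.k_chl_a) / optics.k_chl_b) ** (1.0 / optics.k_chl_c))


def _ar1_annual(rng: np.random.Generator, n_years: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) annual anomaly series with marginal SD ``sd``."""
    eps = np.empty(n_years)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    for i in range(1, n_years):
        eps[i] = rho * eps[i - 1] + rng.normal(0.0, innov_sd)
    return eps


def monthly_time_axis(start_year: int = START_YEAR, end_year: int = END_YEAR) -> pd.DatetimeIndex:
    n = (end_year - start_year + 1) * 12
    return pd.date_range(f"{start_year}-01-01", periods=n, freq="MS") + pd.Timedelta(days=14)


def generate_member(grid: ModelGrid, params: ScenarioParams,
                    depth_levels: np.ndarray | None = None,
                    optics: OpticsParams | None = None,
                    start_year: int = START_YEAR, end_year: int = END_YEAR) -> xr.Dataset:
    """Monthly member fields on (time, depth, y, x), float32, NaN below bottom.

    Deterministic for a fixed seed.  Variables: ``temperature`` (°C),
    ``oxygen`` (mmol/m³), ``phyto`` (mmol N/m³), ``swrad`` (W/m², 2-D+time).
    """
    optics = optics or OpticsParams()
    z = default_depth_levels() if depth_levels is None else np.asarray(depth_levels, dtype=float)
    times = monthly_time_axis(start_year, end_year)
    nt, nz = len(times), len(z)
    ny, nx = grid.shape
    rng = np.random.default_rng(params.seed)

    month = times.month.to_numpy()
    year = times.year.to_numpy()
    t_years = (year - start_year) + (month - 0.5) / 12.0
    n_years = end_year - start_year + 1
    year_idx = year - start_year

    # annual AR(1) anomalies, shared across the domain (interannual noise)
    eps_t = _ar1_annual(rng, n_years, params.interannual_sd.get("temperature", 0.0),
                        params.ar1_rho)[year_idx]
    eps_o = _ar1_annual(rng, n_years, params.interannual_sd.get("oxygen", 0.0),
                        params.ar1_rho)[year_idx]
    eps_c = _ar1_annual(rng, n_years, params.interannual_sd.get("chl_frac", 0.0),
                        params.ar1_rho)[year_idx]

    heatwave = np.isin(year, np.asarray(params.heatwave_years, dtype=int))

    # fixed smooth cross-shore pattern in [0, 1] (0 at coast): mild horizontal structure
    offshore_frac = np.broadcast_to(
        ((nx - 1) - np.arange(nx)) / max(nx - 1, 1), (ny, nx)).astype(float)
    pat = offshore_frac - offshore_frac.mean()

    zc = z[None, :, None, None]
    tc = t_years[:, None, None, None]

    # --- temperature ---------------------------------------------------
    h_t = 150.0 / np.log((T_SURFACE - T_DEEP) / (T_AT_150 - T_DEEP))
    t_base = T_DEEP + (T_SURFACE - T_DEEP) * np.exp(-z / h_t)
    warm_shape = np.exp(-(z - 150.0) / WARMING_EFOLD_M)
    seasonal_t = SEASONAL_T_AMPLITUDE * np.cos(2 * np.pi * (month - 8.0) / 12.0)
    temp = (t_base[None, :, None, None]
            + params.surface_warming_rate * (tc / 100.0) * warm_shape[None, :, None, None]
            + seasonal_t[:, None, None, None] * np.exp(-zc / 50.0)
            + eps_t[:, None, None, None] * np.exp(-zc / 100.0)
            + (heatwave * params.heatwave_temp_bump)[:, None, None, None] * np.exp(-zc / 50.0)
            + 0.4 * pat[None, None, :, :] * np.exp(-zc / 200.0))

    # --- dissolved oxygen ----------------------------------------------
    o_base = base_oxygen(z, params)
    g = oxygen_trend_shape(z)
    oxy = (o_base[None, :, None, None]
           + params.oxygen_trend_at_300m * (tc / 100.0) * g[None, :, None, None]
           + eps_o[:, None, None, None] * g[None, :, None, None]
           + OXYGEN_PATTERN_AMPLITUDE * pat[None, None, :, :] * g[None, :, None, None])
    n_clipped = int((oxy < 0).sum())
    if n_clipped:
        logger.info("member %s: clipped %d negative oxygen values to 0", params.member, n_clipped)
    oxy = np.clip(oxy, 0.0, None)

    # --- phytoplankton nitrogen ----------------------------------------
    chl0 = base_chlorophyll(params, optics)
    p0 = chl0 / optics.chl_per_mmol_n
    p_shape = np.where(z <= 100.0, 1.0, np.exp(-(z - 100.0) / 50.0))
    seasonal_c = 1.0 + SEASONAL_CHL_AMPLITUDE * np.cos(2 * np.pi * (month - 4.0) / 12.0)
    hw_factor = np.where(heatwave, 1.0 - params.chl_suppression_fraction, 1.0)
    p_time = (1.0 + params.chl_trend * t_years / 100.0) * seasonal_c * (1.0 + eps_c) * hw_factor
    phyto = p0 * np.clip(p_time, 0.0, None)[:, None, None, None] * p_shape[None, :, None, None] \
        * (1.0 + 0.1 * pat[None, None, :, :])
    phyto = np.clip(phyto, 0.0, None)

    # --- surface shortwave ----------------------------------------------
    sw = SHORTWAVE_MEAN + SHORTWAVE_SEASONAL_AMPLITUDE * np.cos(2 * np.pi * (month - 6.5) / 12.0)
    swrad = np.broadcast_to(sw[:, None, None], (nt, ny, nx)).copy()

    # mask below the sea floor and on land
    below = zc > grid.bottom_depth[None, None, :, :]
    land = grid.land_mask[None, None, :, :]
    for arr in (temp, oxy, phyto):
        arr[np.broadcast_to(below | land, arr.shape)] = np.nan
    swrad[np.broadcast_to(land[:, 0], swrad.shape)] = np.nan

    ds = xr.Dataset(
        {
            "temperature": make_field(temp.astype(np.float32), z, times, "temperature", "degC"),
            "oxygen": make_field(oxy.astype(np.float32), z, times, "oxygen", "mmol m-3"),
            "phyto": make_field(phyto.astype(np.float32), z, times, "phyto", "mmolN m-3"),
            "swrad": xr.DataArray(swrad.astype(np.float32), dims=("time", "y", "x"),
                                  coords={"time": times}, name="swrad",
                                  attrs={"units": "W m-2"}),
        }
    )
    ds.attrs["member"] = params.member
    ds.attrs["scenario_params"] = repr(asdict(params))
    return ds


def default_ensemble_params(seed: int = 0) -> list[ScenarioParams]:
    """The three-member ensemble the generator emulates.

    Two members deoxygenate at depth at different rates and one gains
    subsurface oxygen; the per-member oxygen trends come from the
    analytic isopleth solver so the member-level epoch shoalings are
    +93, +81 and -59 m (an ensemble-mean shoaling of ~40 m).
    """
    # (member, warming °C/century at 150 m, epoch shoaling of the hypoxic
    #  isopleth in m; negative = deepening, the oxygenating member)
    specs = [
        ("gfdl-like", 1.3, +93.0),
        ("ipsl-like", 1.8, +81.0),
        ("hadl-like", 2.6, -59.0),
    ]
    out = []
    for i, (name, warm, shoal_m) in enumerate(specs):
        trend = oxygen_trend_for_epoch_shoaling(shoal_m)
        out.append(ScenarioParams(member=name, surface_warming_rate=warm,
                                  oxygen_trend_at_300m=trend, seed=seed + i + 1))
    return out


def generate_ensemble(grid: ModelGrid, seed: int = 0,
                      depth_levels: np.ndarray | None = None,
                      optics: OpticsParams | None = None,
                      params_list: list[ScenarioParams] | None = None) -> dict[str, xr.Dataset]:
    """Generate all members on a shared grid; keyed by member id."""
    params_list = params_list or default_ensemble_params(seed)
    return {p.member: generate_member(grid, p, depth_levels=depth_levels, optics=optics)
            for p in params_list}


def generate_observations(member: xr.Dataset, grid: ModelGrid, n_per_year: int,
                          noise_sd: dict[str, float] | None = None, seed: int = 0,
                          variables: tuple[str, ...] = ("temperature", "oxygen")) -> pd.DataFrame:
    """Pseudo-observations: random space/depth/time samples plus Gaussian noise.

    Returns a flat table with columns (lat, lon, depth_m, time, variable,
    value, units); reproducible under ``seed``.
    """
    if n_per_year < 1:
        raise ValueError("n_per_year must be >= 1")
    noise_sd = noise_sd or {}
    rng = np.random.default_rng(seed)
    times = pd.DatetimeIndex(member["time"].values)
    years = sorted(set(times.year))
    wet_idx = np.argwhere(grid.water_mask)
    z_levels = member["depth"].values
    records = []
    for var in variables:
        da = member[var]
        units = da.attrs.get("units", "")
        sd = float(noise_sd.get(var, 0.0))
        for yr in years:
            tsel = np.flatnonzero(times.year == yr)
            for _ in range(n_per_year):
                iy, ix = wet_idx[rng.integers(len(wet_idx))]
                it = tsel[rng.integers(len(tsel))]
                wet_levels = z_levels[z_levels <= grid.bottom_depth[iy, ix]]
                depth = float(rng.uniform(0.0, wet_levels[-1]))
                profile = da.isel(time=it, y=iy, x=ix).values.astype(float)
                val = float(np.interp(depth, z_levels, profile))
                if not np.isfinite(val):
                    continue
                records.append({
                    "lat": grid.lat[iy, ix], "lon": grid.lon[iy, ix],
                    "depth_m": depth, "time": times[it], "variable": var,
                    "value": val + rng.normal(0.0, sd) if sd > 0 else val,
                    "units": units,
                })
    return pd.DataFrame.from_records(records)
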