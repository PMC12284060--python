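"""Per-column derived quantities from gridded ocean fields.

Fields are xarray DataArrays on dims ``(time, depth, y, x)`` (or a subset
ending in the same order), with a ``depth`` coordinate in meters positive
down and strictly increasing.  Values below the sea floor are NaN.

Covered here: photon-flux/irradiance conversion, chlorophyll from
phytoplankton nitrogen biomass, upper-ocean integrals/averages, the bulk
k-Chl attenuation relation, exponential light profiles, euphotic depth,
maximum buoyancy frequency, and extraction at a fixed depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

logger = logging.getLogger(__name__)

FIELD_DIMS = ("time", "depth", "y", "x")


@dataclass
class OpticsParams:
    """Constants of the optics / biomass-conversion model.

    photons_per_joule
        PAR quantum-to-energy factor, µmol photons per J (4.6).
    chl_to_c
        Chlorophyll-to-carbon mass ratio, g Chl per g C (0.03, bulk
        phytoplankton community value for the southern California Current).
    redfield_c_n
        Molar Redfield carbon:nitrogen ratio (106/16).
    carbon_molar_mass
        g C per mol C.
    par_fraction_of_shortwave
        Fraction of downwelling shortwave that is PAR (0.43).
    k_chl_a, k_chl_b, k_chl_c
        Coefficients of the bulk attenuation relation
        k = a + b * Chl**c  [1/m], with Chl the 0-100 m chlorophyll
        concentration in mg/m³.  The shipped coefficients are an
        implementer default for a Morel-type empirical fit; override them
        in configuration when a regionally calibrated fit is available.
    """

    photons_per_joule: float = 4.6
    chl_to_c: float = 0.03
    redfield_c_n: float = 106.0 / 16.0
    carbon_molar_mass: float = 12.011
    par_fraction_of_shortwave: float = 0.43
    k_chl_a: float = 0.0384
    k_chl_b: float = 0.0518
    k_chl_c: float = 0.428

    def __post_init__(self):
        for name in ("photons_per_joule", "chl_to_c", "redfield_c_n",
                     "carbon_molar_mass", "par_fraction_of_shortwave",
                     "k_chl_a", "k_chl_b", "k_chl_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.k_chl_c <= 1.5):
            raise ValueError("k_chl_c must lie in (0, 1.5]")

    @property
    def chl_per_mmol_n(self) -> float:
        """mg Chl per mmol N: Redfield C:N × molar mass of C × Chl:C."""
        return self.redfield_c_n * self.carbon_molar_mass * self.chl_to_c


@dataclass
class HydroParams:
    """Constants for stratification diagnostics."""

    gravity: float = 9.81            # m/s²
    reference_density: float = 1025.0  # kg/m³
    n2_search_depth_m: float = 100.0   # main thermocline depth
    # linear equation-of-state fallback (used when only T, S are available)
    thermal_expansion: float = 2.0e-4   # 1/°C
    haline_contraction: float = 7.6e-4  # 1/psu
    reference_temperature: float = 10.0  # °C
    reference_salinity: float = 34.0     # psu

    def __post_init__(self):
        if self.gravity <= 0 or self.reference_density <= 0 or self.n2_search_depth_m <= 0:
            raise ValueError("HydroParams must be strictly positive")


def make_field(values, depth_levels, time_stamps, name: str, units: str) -> xr.DataArray:
    """Assemble a (time, depth, y, x) DataArray with validated depth axis."""
    depth_levels = np.asarray(depth_levels, dtype=float)
    if depth_levels.ndim != 1 or np.any(np.diff(depth_levels) <= 0):
        raise ValueError("depth_levels must be 1-D and strictly increasing")
    if not units:
        raise ValueError("units must be non-empty")
    da = xr.DataArray(
        np.asarray(values),
        dims=FIELD_DIMS,
        coords={"time": np.asarray(time_stamps), "depth": depth_levels},
        name=name,
        attrs={"units": units, "positive": "down"},
    )
    return da


def photon_flux_to_irradiance(q, params: OpticsParams | None = None):
    """Convert a PAR photon flux (µmol photons/m²/s) to irradiance (W/m²)."""
    params = params or OpticsParams()
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("photon flux must be non-negative")
    out = q / params.photons_per_joule
    return float(out) if out.ndim == 0 else out


def irradiance_to_photon_flux(e, params: OpticsParams | None = None):
    """Inverse of :func:`photon_flux_to_irradiance` (exact round-trip)."""
    params = params or OpticsParams()
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("irradiance must be non-negative")
    out = e * params.photons_per_joule
    return float(out) if out.ndim == 0 else out


def phyto_to_chl(p, params: OpticsParams | None = None):
    """Chlorophyll (mg/m³) from phytoplankton nitrogen biomass (mmol N/m³).

    Linear conversion through the Redfield C:N ratio and a fixed Chl:C.
    """
    params = params or OpticsParams()
    arr = p.values if isinstance(p, xr.DataArray) else np.asarray(p, dtype=float)
    if np.any(np.asarray(arr)[np.isfinite(arr)] < 0):
        raise ValueError("phytoplankton biomass must be non-negative")
    out = p * params.chl_per_mmol_n
    if isinstance(out, xr.DataArray):
        out = out.rename("chlorophyll")
        out.attrs["units"] = "mg m-3"
        return out
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def integrate_upper(field: xr.DataArray, z_max: float, mode: str = "integral") -> xr.DataArray:
    """Trapezoidal depth integral (units × m) or average over [0, z_max].

    Columns shallower than ``z_max`` (NaN below the bottom) are integrated
    to their deepest valid level; the average divides by the actually
    integrated thickness.
    """
    if mode not in ("integral", "average"):
        raise ValueError("mode must be 'integral' or 'average'")
    depth = field["depth"].values
    if z_max > depth[-1]:
        raise ValueError(f"z_max={z_max} m exceeds deepest level {depth[-1]} m")
    if (depth <= z_max).sum() < 2:
        raise ValueError("need at least 2 levels above z_max")
    sub = field.sel(depth=slice(None, z_max))
    if sub["depth"].values[-1] < z_max:
        # close the slab with an interpolated value exactly at z_max
        edge = field.interp(depth=[z_max])
        sub = xr.concat([sub, edge], dim="depth")

    z = sub["depth"].values
    v = sub.values
    ax = sub.get_axis_num("depth")
    v = np.moveaxis(v, ax, -1)
    dz = np.diff(z)
    pair_ok = np.isfinite(v[..., :-1]) & np.isfinite(v[..., 1:])
    seg = 0.5 * (v[..., :-1] + v[..., 1:]) * dz
    integral = np.where(pair_ok, seg, 0.0).sum(axis=-1)
    thickness = np.where(pair_ok, dz, 0.0).sum(axis=-1)
    none_valid = thickness == 0
    if np.any(none_valid & np.isfinite(v).any(axis=-1)):
        logger.info("columns with <2 wet levels above %.0f m set to NaN", z_max)
    if mode == "average":
        with np.errstate(invalid="ignore", divide="ignore"):
            integral = integral / thickness
    integral = np.where(none_valid, np.nan, integral)
    dims = [d for d in sub.dims if d != "depth"]
    out = xr.DataArray(
        np.moveaxis(integral, -1, -1),
        dims=dims,
        coords={d: sub[d] for d in dims if d in sub.coords},
        name=f"{field.name}_{mode}_0_{int(z_max)}m" if field.name else None,
    )
    units = field.attrs.get("units", "")
    if units:
        out.attrs["units"] = f"{units} m" if mode == "integral" else units
    return out


def attenuation_coefficient(chl, params: OpticsParams | None = None):
    """Bulk light attenuation k = a + b·Chl^c (1/m) from 0-100 m chlorophyll."""
    params = params or OpticsParams()
    arr = chl.values if isinstance(chl, xr.DataArray) else np.asarray(chl, dtype=float)
    if np.any(np.asarray(arr)[np.isfinite(arr)] < 0):
        raise ValueError("chlorophyll must be non-negative")
    k = params.k_chl_a + params.k_chl_b * chl ** params.k_chl_c
    if isinstance(k, xr.DataArray):
        k = k.rename("attenuation_coefficient")
        k.attrs["units"] = "m-1"
        return k
    k = np.asarray(k, dtype=float)
    return float(k) if k.ndim == 0 else k


def light_profile(surface_shortwave, k, depth_levels, params: OpticsParams | None = None) -> xr.DataArray:
    """Underwater PAR irradiance I(z) = f_PAR · SW · exp(−k z), W/m².

    ``surface_shortwave`` and ``k`` may be scalars or (time, y, x)
    DataArrays; the result gains a ``depth`` dimension on ``depth_levels``.
    """
    params = params or OpticsParams()
    depth_levels = np.asarray(depth_levels, dtype=float)
    if np.any(np.asarray(k if np.isscalar(k) else getattr(k, "values", k)) <= 0):
        raise ValueError("attenuation coefficient must be strictly positive")
    z = xr.DataArray(depth_levels, dims=("depth",), coords={"depth": depth_levels})
    i0 = params.par_fraction_of_shortwave * surface_shortwave
    light = i0 * np.exp(-k * z)
    if isinstance(light, xr.DataArray):
        if "depth" in light.dims:
            order = [d for d in FIELD_DIMS if d in light.dims]
            light = light.transpose(*order)
        light = light.rename("light")
        light.attrs["units"] = "W m-2"
    return light


def euphotic_depth(k):
    """Depth (m) where light reaches 1% of its surface value: ln(100)/k.

    Independent of surface irradiance by construction.
    """
    arr = k.values if isinstance(k, xr.DataArray) else np.asarray(k, dtype=float)
    if np.any(np.asarray(arr)[np.isfinite(arr)] <= 0):
        raise ValueError("euphotic depth undefined for k <= 0")
    out = np.log(100.0) / k
    if isinstance(out, xr.DataArray):
        out = out.rename("euphotic_depth")
        out.attrs["units"] = "m"
        return out
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def linear_density(temperature, salinity=None, params: HydroParams | None = None):
    """Potential density (kg/m³) from a linear equation of state.

    ρ = ρ0 (1 − α(T−T0) + β(S−S0)); salinity defaults to the reference
    value (pure thermal stratification).
    """
    params = params or HydroParams()
    s_term = 0.0
    if salinity is not None:
        s_term = params.haline_contraction * (salinity - params.reference_salinity)
    return params.reference_density * (
        1.0 - params.thermal_expansion * (temperature - params.reference_temperature) + s_term
    )


def buoyancy_frequency_max(density, depth_levels=None, params: HydroParams | None = None):
    """Maximum N² (1/s²) within the upper search depth, and its depth.

    N² = (g/ρ0) dρ/dz on level midpoints, z positive down, so a stable
    (density increasing downward) column gives positive N².  Returns
    ``(n2_max, depth_of_max)``; for gridded input these are DataArrays.
    An entirely unstable column still returns its (negative) maximum, with
    a warning logged.
    """
    params = params or HydroParams()
    if isinstance(density, xr.DataArray):
        z = density["depth"].values
        v = density.values
        ax = density.get_axis_num("depth")
        v = np.moveaxis(v, ax, -1)
        other_dims = [d for d in density.dims if d != "depth"]
    else:
        if depth_levels is None:
            raise ValueError("depth_levels required for plain-array input")
        z = np.asarray(depth_levels, dtype=float)
        v = np.asarray(density, dtype=float)
        other_dims = None
    if v.shape[-1] < 3:
        raise ValueError("need at least 3 depth levels")
    z_mid = 0.5 * (z[:-1] + z[1:])
    within = z_mid <= params.n2_search_depth_m
    if within.sum() < 2:
        raise ValueError("need at least 3 levels within the N² search depth")
    n2 = (params.gravity / params.reference_density) * np.diff(v, axis=-1) / np.diff(z)
    n2 = n2[..., within]
    zm = z_mid[within]
    n2 = np.where(np.isfinite(n2), n2, -np.inf)
    idx = np.argmax(n2, axis=-1)
    n2_max = np.take_along_axis(n2, idx[..., None], axis=-1)[..., 0]
    depth_of_max = zm[idx]
    all_nan = ~np.isfinite(n2_max)
    n2_max = np.where(all_nan, np.nan, n2_max)
    depth_of_max = np.where(all_nan, np.nan, depth_of_max)
    if np.any(n2_max[np.isfinite(n2_max)] < 0):
        logger.warning("unstable column(s): maximum N² is negative")
    if other_dims is not None:
        coords = {d: density[d] for d in other_dims if d in density.coords}
        n2_da = xr.DataArray(n2_max, dims=other_dims, coords=coords, name="n2_max",
                             attrs={"units": "s-2"})
        z_da = xr.DataArray(depth_of_max, dims=other_dims, coords=coords,
                            name="n2_max_depth", attrs={"units": "m"})
        return n2_da, z_da
    if np.ndim(n2_max) == 0:
        return float(n2_max), float(depth_of_max)
    return n2_max, depth_of_max


def extract_at_depth(field: xr.DataArray, z: float) -> xr.DataArray:
    """Linearly interpolate a field to a fixed depth z (m, positive down).

    Columns whose bottom is shallower than z come out NaN (the NaN below
    the bottom propagates through the interpolation).
    """
    depth = field["depth"].values
    if z < depth[0] or z > depth[-1]:
        raise ValueError(f"z={z} m outside the level range [{depth[0]}, {depth[-1]}] m")
    out = field.interp(depth=z).drop_vars("depth")
    if field.name:
        out = out.rename(f"{field.name}_at_{int(z)}m")
    out.attrs = dict(field.attrs)
    return out
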