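"""Mesopelagic habitat boundaries and extent.

The habitat definition: the upper boundary is the depth where underwater
PAR irradiance falls to a visual-predation light threshold (default
0.0217 W/m², i.e. 0.1 µmol photons/m²/s); the lower boundary is the depth
where dissolved oxygen first drops below a hypoxic threshold (default
63 mmol/m³ ≈ 63 µmol/l), falling back to the sea-floor depth where the
column never goes hypoxic.  The vertical extent is the distance between
the two, and the horizontal habitat area at a reference depth (default
300 m) is the area where oxygen at that depth is still above threshold.

All crossings are located by linear interpolation between the bracketing
model levels; a profile exactly equal to the threshold at a level returns
that level's depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .fields import extract_at_depth
from .grid import ModelGrid

logger = logging.getLogger(__name__)


@dataclass
class HabitatThresholds:
    light_threshold: float = 0.0217       # W/m²
    oxygen_threshold: float = 63.0        # mmol/m³
    reference_depth_for_area: float = 300.0  # m

    def __post_init__(self):
        if min(self.light_threshold, self.oxygen_threshold, self.reference_depth_for_area) <= 0:
            raise ValueError("habitat thresholds must be strictly positive")


def threshold_crossing_depth(profile_values, depth_levels, threshold: float,
                             direction: str = "decreasing"):
    """Depth of the shallowest downward threshold crossing.

    ``profile_values`` is an array with depth on the last axis (or an
    xarray DataArray with a ``depth`` dim); NaNs mark levels below the sea
    floor and must sit at the bottom of the column.  ``direction``
    "decreasing" finds where the profile drops to/below the threshold,
    "increasing" where it rises to/above it.

    Returns ``(depth, flags)`` where depth is NaN when no crossing exists
    above the bottom, and ``flags`` has boolean fields:

    - ``at_top``: already past the threshold at the shallowest wet level
      (the returned depth is that level's depth);
    - ``reached``: a genuine crossing (or top condition) was found;
    - ``too_shallow``: fewer than 2 wet levels.
    """
    if direction not in ("decreasing", "increasing"):
        raise ValueError("direction must be 'decreasing' or 'increasing'")
    was_dataarray = isinstance(profile_values, xr.DataArray)
    if was_dataarray:
        da = profile_values
        z = da["depth"].values
        v = np.moveaxis(da.values, da.get_axis_num("depth"), -1)
        other_dims = [d for d in da.dims if d != "depth"]
    else:
        z = np.asarray(depth_levels, dtype=float)
        v = np.asarray(profile_values, dtype=float)
        other_dims = None
    if z.ndim != 1 or np.any(np.diff(z) <= 0):
        raise ValueError("depth_levels must be 1-D and strictly increasing")

    finite = np.isfinite(v)
    nwet = finite.sum(axis=-1)
    if direction == "decreasing":
        past = finite & (v <= threshold)
    else:
        past = finite & (v >= threshold)
    any_past = past.any(axis=-1)
    j = np.argmax(past, axis=-1)

    too_shallow = nwet < 2
    if np.any(too_shallow & finite.any(axis=-1)):
        logger.warning("columns with <2 wet levels: crossing undefined")
    at_top = any_past & (j == 0) & ~too_shallow
    interior = any_past & (j > 0) & ~too_shallow

    jj = np.clip(j, 1, v.shape[-1] - 1)
    v1 = np.take_along_axis(v, jj[..., None], axis=-1)[..., 0]
    v0 = np.take_along_axis(v, (jj - 1)[..., None], axis=-1)[..., 0]
    z1 = z[jj]
    z0 = z[jj - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (v0 - threshold) / (v0 - v1)
    depth = z0 + (z1 - z0) * frac

    first_wet = np.argmax(finite, axis=-1)
    out = np.full(v.shape[:-1], np.nan)
    out[interior] = depth[interior]
    out[at_top] = z[first_wet][at_top]
    reached = interior | at_top

    flags = {"at_top": at_top, "reached": reached, "too_shallow": too_shallow}
    if was_dataarray and other_dims:
        coords = {d: da[d] for d in other_dims if d in da.coords}
        out = xr.DataArray(out, dims=other_dims, coords=coords)
        flags = {k: xr.DataArray(m, dims=other_dims, coords=coords) for k, m in flags.items()}
    return out, flags


def upper_boundary(light: xr.DataArray, thresholds: HabitatThresholds | None = None) -> xr.Dataset:
    """Depth of the light threshold (upper mesopelagic boundary).

    Requires light strictly decreasing with depth in every wet column (the
    exponential optics model guarantees it); undefined — and flagged —
    where even the shallowest level is darker than the threshold, or where
    the threshold is never reached above the bottom.
    """
    thresholds = thresholds or HabitatThresholds()
    v = np.moveaxis(light.values, light.get_axis_num("depth"), -1)
    pair = np.isfinite(v[..., :-1]) & np.isfinite(v[..., 1:])
    increasing = pair & (np.diff(v, axis=-1) >= 0)
    if increasing.any():
        idx = np.unravel_index(np.argmax(increasing), increasing.shape)
        raise ValueError(
            f"light profile not strictly decreasing with depth at index {idx[:-1]}"
        )
    depth, flags = threshold_crossing_depth(light, None, thresholds.light_threshold,
                                            direction="decreasing")
    depth = depth.where(~flags["at_top"])
    ds = xr.Dataset(
        {
            "upper_depth": depth,
            "upper_undefined": ~flags["reached"] | flags["at_top"],
            "surface_below_threshold": flags["at_top"],
        }
    )
    ds["upper_depth"].attrs.update(units="m", long_name="depth of light threshold")
    return ds


def lower_boundary(oxygen: xr.DataArray, grid: ModelGrid,
                   thresholds: HabitatThresholds | None = None) -> xr.Dataset:
    """Depth of the hypoxic threshold (lower mesopelagic boundary).

    First downward crossing of the oxygen threshold; columns that never go
    hypoxic return the sea-floor depth with ``lower_is_bottom_fallback``
    set; columns hypoxic at their shallowest wet level return that level's
    depth with ``hypoxic_at_top`` set.
    """
    thresholds = thresholds or HabitatThresholds()
    if np.any(oxygen.values[np.isfinite(oxygen.values)] < 0):
        raise ValueError("oxygen concentrations must be non-negative")
    depth, flags = threshold_crossing_depth(oxygen, None, thresholds.oxygen_threshold,
                                            direction="decreasing")
    wet = xr.DataArray(
        np.isfinite(np.moveaxis(oxygen.values, oxygen.get_axis_num("depth"), -1)).any(axis=-1),
        dims=depth.dims, coords=depth.coords,
    )
    fallback = ~flags["reached"] & ~flags["too_shallow"] & wet
    bottom = xr.DataArray(grid.bottom_depth, dims=("y", "x"))
    depth = depth.where(~fallback, bottom)
    ds = xr.Dataset(
        {
            "lower_depth": depth,
            "lower_is_bottom_fallback": fallback,
            "hypoxic_at_top": flags["at_top"],
        }
    )
    ds["lower_depth"].attrs.update(units="m", long_name="depth of hypoxic threshold")
    return ds


def vertical_extent(boundaries: xr.Dataset, omit_fallback: bool = False) -> xr.Dataset:
    """Vertical habitat extent (m) between the two boundaries.

    Undefined (NaN, omitted from downstream means) where either boundary
    is undefined — and, with ``omit_fallback``, where the lower boundary
    is a sea-floor fallback.  Columns whose hypoxic boundary sits above
    the light boundary get extent 0 with ``fully_compressed`` set, keeping
    the habitat-lost signal in spatial means.
    """
    upper = boundaries["upper_depth"]
    lower = boundaries["lower_depth"]
    defined = upper.notnull() & lower.notnull()
    if omit_fallback:
        defined = defined & ~boundaries["lower_is_bottom_fallback"]
    raw = lower - upper
    compressed = defined & (raw < 0)
    extent = raw.clip(min=0.0).where(defined)
    out = boundaries.copy()
    out["extent"] = extent
    out["extent"].attrs.update(units="m", long_name="vertical extent of mesopelagic habitat")
    out["fully_compressed"] = compressed
    out.attrs["omit_fallback"] = int(omit_fallback)
    return out


def compute_boundaries(light: xr.DataArray, oxygen: xr.DataArray, grid: ModelGrid,
                       thresholds: HabitatThresholds | None = None,
                       omit_fallback: bool = False) -> xr.Dataset:
    """Upper + lower boundaries and extent in one Dataset."""
    thresholds = thresholds or HabitatThresholds()
    ds = xr.merge([upper_boundary(light, thresholds), lower_boundary(oxygen, grid, thresholds)])
    return vertical_extent(ds, omit_fallback=omit_fallback)


def habitat_area_at_depth(oxygen: xr.DataArray, grid: ModelGrid, mask: np.ndarray,
                          thresholds: HabitatThresholds | None = None) -> xr.DataArray:
    """Habitat area (km²) above the hypoxic threshold at the reference depth.

    Per time step: the summed area of analysis-domain cells whose
    interpolated oxygen at the reference depth (default 300 m) exceeds the
    oxygen threshold.  Cells with bottom shallower than the reference
    depth are excluded.
    """
    thresholds = thresholds or HabitatThresholds()
    z = thresholds.reference_depth_for_area
    do_z = extract_at_depth(oxygen, z)
    deep_enough = xr.DataArray(grid.bottom_depth >= z, dims=("y", "x"))
    mask_da = xr.DataArray(np.asarray(mask, dtype=bool), dims=("y", "x"))
    area = xr.DataArray(grid.cell_area, dims=("y", "x"))
    above = (do_z > thresholds.oxygen_threshold) & deep_enough & mask_da
    out = (area * above).sum(dim=("y", "x"))
    out = out.rename("habitat_area")
    out.attrs.update(units="km2",
                     long_name=f"area above {thresholds.oxygen_threshold} mmol/m3 at {z} m")
    return out
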