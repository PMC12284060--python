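"""NetCDF reading/writing.

All files go through xarray's scipy backend (classic NetCDF-3, 64-bit
offsets), which keeps the on-disk format dependency-light.  Boolean flag
variables are stored as byte variables with flag attributes; every file
written here carries ``package_version`` and (when supplied) the
configuration hash in its global attributes.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from . import __version__
from .grid import ModelGrid

ENGINE = "scipy"


def _stamp(ds: xr.Dataset, config_hash: str | None = None) -> xr.Dataset:
    ds = ds.copy()
    ds.attrs["package_version"] = __version__
    if config_hash:
        ds.attrs["config_hash"] = config_hash
    return ds


def _encode_flags(ds: xr.Dataset) -> xr.Dataset:
    ds = ds.copy()
    for name, da in ds.data_vars.items():
        if da.dtype == bool:
            ds[name] = da.astype("i1")
            ds[name].attrs.update(flag_values="0 1", flag_meanings=f"not_{name} {name}")
    return ds


def write_dataset(ds: xr.Dataset, path, config_hash: str | None = None) -> None:
    ds = _encode_flags(_stamp(ds, config_hash))
    # scipy backend dislikes non-scalar/None attrs
    for k, v in list(ds.attrs.items()):
        if not isinstance(v, (str, int, float, np.integer, np.floating)):
            ds.attrs[k] = repr(v)
    ds.to_netcdf(path, engine=ENGINE, format="NETCDF3_64BIT")


def write_member(member: xr.Dataset, grid: ModelGrid, path, config_hash: str | None = None) -> None:
    """One file per ensemble member: fields plus the grid variables."""
    write_dataset(xr.merge([member, grid.to_dataset()], combine_attrs="override"),
                  path, config_hash)


def read_member(path, var_map: dict[str, str] | None = None) -> tuple[ModelGrid, xr.Dataset]:
    """Read a member file back into (grid, fields).

    ``var_map`` maps canonical names (temperature, oxygen, phyto, swrad,
    lat, lon, bottom_depth, land_mask, cell_area) to the file's names.
    """
    var_map = var_map or {}
    ds = xr.open_dataset(path, engine=ENGINE).load()
    grid_names = ("lat", "lon", "bottom_depth", "land_mask", "cell_area")
    grid = ModelGrid.from_dataset(ds, {k: var_map.get(k, k) for k in grid_names})
    fields = {}
    for canonical in ("temperature", "oxygen", "phyto", "swrad"):
        name = var_map.get(canonical, canonical)
        if name in ds:
            fields[canonical] = ds[name].rename(canonical)
    missing = {"temperature", "oxygen"} - set(fields)
    if missing:
        raise ValueError(f"member file {path} lacks required variables: {sorted(missing)} "
                         f"(declare a variable-name mapping if they are named differently)")
    out = xr.Dataset(fields, attrs=dict(ds.attrs))
    return grid, out


def read_boundaries(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine=ENGINE).load()
    for name, da in ds.data_vars.items():
        if da.dtype == np.int8:
            ds[name] = da.astype(bool)
    return ds
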