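"""Model grid geometry, bathymetry, and the analysis-domain mask.

The analysis domain used throughout the package follows the standard
eastern-boundary-upwelling habitat definition: water cells deeper than a
minimum isobath (default 400 m), within a maximum offshore distance of the
coast (default 200 km), and inside a latitude band (default 34.5-40 °N,
Point Conception to Cape Mendocino).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class ModelGrid:
    """Horizontal grid: cell-center coordinates, bathymetry, land mask, areas.

    All 2-D arrays share the shape (ny, nx).  ``bottom_depth`` is meters,
    positive down (the depth convention used everywhere in this package);
    ``cell_area`` is km²; ``land_mask`` is True on land.
    """

    lat: np.ndarray
    lon: np.ndarray
    bottom_depth: np.ndarray
    land_mask: np.ndarray
    cell_area: np.ndarray

    def __post_init__(self):
        arrs = [self.lat, self.lon, self.bottom_depth, self.land_mask, self.cell_area]
        shapes = {np.asarray(a).shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError(f"grid arrays have inconsistent shapes: {shapes}")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        if np.any((self.lat < -90) | (self.lat > 90)):
            raise ValueError("latitudes outside [-90, 90]")
        wet = ~self.land_mask
        if np.any(self.bottom_depth[wet] < 0):
            raise ValueError("negative bottom depth on water cells")
        if np.any(self.cell_area[wet] <= 0):
            raise ValueError("non-positive cell area on water cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.shape

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask

    def to_dataset(self) -> xr.Dataset:
        """Export the grid as a CF-styled xarray Dataset."""
        dims = ("y", "x")
        ds = xr.Dataset(
            {
                "lat": (dims, self.lat, {"units": "degrees_north", "standard_name": "latitude"}),
                "lon": (dims, self.lon, {"units": "degrees_east", "standard_name": "longitude"}),
                "bottom_depth": (dims, self.bottom_depth, {"units": "m", "positive": "down",
                                                           "standard_name": "sea_floor_depth_below_sea_surface"}),
                "land_mask": (dims, self.land_mask.astype("i1"), {"flag_values": "0 1",
                                                                  "flag_meanings": "water land"}),
                "cell_area": (dims, self.cell_area, {"units": "km2"}),
            }
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, name_map: dict[str, str] | None = None) -> "ModelGrid":
        """Build a grid from a Dataset, optionally remapping variable names.

        ``name_map`` maps the canonical names (lat, lon, bottom_depth,
        land_mask, cell_area) to the names used in the file.
        """
        name_map = name_map or {}
        def get(canonical):
            return np.asarray(ds[name_map.get(canonical, canonical)].values)
        return cls(
            lat=get("lat"),
            lon=get("lon"),
            bottom_depth=get("bottom_depth"),
            land_mask=get("land_mask").astype(bool),
            cell_area=get("cell_area"),
        )


@dataclass
class DomainMaskParams:
    """Thresholds defining the analysis domain."""

    min_bottom_depth_m: float = 400.0
    max_offshore_km: float = 200.0
    lat_min_deg: float = 34.5
    lat_max_deg: float = 40.0

    def __post_init__(self):
        if self.min_bottom_depth_m <= 0:
            raise ValueError("min_bottom_depth_m must be positive")
        if self.max_offshore_km <= 0:
            raise ValueError("max_offshore_km must be positive")
        if self.lat_min_deg >= self.lat_max_deg:
            raise ValueError("lat_min_deg must be < lat_max_deg")


def distance_offshore(grid: ModelGrid) -> np.ndarray:
    """Distance (km) from each water cell center to the nearest land cell center.

    Land cells get distance 0.  The offshore distance is measured to the
    coastline as represented by land cells, by great-circle (haversine)
    distance; no coastline polygon is used.
    """
    if not grid.land_mask.any():
        raise ValueError(
            "grid has no land cells: cannot measure offshore distance without a coastline"
        )
    land_lat = grid.lat[grid.land_mask]
    land_lon = grid.lon[grid.land_mask]
    out = np.zeros(grid.shape, dtype=float)
    wet = grid.water_mask
    # all-pairs haversine, vectorised over land cells per water cell block
    wlat = grid.lat[wet][:, None]
    wlon = grid.lon[wet][:, None]
    d = haversine_km(wlat, wlon, land_lat[None, :], land_lon[None, :])
    out[wet] = d.min(axis=1)
    return out


def build_domain_mask(grid: ModelGrid, params: DomainMaskParams | None = None,
                      offshore_km: np.ndarray | None = None) -> np.ndarray:
    """Boolean analysis-domain mask.

    True iff the cell is water, bottom_depth >= min_bottom_depth_m, offshore
    distance <= max_offshore_km, and latitude within [lat_min, lat_max].
    Bounds are inclusive (cells exactly on a bound are kept).
    """
    params = params or DomainMaskParams()
    if offshore_km is None:
        offshore_km = distance_offshore(grid)
    mask = (
        grid.water_mask
        & (grid.bottom_depth >= params.min_bottom_depth_m)
        & (offshore_km <= params.max_offshore_km)
        & (grid.lat >= params.lat_min_deg)
        & (grid.lat <= params.lat_max_deg)
    )
    if not mask.any():
        logger.warning("domain mask is empty for params %s", params)
    return mask


def domain_area(grid: ModelGrid, mask: np.ndarray) -> float:
    """Total area (km²) of the masked cells."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    return float(grid.cell_area[mask].sum())
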