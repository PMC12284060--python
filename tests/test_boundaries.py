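import numpy as np
import pandas as pd
import pytest
import xarray as xr

from mesohab.boundaries import (HabitatThresholds, compute_boundaries,
                                habitat_area_at_depth, lower_boundary,
                                threshold_crossing_depth, upper_boundary,
                                vertical_extent)
from mesohab.fields import make_field
from mesohab.grid import domain_area
from tests.conftest import uniform_grid


def column(values, depths, units="W m-2", name="var"):
    v = np.asarray(values, dtype=float)[None, :, None, None]
    return make_field(v, depths, pd.to_datetime(["2000-06-15"]), name, units)


class TestThresholdCrossing:
    def test_interpolated_crossing(self):
        # light 0.03 at 200 m, 0.01 at 250 m, threshold 0.0217:
        # 200 + 50*(0.03-0.0217)/(0.03-0.01) = 220.75
        d, flags = threshold_crossing_depth(np.array([0.03, 0.01]),
                                            np.array([200.0, 250.0]), 0.0217)
        assert d == pytest.approx(220.75)
        assert flags["reached"]

    def test_not_reached(self):
        d, flags = threshold_crossing_depth(np.array([5.0, 4.0, 3.0]),
                                            np.array([0.0, 50, 100.0]), 0.0217)
        assert np.isnan(d)
        assert not flags["reached"]

    def test_exact_tie_at_level(self):
        d, _ = threshold_crossing_depth(np.array([100.0, 63.0, 40.0]),
                                        np.array([200.0, 300.0, 400.0]), 63.0)
        assert d == 300.0

    def test_increasing_direction(self):
        # density-style profile rising past a threshold
        d, _ = threshold_crossing_depth(np.array([10.0, 20.0, 30.0]),
                                        np.array([0.0, 10.0, 20.0]), 25.0,
                                        direction="increasing")
        assert d == pytest.approx(15.0)

    def test_single_wet_level_flagged(self):
        d, flags = threshold_crossing_depth(np.array([0.5, np.nan, np.nan]),
                                            np.array([0.0, 10.0, 20.0]), 1.0)
        assert np.isnan(d)
        assert flags["too_shallow"]


class TestUpperBoundary:
    depths = np.arange(0.0, 400.0, 5.0)

    def closed_form(self, i0, k, thr=0.0217):
        return np.log(i0 / thr) / k

    def test_matches_closed_form_within_half_meter(self):
        thr = HabitatThresholds()
        for i0, k in [(77.4, 0.0437), (50.0, 0.03), (120.0, 0.06)]:
            light = column(i0 * np.exp(-k * self.depths), self.depths)
            ds = upper_boundary(light, thr)
            expect = self.closed_form(i0, k)
            assert ds["upper_depth"].item() == pytest.approx(expect, abs=0.5)

    def test_dark_surface_flagged_undefined(self):
        light = column(0.01 * np.exp(-0.05 * self.depths), self.depths)
        ds = upper_boundary(light)
        assert np.isnan(ds["upper_depth"].item())
        assert bool(ds["surface_below_threshold"].item())

    def test_higher_attenuation_shoals_boundary(self):
        z1 = upper_boundary(column(80 * np.exp(-0.04 * self.depths), self.depths))
        z2 = upper_boundary(column(80 * np.exp(-0.05 * self.depths), self.depths))
        assert z2["upper_depth"].item() < z1["upper_depth"].item()

    def test_non_monotone_light_rejected(self):
        prof = 80 * np.exp(-0.04 * self.depths)
        prof[10] = prof[9] * 1.1
        with pytest.raises(ValueError, match="decreasing"):
            upper_boundary(column(prof, self.depths))


class TestLowerBoundary:
    depths = np.arange(0.0, 1001.0, 25.0)

    def test_interpolated_crossing(self):
        # linear DO 100 mmol/m³ at 200 m to 40 at 400 m -> 63 at ~323.3 m
        prof = np.interp(self.depths, [0, 200, 400, 1000], [250, 100, 40, 40])
        g = uniform_grid(1, 1, bottom=1000.0)
        ds = lower_boundary(column(prof, self.depths, units="mmol m-3"), g)
        assert ds["lower_depth"].item() == pytest.approx(200 + 200 * 37 / 60, abs=0.5)
        assert not bool(ds["lower_is_bottom_fallback"].item())

    def test_bottom_fallback_when_threshold_not_met(self):
        prof = np.full(len(self.depths), 80.0)  # minimum DO 80: never hypoxic
        g = uniform_grid(1, 1, bottom=1000.0)
        ds = lower_boundary(column(prof, self.depths, units="mmol m-3"), g)
        assert ds["lower_depth"].item() == 1000.0
        assert bool(ds["lower_is_bottom_fallback"].item())

    def test_exact_tie_at_level(self):
        prof = np.interp(self.depths, [0, 300, 1000], [200, 63, 10])
        g = uniform_grid(1, 1)
        ds = lower_boundary(column(prof, self.depths, units="mmol m-3"), g)
        assert ds["lower_depth"].item() == pytest.approx(300.0, abs=1e-9)

    def test_hypoxic_at_top(self):
        prof = np.full(len(self.depths), 30.0)
        g = uniform_grid(1, 1)
        ds = lower_boundary(column(prof, self.depths, units="mmol m-3"), g)
        assert bool(ds["hypoxic_at_top"].item())
        assert ds["lower_depth"].item() == 0.0

    def test_lowering_oxygen_never_deepens_boundary(self):
        rng = np.random.default_rng(8)
        g = uniform_grid(1, 1)
        base = np.interp(self.depths, [0, 300, 1000], [250, 63, 20])
        for _ in range(5):
            drop = rng.uniform(0, 30)
            d0 = lower_boundary(column(base, self.depths, units="mmol m-3"), g)
            d1 = lower_boundary(column(np.clip(base - drop, 0, None), self.depths,
                                       units="mmol m-3"), g)
            assert d1["lower_depth"].item() <= d0["lower_depth"].item() + 1e-9


class TestVerticalExtent:
    def _bnd(self, upper, lower, fallback=False):
        dims = ("time", "y", "x")
        shape = (1, 1, 1)
        coords = {"time": pd.to_datetime(["2000-06-15"])}
        return xr.Dataset({
            "upper_depth": (dims, np.full(shape, upper), {}),
            "lower_depth": (dims, np.full(shape, lower), {}),
            "upper_undefined": (dims, np.isnan(np.full(shape, upper))),
            "surface_below_threshold": (dims, np.zeros(shape, dtype=bool)),
            "lower_is_bottom_fallback": (dims, np.full(shape, fallback)),
            "hypoxic_at_top": (dims, np.zeros(shape, dtype=bool)),
        }, coords=coords)

    def test_basic_distance(self):
        ds = vertical_extent(self._bnd(188.0, 293.0))
        assert ds["extent"].item() == pytest.approx(105.0)
        assert not bool(ds["fully_compressed"].item())

    def test_coincident_boundaries(self):
        ds = vertical_extent(self._bnd(250.0, 250.0))
        assert ds["extent"].item() == 0.0

    def test_inverted_boundaries_compressed_to_zero(self):
        ds = vertical_extent(self._bnd(250.0, 240.0))
        assert ds["extent"].item() == 0.0
        assert bool(ds["fully_compressed"].item())

    def test_undefined_boundary_omitted(self):
        ds = vertical_extent(self._bnd(np.nan, 293.0))
        assert np.isnan(ds["extent"].item())

    def test_omit_fallback_drops_fallback_columns(self):
        bnd = self._bnd(188.0, 1000.0, fallback=True)
        keep = vertical_extent(bnd, omit_fallback=False)
        drop = vertical_extent(bnd, omit_fallback=True)
        assert keep["extent"].item() == pytest.approx(812.0)
        assert np.isnan(drop["extent"].item())


class TestComputeBoundariesConservation:
    def test_defined_plus_omitted_covers_wet_columns(self, small_grid):
        depths = np.arange(0.0, 1001.0, 20.0)
        nt = 2
        ny, nx = small_grid.shape
        times = pd.date_range("2000-01-15", periods=nt, freq="MS")
        k = 0.0437
        light = 77.4 * np.exp(-k * depths)[None, :, None, None] * np.ones((nt, 1, ny, nx))
        oxy = np.interp(depths, [0, 290, 1000], [250, 63, 5])[None, :, None, None] \
            * np.ones((nt, 1, ny, nx))
        below = depths[None, :, None, None] > small_grid.bottom_depth[None, None]
        land = small_grid.land_mask[None, None]
        for arr in (light, oxy):
            arr[np.broadcast_to(below | land, arr.shape)] = np.nan
        light_da = make_field(light, depths, times, "light", "W m-2")
        oxy_da = make_field(oxy, depths, times, "oxygen", "mmol m-3")
        ds = compute_boundaries(light_da, oxy_da, small_grid)
        wet = small_grid.water_mask & (small_grid.bottom_depth > 0)
        for it in range(nt):
            ext = ds["extent"].isel(time=it).values
            defined = np.isfinite(ext)
            omitted = ~defined & wet
            assert defined.sum() + omitted.sum() == wet.sum()
            # extent equals lower - upper wherever not compressed
            ok = defined & ~ds["fully_compressed"].isel(time=it).values
            diff = (ds["lower_depth"] - ds["upper_depth"]).isel(time=it).values
            np.testing.assert_allclose(ext[ok], diff[ok], rtol=1e-12)


class TestHabitatArea:
    depths = np.arange(0.0, 501.0, 25.0)

    def _oxygen(self, grid, values_at_300):
        ny, nx = grid.shape
        prof = np.ones(len(self.depths))
        oxy = prof[None, :, None, None] * np.asarray(values_at_300)[None, None, :, :]
        return make_field(oxy, self.depths, pd.to_datetime(["2000-06-15"]),
                          "oxygen", "mmol m-3")

    def test_all_above_threshold_gives_domain_area(self):
        g = uniform_grid(2, 2, area=10.0, bottom=1000.0)
        mask = np.ones((2, 2), dtype=bool)
        oxy = self._oxygen(g, np.full((2, 2), 100.0))
        area = habitat_area_at_depth(oxy, g, mask)
        assert area.item() == pytest.approx(domain_area(g, mask))

    def test_none_above_threshold_gives_zero(self):
        g = uniform_grid(2, 2, area=10.0)
        oxy = self._oxygen(g, np.full((2, 2), 20.0))
        assert habitat_area_at_depth(oxy, g, np.ones((2, 2), dtype=bool)).item() == 0.0

    def test_half_above_threshold(self):
        g = uniform_grid(2, 2, area=10.0)
        vals = np.array([[100.0, 100.0], [20.0, 20.0]])
        oxy = self._oxygen(g, vals)
        area = habitat_area_at_depth(oxy, g, np.ones((2, 2), dtype=bool))
        assert area.item() == pytest.approx(20.0)

    def test_shallow_cells_excluded(self):
        g = uniform_grid(1, 2, area=10.0)
        g.bottom_depth[0, 0] = 200.0  # shallower than the 300 m reference
        oxy = self._oxygen(g, np.full((1, 2), 100.0))
        assert habitat_area_at_depth(oxy, g, np.ones((1, 2), dtype=bool)).item() == 10.0

    def test_lowering_oxygen_never_increases_area(self):
        g = uniform_grid(2, 2, area=10.0)
        vals = np.array([[100.0, 70.0], [64.0, 50.0]])
        a0 = habitat_area_at_depth(self._oxygen(g, vals), g, np.ones((2, 2), dtype=bool))
        a1 = habitat_area_at_depth(self._oxygen(g, vals - 10), g, np.ones((2, 2), dtype=bool))
        assert a1.item() <= a0.item()
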