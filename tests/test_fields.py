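import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st
from scipy import stats

from mesohab.fields import (HydroParams, OpticsParams, attenuation_coefficient,
                            buoyancy_frequency_max, euphotic_depth, extract_at_depth,
                            integrate_upper, irradiance_to_photon_flux, light_profile,
                            linear_density, make_field, photon_flux_to_irradiance,
                            phyto_to_chl)


def column_field(values, depths, units="mmol m-3"):
    """One-column (time=1, y=1, x=1) field from a 1-D profile."""
    v = np.asarray(values, dtype=float)[None, :, None, None]
    return make_field(v, depths, pd.to_datetime(["2000-01-15"]), "var", units)


class TestPhotonConversion:
    def test_threshold_value(self):
        # the 0.1 µmol photons/m²/s habitat light threshold in energy units
        assert photon_flux_to_irradiance(0.1) == pytest.approx(0.0217, abs=5e-5)

    def test_zero_and_definition(self):
        assert photon_flux_to_irradiance(0.0) == 0.0
        assert photon_flux_to_irradiance(4.6) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            photon_flux_to_irradiance(-0.1)
        with pytest.raises(ValueError):
            irradiance_to_photon_flux(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1e6, allow_nan=False, allow_subnormal=False))
    def test_round_trip_exact(self, q):
        assert irradiance_to_photon_flux(photon_flux_to_irradiance(q)) == pytest.approx(q, rel=1e-15, abs=0.0)


class TestPhytoToChl:
    def test_hand_value(self):
        # 1 mmol N/m³ × (106/16) × 12.011 g/mol × 0.03 = 2.3872 mg Chl/m³
        assert phyto_to_chl(1.0) == pytest.approx(2.3872, abs=1e-4)
        assert phyto_to_chl(0.0) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0, 100, allow_nan=False))
    def test_linearity(self, p):
        params = OpticsParams()
        assert phyto_to_chl(p) == pytest.approx(p * params.chl_per_mmol_n)
        assert phyto_to_chl(10 * p) == pytest.approx(10 * phyto_to_chl(p))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phyto_to_chl(-0.5)


class TestIntegrateUpper:
    depths = np.arange(0.0, 201.0, 20.0)

    def test_uniform_integral_and_average(self):
        f = column_field(np.full(len(self.depths), 2.0), self.depths)
        assert integrate_upper(f, 100.0, "integral").item() == pytest.approx(200.0)
        f12 = column_field(np.full(len(self.depths), 12.0), self.depths)
        assert integrate_upper(f12, 100.0, "average").item() == pytest.approx(12.0)

    def test_linear_profile_average(self):
        prof = np.interp(self.depths, [0, 100], [0, 10])  # 0 -> 10 over 0-100 m
        f = column_field(prof, self.depths)
        assert integrate_upper(f, 100.0, "average").item() == pytest.approx(5.0)

    def test_z_max_between_levels(self):
        f = column_field(np.full(len(self.depths), 3.0), self.depths)
        assert integrate_upper(f, 90.0, "integral").item() == pytest.approx(270.0)

    def test_shallow_column_integrates_to_bottom(self):
        prof = np.full(len(self.depths), 4.0)
        prof[self.depths > 60] = np.nan  # bottom at 60 m
        f = column_field(prof, self.depths)
        assert integrate_upper(f, 100.0, "integral").item() == pytest.approx(240.0)
        assert integrate_upper(f, 100.0, "average").item() == pytest.approx(4.0)

    def test_errors(self):
        f = column_field(np.full(len(self.depths), 1.0), self.depths)
        with pytest.raises(ValueError):
            integrate_upper(f, 500.0)
        with pytest.raises(ValueError):
            integrate_upper(f, 100.0, mode="median")


class TestAttenuation:
    def test_pure_water_limit_and_formula(self):
        p = OpticsParams()
        assert attenuation_coefficient(0.0, p) == pytest.approx(p.k_chl_a)
        chl = 2.5
        assert attenuation_coefficient(chl, p) == pytest.approx(
            p.k_chl_a + p.k_chl_b * chl ** p.k_chl_c)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0, 50), st.floats(0, 50))
    def test_monotone_in_chl(self, c1, c2):
        lo, hi = sorted((c1, c2))
        assert attenuation_coefficient(lo) <= attenuation_coefficient(hi)


class TestLightProfile:
    def test_surface_par_fraction(self):
        p = OpticsParams()
        light = light_profile(100.0, 0.05, [0.0, 10.0], p)
        assert float(light.sel(depth=0.0)) == pytest.approx(43.0)

    def test_exponential_decay_value(self):
        p = OpticsParams(par_fraction_of_shortwave=1.0)
        light = light_profile(100.0, 0.04605, [0.0, 100.0], p)
        assert float(light.sel(depth=100.0)) == pytest.approx(1.0, rel=1e-3)

    def test_doubling_k_squares_transmittance(self):
        p = OpticsParams(par_fraction_of_shortwave=1.0)
        z = [0.0, 123.0]
        t1 = float(light_profile(1.0, 0.01, z, p).sel(depth=123.0))
        t2 = float(light_profile(1.0, 0.02, z, p).sel(depth=123.0))
        assert t2 == pytest.approx(t1 ** 2, rel=1e-10)

    def test_strictly_decreasing(self):
        light = light_profile(50.0, 0.03, np.arange(0, 300, 5.0))
        assert np.all(np.diff(light.values) < 0)


class TestEuphoticDepth:
    def test_value_scaling_and_error(self):
        assert euphotic_depth(0.04605) == pytest.approx(100.0, rel=1e-3)
        assert euphotic_depth(2 * 0.04605) == pytest.approx(50.0, rel=1e-3)
        with pytest.raises(ValueError):
            euphotic_depth(0.0)

    def test_independent_of_surface_irradiance(self):
        # light at the euphotic depth is 1% of surface light for any I0
        p = OpticsParams(par_fraction_of_shortwave=1.0)
        k = 0.0731
        zeu = euphotic_depth(k)
        for i0 in (10.0, 100.0, 1000.0):
            prof = light_profile(i0, k, [0.0, zeu], p)
            ratio = float(prof.sel(depth=zeu)) / float(prof.sel(depth=0.0))
            assert ratio == pytest.approx(0.01, rel=1e-10)


class TestChlLightCoupling:
    def test_chl_anticorrelates_with_light_at_150m(self):
        # chl drives k drives light at depth: strongly negative correlation
        rng = np.random.default_rng(11)
        # fractional interannual-scale variability around a base value
        chl = 2.0 * (1.0 + rng.normal(0.0, 0.15, 200)).clip(0.3)
        k = attenuation_coefficient(chl)
        light150 = 0.43 * 180.0 * np.exp(-k * 150.0)
        r = stats.pearsonr(chl, light150).statistic
        assert r <= -0.9


class TestBuoyancyFrequency:
    depths = np.arange(0.0, 201.0, 10.0)

    def test_uniform_density_gives_zero(self):
        n2, _ = buoyancy_frequency_max(np.full(len(self.depths), 1025.0), self.depths)
        assert n2 == 0.0

    def test_linear_gradient_hand_value(self):
        rho = 1025.0 + 0.01 * self.depths
        n2, _ = buoyancy_frequency_max(rho, self.depths)
        assert n2 == pytest.approx(9.81 / 1025.0 * 0.01, rel=1e-10)

    def test_two_layer_interface(self):
        rho = np.where(self.depths < 50, 1024.0, 1026.0)
        n2, z = buoyancy_frequency_max(rho, self.depths)
        assert z == pytest.approx(45.0)  # midpoint of the 40-50 m step

    def test_matches_dense_finite_difference_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b, c = rng.uniform(0.001, 0.05), rng.uniform(10, 80), rng.uniform(0, 2)
            rho = 1024.0 + a * self.depths + c * np.tanh((self.depths - b) / 20.0)
            params = HydroParams()
            zm = 0.5 * (self.depths[:-1] + self.depths[1:])
            n2_all = (params.gravity / params.reference_density) * np.diff(rho) / np.diff(self.depths)
            sel = zm <= params.n2_search_depth_m
            expect = n2_all[sel].max()
            got, _ = buoyancy_frequency_max(rho, self.depths)
            assert got == pytest.approx(expect, rel=1e-8)

    def test_search_depth_respected(self):
        rho = 1024.0 + 0.001 * self.depths
        rho[self.depths >= 150] += 5.0  # huge gradient, but below 100 m
        n2, z = buoyancy_frequency_max(rho, self.depths)
        assert z <= 100.0
        assert n2 == pytest.approx(9.81 / 1025.0 * 0.001, rel=1e-6)

    def test_gridded_input(self):
        rho = 1024.0 + 0.01 * self.depths
        f = column_field(rho, self.depths, units="kg m-3")
        n2, z = buoyancy_frequency_max(f)
        assert n2.dims == ("time", "y", "x")
        assert float(n2[0, 0, 0]) == pytest.approx(9.81 / 1025.0 * 0.01, rel=1e-9)

    def test_linear_density_gradient(self):
        # thermal stratification: warm over cold gives stable density
        t = np.array([15.0, 10.0, 5.0])
        rho = linear_density(t)
        assert np.all(np.diff(rho) > 0)


class TestExtractAtDepth:
    depths = np.array([0.0, 100.0, 200.0, 400.0])

    def test_exact_level_and_interpolation(self):
        f = column_field([12.0, 10.0, 8.0, 6.0], self.depths, units="degC")
        assert extract_at_depth(f, 100.0).item() == pytest.approx(10.0)
        assert extract_at_depth(f, 150.0).item() == pytest.approx(9.0)

    def test_below_bottom_masked(self):
        f = column_field([12.0, 10.0, np.nan, np.nan], self.depths, units="degC")
        assert np.isnan(extract_at_depth(f, 150.0).item())

    def test_out_of_range(self):
        f = column_field([1.0, 1.0, 1.0, 1.0], self.depths)
        with pytest.raises(ValueError):
            extract_at_depth(f, 500.0)
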