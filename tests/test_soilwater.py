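import mpmath
import numpy as np
import pytest

from vom.errors import ConfigurationError, DomainError
from vom.soilwater import (SOIL_TEXTURES, SITE_PRESETS, CatchmentGeometry,
                           SoilColumnState, drainage_flux, drainage_flux_at,
                           hydrostatic_state, soil_evaporation,
                           step_soil_water, storage_mm, suction_heads,
                           uniform_state, vg_conductivity, vg_saturation,
                           vg_suction_from_saturation, vg_water_content,
                           water_table)

mpmath.mp.dps = 50


def mp_saturation(h, p):
    """Independent high-precision retention curve."""
    h = mpmath.mpf(h)
    n = mpmath.mpf(p.n_vg)
    a = mpmath.mpf(p.alpha_vg)
    m = 1 - 1 / n
    return (1 + (a * h) ** n) ** (-m)


def mp_conductivity(se, p):
    """Independent high-precision Mualem conductivity."""
    se = mpmath.mpf(se)
    n = mpmath.mpf(p.n_vg)
    m = 1 - 1 / n
    t = 1 - (1 - se ** (1 / m)) ** m
    return mpmath.mpf(p.k_sat) * mpmath.sqrt(se) * t * t


class TestRetentionCurve:
    def test_saturated_limit(self, sandy_loam):
        assert vg_saturation(0.0, sandy_loam) == 1.0
        assert vg_water_content(0.0, sandy_loam) == pytest.approx(0.41)

    def test_residual_limit(self, sandy_loam):
        assert vg_water_content(1e9, sandy_loam) == pytest.approx(
            sandy_loam.theta_r, abs=1e-6)

    def test_sandy_loam_one_metre_oracle(self, sandy_loam):
        expected = float(mp_saturation(1.0, sandy_loam))
        assert vg_saturation(1.0, sandy_loam) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(100):
            p = list(SOIL_TEXTURES.values())[int(rng.integers(3))]
            h = float(10.0 ** rng.uniform(-3, 3))
            assert vg_saturation(h, p) == pytest.approx(
                float(mp_saturation(h, p)), rel=1e-12)

    def test_inverse_round_trip(self, sandy_loam, rng):
        for h in 10.0 ** rng.uniform(-3, 3, size=20):
            se = vg_saturation(float(h), sandy_loam)
            assert vg_suction_from_saturation(se, sandy_loam) == pytest.approx(
                float(h), rel=1e-8)

    def test_negative_head_rejected(self, sandy_loam):
        with pytest.raises(DomainError):
            vg_saturation(-0.1, sandy_loam)


class TestConductivity:
    def test_saturated_equals_ksat(self, sandy_loam):
        assert vg_conductivity(1.0, sandy_loam) == sandy_loam.k_sat
        assert sandy_loam.k_sat == 1.228e-5

    def test_dry_limit(self, sandy_loam):
        assert vg_conductivity(0.0, sandy_loam) == 0.0

    def test_sandy_clay_loam_half_saturation_oracle(self):
        p = SOIL_TEXTURES["sandy clay loam"]
        expected = float(mp_conductivity(0.5, p))
        assert vg_conductivity(0.5, p) == pytest.approx(expected, rel=1e-12)

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(100):
            p = list(SOIL_TEXTURES.values())[int(rng.integers(3))]
            se = float(rng.uniform(0.01, 0.999))
            assert vg_conductivity(se, p) == pytest.approx(
                float(mp_conductivity(se, p)), rel=1e-12)

    def test_monotone_in_saturation(self, sandy_loam):
        se = np.linspace(0, 1, 200)
        k = vg_conductivity(se, sandy_loam)
        assert np.all(np.diff(k) >= 0)

    def test_out_of_range_rejected(self, sandy_loam):
        with pytest.raises(DomainError):
            vg_conductivity(1.2, sandy_loam)


class TestGeometry:
    def test_site_presets_layer_counts(self):
        soil_name, geom = SITE_PRESETS["VIR"]
        assert soil_name == "sandy loam"
        assert geom.n_layers == 30
        assert SITE_PRESETS["TUM"][1].n_layers == 60

    def test_invalid_geometry(self):
        with pytest.raises(ConfigurationError):
            CatchmentGeometry(z_surface=5.0, z_channel=6.0, slope_deg=2.0)
        with pytest.raises(ConfigurationError):
            CatchmentGeometry(z_surface=5.3, z_channel=1.0, slope_deg=2.0)


class TestStep:
    def test_hydrostatic_equilibrium_is_stationary(self, sandy_loam,
                                                   small_geometry):
        state = hydrostatic_state(0.25, sandy_loam, small_geometry)
        res = step_soil_water(state, 0.0, np.zeros(4), 0.0, 1.0,
                              sandy_loam, small_geometry)
        # below the channel elevation: no drainage, nothing moves
        assert res.drainage == 0.0
        assert res.runoff == 0.0
        np.testing.assert_allclose(res.state.theta, state.theta, rtol=1e-9)

    def test_saturated_column_sheds_rain_as_runoff(self, sandy_loam):
        geom = CatchmentGeometry(z_surface=2.0, z_channel=1.5, slope_deg=2.0)
        state = uniform_state(1.0, sandy_loam, geom)
        res = step_soil_water(state, 30.0, np.zeros(4), 0.0, 1.0,
                              sandy_loam, geom)
        assert res.runoff == pytest.approx(30.0)
        assert res.infiltration == 0.0
        # storage only changes through drainage
        assert storage_mm(res.state, geom) == pytest.approx(
            storage_mm(state, geom) - res.drainage, rel=1e-12)

    def test_pulse_mass_balance_closure(self, sandy_loam, small_geometry):
        state = uniform_state(0.15, sandy_loam, small_geometry)
        s0 = storage_mm(state, small_geometry)
        res = step_soil_water(state, 10.0, np.zeros(4), 0.0, 1.0,
                              sandy_loam, small_geometry)
        s1 = storage_mm(res.state, small_geometry)
        flux_in = res.infiltration
        flux_out = res.drainage + res.e_s + float(np.sum(res.uptake))
        assert abs((s1 - s0) - (flux_in - flux_out)) < 1e-9 * s0
        assert res.infiltration + res.runoff == pytest.approx(10.0)

    def test_sinks_capped_never_negative_storage(self, sandy_loam,
                                                 small_geometry):
        state = uniform_state(0.05, sandy_loam, small_geometry)
        demand = np.full(4, 100.0)  # far beyond available water
        res = step_soil_water(state, 0.0, demand, 50.0, 1.0,
                              sandy_loam, small_geometry)
        assert res.shortfall > 0
        assert np.all(res.state.theta >= sandy_loam.theta_r - 1e-12)

    def test_invalid_inputs(self, sandy_loam, small_geometry):
        state = uniform_state(0.5, sandy_loam, small_geometry)
        with pytest.raises(DomainError):
            step_soil_water(state, -1.0, np.zeros(4), 0.0, 1.0,
                            sandy_loam, small_geometry)
        with pytest.raises(DomainError):
            step_soil_water(state, 0.0, np.zeros(4), 0.0, 0.0,
                            sandy_loam, small_geometry)

    def test_stability_under_hourly_forcing(self, rng):
        # every Table-4 texture: 200 hourly steps, contents stay in range
        for p in SOIL_TEXTURES.values():
            geom = CatchmentGeometry(z_surface=2.0, z_channel=0.5,
                                     slope_deg=2.0)
            state = uniform_state(0.4, p, geom)
            for i in range(200):
                rain = 8.0 if i % 24 == 0 else 0.0
                res = step_soil_water(state, rain, np.full(4, 0.05), 0.05,
                                      1.0, p, geom)
                state = res.state
                assert np.all(state.theta >= p.theta_r - 1e-12)
                assert np.all(state.theta <= p.theta_s + 1e-12)
                zw = water_table(state, p, geom)
                assert 0.0 <= zw <= geom.z_surface


class TestDrainage:
    def test_zero_at_channel_elevation(self, sandy_loam, small_geometry):
        assert drainage_flux_at(0.5, small_geometry, sandy_loam) == 0.0
        assert drainage_flux_at(0.2, small_geometry, sandy_loam) == 0.0

    def test_maximal_when_fully_saturated(self, sandy_loam, small_geometry):
        q_full = drainage_flux_at(2.0, small_geometry, sandy_loam)
        grid = np.linspace(0.0, 2.0, 50)
        assert all(drainage_flux_at(z, small_geometry, sandy_loam) <= q_full
                   for z in grid)

    def test_strictly_increasing_above_channel(self, sandy_loam,
                                               small_geometry):
        zs = np.linspace(0.51, 2.0, 40)
        qs = [drainage_flux_at(z, small_geometry, sandy_loam) for z in zs]
        assert all(b > a for a, b in zip(qs, qs[1:]))

    def test_state_based_flux_consistent(self, sandy_loam, small_geometry):
        state = uniform_state(1.0, sandy_loam, small_geometry)
        assert drainage_flux(state, small_geometry, sandy_loam) == \
            pytest.approx(drainage_flux_at(2.0, small_geometry, sandy_loam))


class TestSoilEvaporation:
    def test_full_cover_shuts_off(self, sandy_loam, small_geometry):
        state = uniform_state(0.8, sandy_loam, small_geometry)
        assert soil_evaporation(state, 500.0, 30.0, 1.0, sandy_loam) == 0.0

    def test_residual_top_layer_shuts_off(self, sandy_loam, small_geometry):
        state = uniform_state(0.5, sandy_loam, small_geometry)
        state.theta[0] = sandy_loam.theta_r
        assert soil_evaporation(state, 500.0, 30.0, 0.2, sandy_loam) == 0.0

    def test_night_shuts_off(self, sandy_loam, small_geometry):
        state = uniform_state(0.8, sandy_loam, small_geometry)
        assert soil_evaporation(state, 0.0, 25.0, 0.2, sandy_loam) == 0.0

    def test_monotone_in_surface_saturation(self, sandy_loam, small_geometry):
        rates = []
        for se in np.linspace(0.05, 0.95, 10):
            state = uniform_state(se, sandy_loam, small_geometry)
            rates.append(soil_evaporation(state, 600.0, 30.0, 0.3,
                                          sandy_loam))
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_cover_out_of_range(self, sandy_loam, small_geometry):
        state = uniform_state(0.5, sandy_loam, small_geometry)
        with pytest.raises(DomainError):
            soil_evaporation(state, 100.0, 25.0, 1.5, sandy_loam)


class TestStateHelpers:
    def test_suction_consistent_with_retention(self, sandy_loam,
                                               small_geometry):
        state = uniform_state(0.37, sandy_loam, small_geometry)
        h = suction_heads(state, sandy_loam)
        np.testing.assert_allclose(
            [vg_saturation(hi, sandy_loam) for hi in h], 0.37, rtol=1e-9)

    def test_water_table_of_saturated_column(self, sandy_loam,
                                             small_geometry):
        state = uniform_state(1.0, sandy_loam, small_geometry)
        assert water_table(state, sandy_loam, small_geometry) == \
            pytest.approx(2.0)
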