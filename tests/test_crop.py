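"""Crop model: thermal time, phenology, soil water, stress, season simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ricegap import crop
from ricegap.crop import (
    CanopyParams,
    CropCalendar,
    PhenologyParams,
    SoilProfile,
    StressParams,
    capillary_rise,
    effective_temperature,
    heat_sterility,
    simulate_phenology,
    simulate_season,
    soil_water_step,
)
from ricegap.errors import (
    CalibrationInfeasibleError,
    CycleIncompleteError,
    ParameterError,
)


class TestEffectiveTemperature:
    @pytest.mark.parametrize("tmean,expected", [
        (14.0, 0.0),     # base temperature
        (24.0, 10.0),    # linear segment
        (30.0, 16.0),    # optimum
        (36.0, 8.0),     # 16 × (42−36)/(42−30)
        (42.0, 0.0),     # upper cutoff
        (10.0, 0.0),     # below base
    ])
    def test_piecewise_response(self, tmean, expected):
        assert effective_temperature(tmean - 5, tmean + 5) == pytest.approx(expected)

    def test_rejects_tmax_below_tmin(self):
        with pytest.raises(ParameterError):
            effective_temperature(25.0, 20.0)

    @given(st.floats(-5, 50), st.floats(0, 15))
    def test_never_negative_and_bounded(self, tmin, spread):
        teff = effective_temperature(tmin, tmin + spread)
        assert 0.0 <= teff <= 16.0


class TestPhenology:
    def test_closed_form_days_to_flowering(self, make_weather):
        # constant mean T 24 °C → Teff 10 °Cd/d; uniform rate r over DVS 0→1
        wx = make_weather(days=400)
        r = 1.0 / 900.0
        p = PhenologyParams(dvrj=r, dvri=r, dvrp=r, dvrr=r)
        fl, mat, dvs = simulate_phenology(wx, 0, p)
        assert fl == math.ceil(1.0 / (10.0 * r))
        assert mat == fl + math.ceil(900 / 10)  # reproductive phase same °Cd here
        assert dvs[-1] >= 2.0

    def test_doubled_rates_halve_duration(self, make_weather):
        wx = make_weather(days=400)
        r = 1.0 / 900.0
        slow = PhenologyParams(dvrj=r, dvri=r, dvrp=r, dvrr=r)
        fast = PhenologyParams(dvrj=2 * r, dvri=2 * r, dvrp=2 * r, dvrr=2 * r)
        fl_s, _, _ = simulate_phenology(wx, 0, slow)
        fl_f, _, _ = simulate_phenology(wx, 0, fast)
        assert abs(fl_f - fl_s / 2) <= 1

    def test_no_development_at_base_temperature(self, make_weather):
        wx = make_weather(days=400, tmax=19.0, tmin=9.0)  # mean 14 °C
        with pytest.raises(CycleIncompleteError):
            simulate_phenology(wx, 0, PhenologyParams())

    def test_weather_exhausted_raises(self, make_weather):
        wx = make_weather(days=30)
        with pytest.raises(CycleIncompleteError):
            simulate_phenology(wx, 0, PhenologyParams())


class TestCalibration:
    def test_round_trip_on_variable_weather(self, monsoon_weather):
        cal = CropCalendar(sowing_doy=165, duration_days=125)
        phen = crop.calibrate_development_rates(monsoon_weather, cal)
        dates = pd.DatetimeIndex(monsoon_weather["date"])
        fls, mats = [], []
        for year in range(2000, 2018):
            start = int(np.flatnonzero((dates.year == year)
                                       & (dates.dayofyear == 165))[0])
            fl, mat, _ = simulate_phenology(monsoon_weather, start, phen)
            fls.append(fl)
            mats.append(mat)
        assert abs(np.mean(fls) - cal.flowering_offset_days) <= 1.0
        assert abs(np.mean(mats) - cal.duration_days) <= 1.0

    def test_constant_temperature_closed_form_rate(self, make_weather):
        # 90 d to flowering at Teff 10 → combined pre-flowering rate 1/900
        wx = make_weather(days=400, start="2001-01-01")
        cal = CropCalendar(sowing_doy=10, duration_days=120)
        phen = crop.calibrate_development_rates(wx, cal)
        combined = 1.0 / (0.40 / phen.dvrj + 0.25 / phen.dvri + 0.35 / phen.dvrp)
        assert combined == pytest.approx(1.0 / 900.0, rel=0.02)

    def test_flowering_convention_fixed_30_days_before_maturity(self, make_weather):
        wx = make_weather(days=400, start="2001-01-01")
        cal = CropCalendar(sowing_doy=10, duration_days=120)
        assert cal.flowering_offset_days == 90
        phen = crop.calibrate_development_rates(wx, cal)
        fl, mat, _ = simulate_phenology(wx, 9, phen)
        assert abs((mat - fl) - 30) <= 2

    def test_infeasible_target_raises(self, make_weather):
        wx = make_weather(days=400, start="2001-01-01")
        cal = CropCalendar(sowing_doy=10, duration_days=35)  # 5 d to flowering
        with pytest.raises(CalibrationInfeasibleError):
            crop.calibrate_development_rates(wx, cal, max_multiplier=1.5)


class TestSoilWater:
    def test_ample_water_full_ratio(self):
        soil = SoilProfile.rainfed_lowland()
        state = soil.initial_state()
        _, ratio, _ = soil_water_step(state, 10.0, 0.0, 10.0, 0.0, soil)
        assert ratio == 1.0

    def test_dry_soil_zero_ratio(self):
        soil = SoilProfile.rainfed_upland()
        state = crop.SoilWaterState(storage_mm=soil.wilting_mm, pond_mm=0.0)
        _, ratio, _ = soil_water_step(state, 0.0, 0.0, 5.0, 0.0, soil)
        assert ratio == 0.0

    def test_pond_capped_at_bund_and_percolation_at_ksat(self):
        soil = SoilProfile.rainfed_lowland()
        state = soil.initial_state()
        new, _, fluxes = soil_water_step(state, 500.0, 0.0, 0.0, 0.0, soil)
        assert new.pond_mm <= soil.bund_height_cm * 10.0 + 1e-9
        assert fluxes.percolation <= soil.ksat_cm_d * 10.0 + 1e-9
        assert fluxes.runoff > 0

    @pytest.mark.parametrize("soil", [SoilProfile.rainfed_lowland(),
                                      SoilProfile.rainfed_lowland(100.0),
                                      SoilProfile.rainfed_upland()])
    def test_mass_balance_closes_over_120_days(self, soil):
        rng = np.random.default_rng(42)
        state = soil.initial_state()
        total0 = state.total_mm
        sum_in = sum_out = 0.0
        for _ in range(120):
            rain = float(rng.gamma(1.2, 8.0)) if rng.random() < 0.4 else 0.0
            demand = float(rng.uniform(2.0, 8.0))
            evap = float(rng.uniform(0.0, 3.0))
            cap = capillary_rise(soil.groundwater_depth_cm)
            state, _, fx = soil_water_step(state, rain, 0.0, demand, cap, soil,
                                           evaporation_mm=evap)
            sum_in += fx.rain + fx.irrigation + fx.capillary
            sum_out += fx.transpiration + fx.evaporation + fx.percolation + fx.runoff
        assert (state.total_mm - total0) == pytest.approx(sum_in - sum_out, abs=1e-8)

    def test_negative_flux_rejected(self):
        soil = SoilProfile.rainfed_upland()
        with pytest.raises(ParameterError):
            soil_water_step(soil.initial_state(), -1.0, 0.0, 5.0, 0.0, soil)

    def test_capillary_rise_profile(self):
        assert capillary_rise(40.0) == 5.0
        assert capillary_rise(100.0) == 1.0
        assert capillary_rise(1000.0) == 0.0
        assert capillary_rise(70.0) == pytest.approx(3.0)


class TestHeatSterility:
    @pytest.mark.parametrize("tmax,expected", [
        (30.0, 0.0),     # below threshold
        (50.0, 1.0),     # clamped
        (38.6, 0.30),    # 3.0 °C × 0.10 per °C
    ])
    def test_linear_above_threshold(self, tmax, expected):
        assert heat_sterility([tmax] * 5) == pytest.approx(expected)

    def test_window_average(self):
        assert heat_sterility([35.6, 37.6]) == pytest.approx(0.10)

    def test_empty_window(self):
        assert heat_sterility([]) == 0.0


SEASON_CAL = CropCalendar(sowing_doy=165, duration_days=125)


@pytest.fixture(scope="module")
def phen(monsoon_weather):
    return crop.calibrate_development_rates(monsoon_weather, SEASON_CAL)


class TestSeason:
    CAL = SEASON_CAL

    def test_no_light_no_yield(self, make_weather):
        wx = make_weather(days=400, srad=0.0)
        cal = CropCalendar(sowing_doy=10, duration_days=120)
        phen = crop.calibrate_development_rates(wx, cal)
        res = simulate_season(wx, 2000, cal, "irrigated", phenology=phen)
        assert res.yield_mgha == 0.0
        assert res.biomass_mgha == 0.0

    def test_cold_snap_kills_crop(self, make_weather):
        tmax = np.full(400, 29.0)
        tmin = np.full(400, 19.0)
        tmax[60:64] = 13.0   # mean 11 °C for > 3 consecutive days mid-season
        tmin[60:64] = 9.0
        wx = make_weather(days=400, tmax=tmax, tmin=tmin)
        cal = CropCalendar(sowing_doy=10, duration_days=120)
        phen = crop.calibrate_development_rates(wx, cal)
        res = simulate_season(wx, 2000, cal, "irrigated", phenology=phen)
        assert res.died
        assert res.yield_mgha == 0.0

    def test_water_limitation_dominance(self, monsoon_weather, phen):
        args = (monsoon_weather, 2003, self.CAL)
        irr = simulate_season(*args, "irrigated", phenology=phen)
        low = simulate_season(*args, "rainfed_lowland", phenology=phen)
        up = simulate_season(*args, "rainfed_upland", phenology=phen)
        assert low.yield_mgha <= irr.yield_mgha
        assert up.yield_mgha <= irr.yield_mgha

    def test_groundwater_monotonicity(self, monsoon_weather, phen):
        yields = []
        for gw in (40.0, 100.0, 1000.0):
            soil = SoilProfile.rainfed_lowland(groundwater_depth_cm=gw)
            series = crop.simulate_multi_year(monsoon_weather, self.CAL,
                                              "rainfed_lowland", phenology=phen,
                                              soil=soil)
            yields.append(series.yields.mean())
        assert yields[0] >= yields[1] >= yields[2]

    def test_precipitation_monotonicity(self, monsoon_weather, phen):
        means = []
        for k in (1.0, 0.5, 0.0):
            wx = monsoon_weather.copy()
            wx["precip"] = wx["precip"] * k
            series = crop.simulate_multi_year(wx, self.CAL, "rainfed_upland",
                                              phenology=phen)
            means.append(series.yields.mean())
        assert means[0] >= means[1] >= means[2]

    def test_yield_within_harvest_index_ceiling(self, monsoon_weather, phen):
        canopy = CanopyParams()
        for year in (2001, 2005, 2010):
            res = simulate_season(monsoon_weather, year, self.CAL, "irrigated",
                                  phenology=phen)
            ceiling = res.biomass_mgha * canopy.harvest_index_ceiling / 0.86
            assert 0.0 <= res.yield_mgha <= ceiling

    def test_unknown_regime_rejected(self, monsoon_weather, phen):
        with pytest.raises(ParameterError):
            simulate_season(monsoon_weather, 2001, self.CAL, "flooded",
                            phenology=phen)


class TestMultiYear:
    def test_identical_years_identical_yields(self, make_weather):
        one_year = dict(tmax=29.0, tmin=19.0, srad=18.0, precip=0.0)
        wx = make_weather(days=3 * 365, start="2001-01-01", **one_year)
        cal = CropCalendar(sowing_doy=20, duration_days=120)
        phen = crop.calibrate_development_rates(wx, cal)
        series = crop.simulate_multi_year(wx, cal, "irrigated", phenology=phen)
        assert len(set(np.round(series.yields, 12))) == 1

    def test_lowland_blend_is_mean_of_scenarios(self, monsoon_weather):
        cal = CropCalendar(sowing_doy=165, duration_days=125)
        phen = crop.calibrate_development_rates(monsoon_weather, cal)
        s = crop.simulate_multi_year(monsoon_weather, cal, "rainfed_lowland",
                                     phenology=phen)
        np.testing.assert_allclose(
            s.yields, 0.5 * (s.components["gw40"] + s.components["gw100"]))

    def test_upland_more_variable_than_irrigated(self, monsoon_weather):
        cal = CropCalendar(sowing_doy=165, duration_days=125)
        phen = crop.calibrate_development_rates(monsoon_weather, cal)
        irr = crop.simulate_multi_year(monsoon_weather, cal, "irrigated",
                                       phenology=phen)
        up = crop.simulate_multi_year(monsoon_weather, cal, "rainfed_upland",
                                      phenology=phen)
        cv = lambda x: x.std(ddof=1) / x.mean()  # noqa: E731
        assert cv(up.yields) > cv(irr.yields)
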