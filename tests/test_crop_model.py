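import datetime as dt

import numpy as np
import pytest

from topdress.crop_model import (
    CultivarParams,
    FertilizationEvent,
    ManagementPlan,
    SoilInit,
    Stage,
    WeatherDay,
    WeatherSeries,
    daylength_hours,
    extraterrestrial_radiation,
    growing_degree_days,
    simulate_season,
    solar_radiation_angstrom,
)
from topdress import synthetic as syn


class TestGrowingDegreeDays:
    def test_direct_arithmetic(self):
        assert growing_degree_days(20, 10, 0) == 15

    def test_mean_equals_base(self):
        assert growing_degree_days(5, 5, 5) == 0

    def test_clamped_at_zero(self):
        assert growing_degree_days(2, -6, 0) == 0

    def test_tmax_below_tmin_raises(self):
        with pytest.raises(ValueError):
            growing_degree_days(5, 10, 0)


class TestAngstrom:
    def test_full_sunshine_limit(self):
        assert solar_radiation_angstrom(12, 12, 30.0) == pytest.approx(0.75 * 30.0)

    def test_overcast_limit(self):
        assert solar_radiation_angstrom(0, 12, 30.0) == pytest.approx(0.25 * 30.0)

    def test_zero_extraterrestrial(self):
        assert solar_radiation_angstrom(6, 12, 0.0, 0.3, 0.6) == 0.0

    def test_sunshine_exceeding_daylength_raises(self):
        with pytest.raises(ValueError):
            solar_radiation_angstrom(13, 12, 30.0)

    def test_solar_geometry_sane(self):
        # equinox daylength ~12 h everywhere; midsummer longer at 40N
        assert daylength_hours(80, 40.0) == pytest.approx(12.0, abs=0.3)
        assert daylength_hours(172, 40.0) > 14.0
        assert 0 < extraterrestrial_radiation(172, 40.0) < 45.0


def _constant_weather(start, n_days, tmax=20.0, tmin=10.0, srad=15.0):
    days = [
        WeatherDay(start + dt.timedelta(days=i), tmax, tmin, 0.0, srad=srad)
        for i in range(n_days)
    ]
    return WeatherSeries(days, latitude=39.5)


class TestWeatherTypes:
    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(ValueError):
            WeatherDay(dt.date(2021, 3, 1), 5.0, 10.0, 0.0, srad=15.0)

    def test_negative_precip_rejected(self):
        with pytest.raises(ValueError):
            WeatherDay(dt.date(2021, 3, 1), 15.0, 10.0, -1.0, srad=15.0)

    def test_gap_detected(self):
        a = WeatherDay(dt.date(2021, 3, 1), 15.0, 10.0, 0.0, srad=15.0)
        b = WeatherDay(dt.date(2021, 3, 3), 15.0, 10.0, 0.0, srad=15.0)
        with pytest.raises(ValueError, match="gap"):
            WeatherSeries([a, b])

    def test_soil_water_exceeding_capacity_rejected(self):
        with pytest.raises(ValueError):
            SoilInit(water_holding_capacity=100.0, initial_water=120.0)


class TestSimulateSeason:
    def test_cumulative_gdd_direct_arithmetic(self):
        w = _constant_weather(dt.date(2021, 3, 1), 100)
        mgmt = ManagementPlan(sowing_date=dt.date(2021, 3, 1))
        sim = simulate_season(w, SoilInit(), mgmt)
        assert sim.daily_gdd[-1] == pytest.approx(1500.0)

    def test_monotone_n_response(self, weather, soil, sowing_date):
        y = []
        for n in (0.0, 270.0):
            mgmt = syn.default_management(sowing_date, n)
            y.append(simulate_season(weather, soil, mgmt).yield_t_ha)
        assert y[0] <= y[1]

    def test_deterministic_bit_identical(self, weather, soil, mgmt):
        a = simulate_season(weather, soil, mgmt)
        b = simulate_season(weather, soil, mgmt)
        assert np.array_equal(a.daily_agb, b.daily_agb)
        assert np.array_equal(a.daily_gdd, b.daily_gdd)
        assert np.array_equal(a.daily_stage, b.daily_stage)
        assert a.yield_t_ha == b.yield_t_ha

    def test_trajectory_invariants(self, truth_sim):
        sim = truth_sim
        assert np.all(np.diff(sim.daily_agb) >= -1e-12)
        assert np.all(np.diff(sim.daily_gdd) >= 0)
        assert 0 <= sim.yield_t_ha <= sim.final_agb
        assert np.all((sim.n_stress >= 0) & (sim.n_stress <= 1))
        assert np.all((sim.water_stress >= 0) & (sim.water_stress <= 1))

    def test_stage_progression(self, truth_sim):
        stages = truth_sim.daily_stage
        assert np.all(np.diff(stages) >= 0)
        assert stages[0] == int(Stage.SOWN)
        assert stages[-1] == int(Stage.MATURE)
        d = truth_sim.stage_dates
        assert d["emergence"] < d["jointing"] < d["anthesis"] < d["maturity"]

    def test_n_conservation(self, weather, soil, sowing_date):
        mgmt = syn.default_management(sowing_date, 180.0)
        sim = simulate_season(weather, soil, mgmt)
        assert sim.n_uptake_kg_ha <= soil.mineral_n_kg_ha + mgmt.total_fertilization + 1e-9

    def test_stress_free_limit(self, weather, sowing_date):
        rich = SoilInit(
            no3_n=500.0, nh4_n=500.0,
            water_holding_capacity=5000.0, initial_water=5000.0,
        )
        mgmt = syn.default_management(sowing_date, 0.0).scaled_irrigation(240.0)
        sim = simulate_season(weather, rich, mgmt)
        growing = (sim.daily_stage >= int(Stage.EMERGED)) & (sim.daily_stage < int(Stage.MATURE))
        assert np.all(sim.n_stress[growing] == 1.0)
        assert np.all(sim.water_stress[growing] == 1.0)

    def test_out_of_range_cultivar_raises_in_direct_mode(self, weather, soil, mgmt):
        bad = CultivarParams(p1d=200.0)
        with pytest.raises(ValueError, match="p1d"):
            simulate_season(weather, soil, mgmt, bad)

    def test_out_of_range_cultivar_clamped_in_assimilation_mode(self, weather, soil, mgmt):
        bad = CultivarParams(p1d=200.0)
        sim = simulate_season(weather, soil, mgmt, bad, clamp_params=True)
        ref = simulate_season(weather, soil, mgmt, CultivarParams(p1d=70.0))
        assert sim.yield_t_ha == ref.yield_t_ha

    def test_sowing_outside_weather_raises(self, weather, soil):
        mgmt = ManagementPlan(sowing_date=dt.date(1999, 1, 1))
        with pytest.raises(ValueError, match="sowing"):
            simulate_season(weather, soil, mgmt)

    def test_season_too_short_for_jointing_raises(self):
        w = _constant_weather(dt.date(2021, 3, 1), 20)
        with pytest.raises(ValueError, match="jointing"):
            simulate_season(w, SoilInit(), ManagementPlan(sowing_date=dt.date(2021, 3, 1)))

    def test_higher_slpf_grows_more(self, weather, soil, mgmt):
        lo = simulate_season(weather, soil, mgmt, CultivarParams(slpf=0.8))
        hi = simulate_season(weather, soil, mgmt, CultivarParams(slpf=1.0))
        assert hi.final_agb > lo.final_agb


class TestManagementPlan:
    def test_scaled_fertilization_preserves_split(self, sowing_date):
        mgmt = syn.default_management(sowing_date, 200.0)
        scaled = mgmt.scaled_fertilization(100.0)
        assert scaled.total_fertilization == pytest.approx(100.0)
        fracs = [e.amount_kg_ha / 100.0 for e in scaled.fertilization_events]
        orig = [e.amount_kg_ha / 200.0 for e in mgmt.fertilization_events]
        assert fracs == pytest.approx(orig)

    def test_scaled_from_zero_creates_event(self, sowing_date):
        mgmt = ManagementPlan(sowing_date=sowing_date)
        scaled = mgmt.scaled_fertilization(50.0)
        assert scaled.total_fertilization == pytest.approx(50.0)

    def test_with_topdressing_replaces_flagged_events(self, sowing_date):
        mgmt = syn.default_management(sowing_date, 200.0)
        new = mgmt.with_topdressing(40.0, sowing_date + dt.timedelta(days=180))
        tops = [e for e in new.fertilization_events if e.topdress]
        assert len(tops) == 1 and tops[0].amount_kg_ha == 40.0
        basal_before = sum(e.amount_kg_ha for e in mgmt.fertilization_events if not e.topdress)
        basal_after = sum(e.amount_kg_ha for e in new.fertilization_events if not e.topdress)
        assert basal_after == pytest.approx(basal_before)

    def test_negative_event_rejected(self, sowing_date):
        with pytest.raises(ValueError):
            FertilizationEvent(sowing_date, -5.0)


def test_yield_monotone_saturating_on_grid(weather, soil, sowing_date):
    """Non-decreasing yield with non-increasing marginal gains past the
    inflection over the 0-360 topdress grid (economics well-posedness)."""
    mgmt = syn.default_management(sowing_date, 90.0)
    probe = simulate_season(weather, soil, mgmt)
    ys = []
    for n in np.arange(0.0, 361.0, 10.0):
        plan = mgmt.with_topdressing(float(n), probe.jointing_date)
        ys.append(simulate_season(weather, soil, plan).yield_t_ha)
    d = np.diff(ys)
    assert np.all(d >= -1e-12)
    k = int(np.argmax(d))
    assert np.all(np.diff(d[k:]) <= 1e-9)
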