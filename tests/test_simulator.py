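"""Unit and property tests for the daily growth engine."""
import math

import numpy as np
import pytest

from ddcrop.errors import InvalidInputError, MissingDataError
from ddcrop.simulator import (
    advance_phenology,
    daily_biomass,
    growing_degree_days,
    intercepted_fraction,
    maintenance_respiration,
    partition,
    simulate_season,
    soil_water_step,
    stress_factors,
    vapor_pressure_deficit,
    water_uptake,
)
from ddcrop.synth import SynthConfig, WeatherParams, generate_weather
from ddcrop.types import CropState, Genotype, Management, SoilParams, SoilProfile, Stage

from conftest import make_constant_weather


@pytest.mark.parametrize("tmax,tmin,tbase,tcap,expected", [
    (30, 20, 10, 30, 15.0),   # plain mean minus base
    (10, 5, 10, 30, 0.0),     # at/below base
    (40, 30, 10, 30, 20.0),   # both clipped to the cap
    (25, 5, 10, 30, 7.5),     # only tmin clipped
])
def test_growing_degree_days(tmax, tmin, tbase, tcap, expected):
    assert growing_degree_days(tmax, tmin, tbase, tcap) == pytest.approx(expected)


def test_growing_degree_days_rejects_inverted_extremes():
    with pytest.raises(InvalidInputError):
        growing_degree_days(10, 20, 10, 30)


class TestVPD:
    def test_isothermal_day_matches_tetens_by_hand(self):
        # es(20 degC) = 0.6108 * exp(17.27*20/257.3) ~ 2.339 kPa
        assert vapor_pressure_deficit(20, 20, 1.0) == pytest.approx(1.339, abs=1e-3)

    def test_saturated_air_gives_zero(self):
        es20 = 0.6108 * math.exp(17.27 * 20 / 257.3)
        assert vapor_pressure_deficit(20, 20, es20) == pytest.approx(0.0, abs=1e-12)

    def test_supersaturated_air_clamps_to_zero(self):
        assert vapor_pressure_deficit(20, 20, 5.0) == 0.0


class TestInterception:
    def test_bare_ground_intercepts_nothing(self):
        assert intercepted_fraction(0.0, 0.6) == 0.0

    def test_beer_lambert_value(self):
        assert intercepted_fraction(3.0, 0.6) == pytest.approx(1 - math.exp(-1.8))

    @pytest.mark.parametrize("k", [0.3, 0.6, 0.9])
    def test_monotone_in_lai_and_proportional_at_low_lai(self, k):
        assert intercepted_fraction(2.0, k) < intercepted_fraction(4.0, k)
        assert intercepted_fraction(0.01, k) == pytest.approx(0.01 * k, rel=0.01)


class TestWaterUptake:
    def _geno(self, u_max=0.05):
        return Genotype(800, 1500, 3.0, 9.0, 0.022, 0.45, 0.06, u_max, 34.0)

    def test_no_roots_no_uptake(self):
        state = CropState(soil_water=50.0, root_mass=0.0)
        uptake, drought = water_uptake(state, 2.0, self._geno(), 100.0, 0.133)
        assert uptake == 0.0 and drought == 1.0

    def test_soil_at_wilting_blocks_uptake(self):
        state = CropState(soil_water=10.0, root_mass=10.0)  # wilting = 0.1*100
        uptake, drought = water_uptake(state, 2.0, self._geno(), 100.0, 0.133)
        assert uptake == 0.0 and drought == 0.0

    def test_demand_driven_uptake_with_ample_water(self):
        state = CropState(soil_water=90.0, root_mass=10.0)
        uptake, drought = water_uptake(state, 2.0, self._geno(u_max=0.05), 100.0, 1.0)
        assert uptake == pytest.approx(0.05 * 10 * 2)  # 1.0 L
        assert drought == 1.0


class TestSoilWaterStep:
    SP = SoilParams(sw_cap_scale=1.0, runoff_coeff=0.2, evap_coeff=1.0)

    def test_quiescent_soil_is_unchanged(self):
        state = CropState(soil_water=50.0)
        new, runoff, evap = soil_water_step(state, 0.0, 0.0, 0.0, 0.0, self.SP, 100.0)
        assert (new, runoff, evap) == (50.0, 0.0, 0.0)

    def test_saturation_overflow_goes_to_runoff(self):
        state = CropState(soil_water=95.0)
        new, runoff, evap = soil_water_step(state, 50.0, 0.0, 0.0, 1.0, self.SP, 100.0)
        assert new == 100.0
        assert runoff == pytest.approx(0.2 * 50 + (95 + 40 - 100))

    def test_hand_bookkeeping(self):
        # old 50, rain 10 (runoff 2), uptake 3, demand/cover chosen so evap = 1
        state = CropState(soil_water=50.0)
        sp = SoilParams(sw_cap_scale=1.0, runoff_coeff=0.2, evap_coeff=1.0)
        new, runoff, evap = soil_water_step(state, 10.0, 3.0, 2.0, 0.0, sp, 100.0)
        assert evap == pytest.approx(1.0 * 2.0 * 1.0 * 0.5)
        assert new == pytest.approx(50 + 10 - 2 - 3 - 1)


class TestStress:
    G = Genotype(800, 1500, 3.0, 9.0, 0.022, 0.45, 0.06, 0.055, 34.0)

    def test_benign_day_is_stress_free(self):
        state = CropState()
        assert stress_factors(state, 30.0, 1.0, self.G) == (1.0, 1.0)

    def test_heat_ramp_endpoint_and_midpoint(self):
        state = CropState()
        heat_end, _ = stress_factors(state, 44.0, 1.0, self.G, heat_span=10.0)
        heat_mid, _ = stress_factors(state, 39.0, 1.0, self.G, heat_span=10.0)
        assert heat_end == 0.0
        assert heat_mid == pytest.approx(0.5)

    def test_flood_penalty_after_saturated_spell(self):
        state = CropState(consecutive_saturated_days=3)
        _, flood = stress_factors(state, 20.0, 1.0, self.G,
                                  flood_threshold_days=3, flood_penalty=0.5)
        assert flood == 0.5


class TestDailyBiomass:
    G = Genotype(800, 1500, 3.0, 9.0, 0.022, 0.45, 0.06, 0.055, 34.0)

    def test_no_radiation_no_growth(self):
        assert daily_biomass(0.0, 0.5, 1.0, 1.5, (1, 1, 1), self.G, 0.12) == 0.0

    def test_no_water_no_growth(self):
        assert daily_biomass(20.0, 0.5, 0.0, 1.5, (1, 1, 1), self.G, 0.12) == 0.0

    def test_min_of_both_branches_by_hand(self):
        # radiation: 3*0.5*20*0.12 = 3.6 ; water: 9*1.2/1.5 = 7.2
        got = daily_biomass(20.0, 0.5, 1.2, 1.5, (1.0, 1.0, 1.0), self.G, 0.12)
        assert got == pytest.approx(3.6)


class TestRespiration:
    def test_no_mass_no_respiration(self):
        assert maintenance_respiration(0.0, 25.0, 0.01, 2.0) == 0.0

    def test_reference_temperature(self):
        assert maintenance_respiration(100.0, 20.0, 0.01, 2.0) == pytest.approx(1.0)

    def test_q10_doubling(self):
        assert maintenance_respiration(100.0, 30.0, 0.01, 2.0) == pytest.approx(2.0)


class TestPartition:
    G = Genotype(800, 1500, 3.0, 9.0, 0.022, 0.4, 0.2, 0.055, 34.0)

    def test_vegetative_split(self):
        assert partition(10.0, Stage.VEGETATIVE, self.G) == pytest.approx((4.0, 2.0, 4.0, 0.0))

    def test_reproductive_all_to_grain(self):
        assert partition(5.0, Stage.REPRODUCTIVE, self.G) == (0.0, 0.0, 0.0, 5.0)

    def test_mature_is_inert(self):
        assert partition(5.0, Stage.MATURE, self.G) == (0.0, 0.0, 0.0, 0.0)

    def test_loss_debits_stem_then_leaf_never_grain(self):
        state = CropState(leaf_mass=5.0, stem_mass=2.0, grain_mass=10.0)
        d = partition(-4.0, Stage.REPRODUCTIVE, self.G, state)
        assert d == (-2.0, 0.0, -2.0, 0.0)

    def test_loss_never_drives_pools_negative(self):
        state = CropState(leaf_mass=1.0, stem_mass=0.5)
        d_leaf, d_root, d_stem, d_grain = partition(-10.0, Stage.VEGETATIVE, self.G, state)
        assert d_stem == -0.5 and d_leaf == -1.0
        assert d_root == 0.0 and d_grain == 0.0


class TestPhenology:
    G = Genotype(800, 1600, 3.0, 9.0, 0.022, 0.45, 0.06, 0.055, 34.0)

    def test_threshold_crossing_flips_stage(self):
        state = CropState(cum_gdd=799.0)
        advance_phenology(state, 2.0, self.G)
        assert state.stage is Stage.REPRODUCTIVE

    def test_zero_gdd_never_transitions(self):
        state = CropState()
        for _ in range(100):
            advance_phenology(state, 0.0, self.G)
        assert state.stage is Stage.VEGETATIVE

    def test_constant_gdd_transition_day(self):
        state = CropState()
        days = 0
        while state.stage is Stage.VEGETATIVE:
            advance_phenology(state, 16.0, self.G)
            days += 1
        assert days == 50  # 800 / 16


# ---------------------------------------------------------------------------
# season-level behaviour

def _toy_inputs(**weather_kwargs):
    weather = make_constant_weather(160, **weather_kwargs)
    management = Management(plant_doy=1, harvest_doy=160, density=75_000.0, area=100.0)
    soil = SoilProfile(capacity_mm=250.0, init_fraction=0.85)
    g = Genotype(800, 1500, 3.0, 9.0, 0.022, 0.45, 0.06, 0.055, 34.0)
    sp = SoilParams(1.0, 0.2, 1.0)
    return weather, management, soil, g, sp


def test_dark_season_yields_nothing():
    w, m, soil, g, sp = _toy_inputs(srad=0.0, prcp=3.0)
    assert simulate_season(w, m, soil, g, sp) == 0.0


def test_dry_season_with_empty_soil_yields_nothing():
    w, m, soil, g, sp = _toy_inputs(prcp=0.0)
    soil = SoilProfile(capacity_mm=250.0, init_fraction=0.0)
    assert simulate_season(w, m, soil, g, sp) == 0.0


def test_weather_gap_raises():
    w, m, soil, g, sp = _toy_inputs()
    m = Management(plant_doy=100, harvest_doy=200, density=75_000.0, area=1.0)
    with pytest.raises(MissingDataError):
        simulate_season(w, m, soil, g, sp)


def test_determinism_bit_identical(noisy_dataset):
    key = noisy_dataset.keys()[0]
    args = (noisy_dataset.weather[key], noisy_dataset.management[key],
            noisy_dataset.soil[key[1]], noisy_dataset.true_genotypes[key],
            noisy_dataset.true_soil_params[key[1]])
    assert simulate_season(*args) == simulate_season(*args)


def test_genotype_transfers_across_environments(noisy_dataset):
    """The same genotype value runs under any weather without re-specification."""
    g = noisy_dataset.true_genotypes[noisy_dataset.keys()[0]]
    for key in noisy_dataset.keys()[:5]:
        y = simulate_season(
            noisy_dataset.weather[key], noisy_dataset.management[key],
            noisy_dataset.soil[key[1]], g, noisy_dataset.true_soil_params[key[1]],
        )
        assert y >= 0.0


def test_more_radiation_never_hurts(clean_dataset):
    for key in clean_dataset.keys()[:4]:
        w = clean_dataset.weather[key]
        brighter = type(w)(w.doy, w.tmax, w.tmin, w.prcp, w.srad * 1.1, w.vp)
        base = simulate_season(w, clean_dataset.management[key],
                               clean_dataset.soil[key[1]],
                               clean_dataset.true_genotypes[key],
                               clean_dataset.true_soil_params[key[1]])
        brighter_y = simulate_season(brighter, clean_dataset.management[key],
                                     clean_dataset.soil[key[1]],
                                     clean_dataset.true_genotypes[key],
                                     clean_dataset.true_soil_params[key[1]])
        assert brighter_y >= base - 1e-12


def test_removing_rain_never_helps(clean_dataset):
    for key in clean_dataset.keys()[:4]:
        w = clean_dataset.weather[key]
        dry = type(w)(w.doy, w.tmax, w.tmin, np.zeros_like(w.prcp), w.srad, w.vp)
        base = simulate_season(w, clean_dataset.management[key],
                               clean_dataset.soil[key[1]],
                               clean_dataset.true_genotypes[key],
                               clean_dataset.true_soil_params[key[1]])
        dry_y = simulate_season(dry, clean_dataset.management[key],
                                clean_dataset.soil[key[1]],
                                clean_dataset.true_genotypes[key],
                                clean_dataset.true_soil_params[key[1]])
        assert dry_y <= base + 1e-12


def test_water_and_mass_conservation_over_random_seasons(default_soil_params):
    """Water balance closes exactly and grain never shrinks, across many
    randomly drawn synthetic seasons."""
    n_checked = 0
    for seed in range(40):
        cfg = SynthConfig(n_counties=2, years=(2001, 2002), rng_seed=seed,
                          weather=WeatherParams(wet_prob=0.2 + 0.02 * (seed % 10)))
        for year in (2001, 2002):
            for county in (0, 1):
                w = generate_weather(cfg, year, county)
                m = Management(plant_doy=120, harvest_doy=280,
                               density=75_000.0, area=1.0)
                soil = SoilProfile(capacity_mm=150.0 + 10 * (seed % 7),
                                   init_fraction=0.8)
                g = Genotype(700 + 10 * (seed % 5), 1500, 3.0, 9.0, 0.022,
                             0.45, 0.06, 0.04 + 0.002 * (seed % 8), 34.0)
                res = simulate_season(w, m, soil, g, default_soil_params,
                                      return_result=True, collect_trace=True)
                assert abs(res.water_balance_residual()) <= 1e-8
                grain = res.trace["grain"].to_numpy()
                assert np.all(np.diff(grain) >= 0)
                assert res.final_state.soil_water >= 0
                n_checked += 1
    assert n_checked == 160


def test_mass_conservation_totals(toy_season):
    w, m, soil, g, sp, constants = toy_season
    res = simulate_season(w, m, soil, g, sp, constants=constants,
                          return_result=True)
    seed_mass = constants.seed_leaf + constants.seed_root + constants.seed_stem
    expected = seed_mass + res.totals["net_gain"] - res.totals["debits"]
    assert res.final_state.total_mass == pytest.approx(expected, abs=1e-10)


def test_five_day_toy_season_matches_hand_stepped_oracle(toy_season):
    """Step the 5-day toy season through every equation by hand (independent
    straight-line arithmetic) and compare yields to 1e-6 Mg/ha."""
    from oracles import hand_stepped_toy_yield

    w, m, soil, g, sp, c = toy_season
    expected = hand_stepped_toy_yield(w, m, soil, g, sp, c)
    got = simulate_season(w, m, soil, g, sp, constants=c)
    assert got == pytest.approx(expected, abs=1e-6)
    assert got > 0  # the toy reaches grain fill on day 2
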