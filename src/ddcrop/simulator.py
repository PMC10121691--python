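"""Daily-time-step maize growth engine.

The season is advanced one day at a time from planting to the earlier of
harvest and physiological maturity.  Each day:

1. thermal time accumulates and may trigger a one-way stage transition
   (vegetative -> reproductive -> mature);
2. roots extract soil water in proportion to root mass and atmospheric
   vapour-pressure deficit, limited by the water available above wilting;
3. the soil bucket is updated by rain, runoff, uptake and soil evaporation;
4. heat and flooding stress factors are evaluated;
5. gross growth is the minimum of a radiation-limited branch
   (RUE x intercepted radiation, discounted by stress) and a water-limited
   branch (transpiration efficiency x uptake / VPD);
6. maintenance respiration (Q10 form) is debited;
7. the net gain is partitioned to leaf/root/stem in the vegetative stage and
   entirely to grain during grain fill.

Grain mass at season end times stand density gives yield in Mg/ha.  The
engine is deterministic and conserves water and biomass exactly (to float
round-off); see the per-day trace for an audit trail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InternalConsistencyError, InvalidInputError
from .params import DEFAULT_CONSTANTS, SimConstants
from .types import (
    CropState,
    Genotype,
    Management,
    SoilParams,
    SoilProfile,
    Stage,
    WeatherSeries,
)

__all__ = [
    "growing_degree_days",
    "saturation_vapor_pressure",
    "vapor_pressure_deficit",
    "intercepted_fraction",
    "water_uptake",
    "soil_water_step",
    "stress_factors",
    "daily_biomass",
    "maintenance_respiration",
    "partition",
    "advance_phenology",
    "simulate_season",
    "SeasonResult",
]


def growing_degree_days(tmax: float, tmin: float, tbase: float, tcap: float) -> float:
    """Daily thermal time: mean of [tbase, tcap]-clipped extremes minus tbase."""
    if tmax < tmin:
        raise InvalidInputError("tmax < tmin")
    if tcap <= tbase:
        raise InvalidInputError("tcap must exceed tbase")
    hi = min(max(tmax, tbase), tcap)
    lo = min(max(tmin, tbase), tcap)
    return max(0.0, 0.5 * (hi + lo) - tbase)


def saturation_vapor_pressure(t: float) -> float:
    """Tetens saturation vapour pressure (kPa) over water at t degC."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def vapor_pressure_deficit(tmax: float, tmin: float, ea: float) -> float:
    """Daytime VPD: mean saturation pressure at the extremes minus ambient ea."""
    if tmax < tmin:
        raise InvalidInputError("tmax < tmin")
    if ea <= 0:
        raise InvalidInputError("ambient vapour pressure must be > 0")
    es = 0.5 * (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin))
    return max(0.0, es - ea)


def intercepted_fraction(lai: float, k: float) -> float:
    """Beer-Lambert fraction of incident radiation intercepted by the canopy."""
    if lai < 0:
        raise InvalidInputError("LAI must be >= 0")
    if k <= 0:
        raise InvalidInputError("extinction coefficient must be > 0")
    return 1.0 - math.exp(-k * lai)


def water_uptake(
    state: CropState,
    vpd: float,
    g: Genotype,
    effective_capacity: float,
    plant_area: float,
    wilting_fraction: float = DEFAULT_CONSTANTS.wilting_fraction,
) -> tuple[float, float]:
    """Root water uptake (L/plant) and the drought factor (actual/potential).

    Potential uptake is u_max * root_mass * VPD; actual uptake cannot exceed
    the water stored above the wilting level, converted to litres per plant
    via the ground area per plant (1 mm over 1 m2 = 1 L).
    """
    if vpd < 0:
        raise InvalidInputError("VPD must be >= 0")
    u_pot = g.u_max * state.root_mass * vpd
    if u_pot <= 0.0:
        return 0.0, 1.0
    available_mm = max(0.0, state.soil_water - wilting_fraction * effective_capacity)
    uptake = min(u_pot, available_mm * plant_area)
    return uptake, uptake / u_pot


def soil_water_step(
    state: CropState,
    prcp: float,
    uptake_mm: float,
    evap_demand: float,
    cover: float,
    s: SoilParams,
    capacity: float,
) -> tuple[float, float, float]:
    """One day of the soil-water bucket.

    Returns (new soil water, runoff, evaporation), all mm, satisfying the
    exact balance  new = old + prcp - runoff - uptake_mm - evaporation.
    Runoff is a fixed fraction of rainfall plus any overflow above capacity;
    bare-soil evaporation scales with atmospheric demand, exposed soil
    fraction and relative wetness.
    """
    if min(prcp, uptake_mm, evap_demand) < 0:
        raise InvalidInputError("fluxes must be >= 0")
    old = state.soil_water
    runoff = s.runoff_coeff * prcp
    after_uptake = old + prcp - runoff - uptake_mm
    evap = s.evap_coeff * evap_demand * (1.0 - cover) * (old / capacity)
    evap = min(evap, max(after_uptake, 0.0))
    new = after_uptake - evap
    if new > capacity:
        runoff += new - capacity
        new = capacity
    if new < 0.0:
        if new < -1e-9:
            raise InternalConsistencyError(f"negative soil water: {new}")
        # absorb float round-off into evaporation so the balance stays exact
        evap += new
        new = 0.0
    return new, runoff, evap


def stress_factors(
    state: CropState,
    tmax: float,
    drought_factor: float,
    g: Genotype,
    flood_threshold_days: int = DEFAULT_CONSTANTS.flood_threshold_days,
    heat_span: float = DEFAULT_CONSTANTS.heat_span,
    flood_penalty: float = DEFAULT_CONSTANTS.flood_penalty,
) -> tuple[float, float]:
    """Heat and flooding multipliers in [0, 1].

    Heat declines linearly from 1 at t_heat to 0 at t_heat + heat_span;
    flooding applies a flat penalty after the soil has sat at saturation for
    flood_threshold_days consecutive days.
    """
    heat = min(1.0, max(0.0, 1.0 - (tmax - g.t_heat) / heat_span))
    flood = (
        flood_penalty
        if state.consecutive_saturated_days >= flood_threshold_days
        else 1.0
    )
    return heat, flood


def daily_biomass(
    srad: float,
    f_int: float,
    uptake: float,
    vpd: float,
    stresses: tuple[float, float, float],
    g: Genotype,
    plant_area: float,
    vpd_floor: float = DEFAULT_CONSTANTS.vpd_floor,
) -> float:
    """Gross daily growth (g/plant): min of radiation- and water-limited branches.

    stresses = (heat, drought, flood) multipliers applied to the radiation
    branch; the water branch is already limited through the uptake itself.
    """
    heat, drought, flood = stresses
    radiation_limited = g.rue * f_int * srad * plant_area * heat * flood * drought
    water_limited = g.te * uptake / max(vpd, vpd_floor)
    return max(0.0, min(radiation_limited, water_limited))


def maintenance_respiration(
    total_mass: float,
    tavg: float,
    m0: float = DEFAULT_CONSTANTS.m0,
    q10: float = DEFAULT_CONSTANTS.q10,
) -> float:
    """Q10 maintenance respiration (g/plant/day), referenced to 20 degC."""
    if total_mass < 0:
        raise InvalidInputError("total mass must be >= 0")
    return m0 * total_mass * q10 ** ((tavg - 20.0) / 10.0)


def partition(
    net_gain: float,
    stage: Stage,
    g: Genotype,
    state: CropState | None = None,
) -> tuple[float, float, float, float]:
    """Allocate the day's net gain to (leaf, root, stem, grain) increments.

    Vegetative growth splits by (p_leaf, p_root, remainder); grain fill
    routes everything to grain; at maturity nothing moves.  A net loss is
    debited from stem first, then leaf, never from grain or root, and pools
    never go negative (pool sizes are taken from ``state`` when given).
    """
    if net_gain >= 0.0:
        if stage is Stage.VEGETATIVE:
            leaf = g.p_leaf * net_gain
            root = g.p_root * net_gain
            return leaf, root, net_gain - leaf - root, 0.0
        if stage is Stage.REPRODUCTIVE:
            return 0.0, 0.0, 0.0, net_gain
        return 0.0, 0.0, 0.0, 0.0
    if stage is Stage.MATURE:
        return 0.0, 0.0, 0.0, 0.0
    deficit = -net_gain
    stem_pool = state.stem_mass if state is not None else math.inf
    leaf_pool = state.leaf_mass if state is not None else math.inf
    stem_debit = min(stem_pool, deficit)
    leaf_debit = min(leaf_pool, deficit - stem_debit)
    return -leaf_debit, 0.0, -stem_debit, 0.0


def advance_phenology(state: CropState, gdd_today: float, g: Genotype) -> CropState:
    """Accumulate thermal time and apply one-way stage transitions in place."""
    if gdd_today < 0:
        raise InvalidInputError("daily GDD must be >= 0")
    state.cum_gdd += gdd_today
    if state.stage is Stage.VEGETATIVE and state.cum_gdd >= g.gdd_flower:
        state.stage = Stage.REPRODUCTIVE
    if state.stage is Stage.REPRODUCTIVE and state.cum_gdd >= g.gdd_mature:
        state.stage = Stage.MATURE
    return state


@dataclass
class SeasonResult:
    """Season outcome plus conservation totals and an optional daily trace."""

    yield_mg_ha: float
    final_state: CropState
    initial_soil_water: float
    totals: dict[str, float] = field(default_factory=dict)
    trace: pd.DataFrame | None = None

    def water_balance_residual(self) -> float:
        """(final - initial soil water) - sum(prcp - runoff - uptake - evap)."""
        t = self.totals
        flux = t["prcp"] - t["runoff"] - t["uptake_mm"] - t["evaporation"]
        return (self.final_state.soil_water - self.initial_soil_water) - flux


def simulate_season(
    w: WeatherSeries,
    m: Management,
    soil: SoilProfile,
    g: Genotype,
    s: SoilParams,
    constants: SimConstants = DEFAULT_CONSTANTS,
    irrigation: np.ndarray | None = None,
    return_result: bool = False,
    collect_trace: bool = False,
):
    """Run one county-year season and return grain yield in Mg/ha.

    The daily loop runs from plant_doy to min(harvest_doy, maturity); grain
    mass on the final day, scaled by stand density, is the yield.  Pass
    ``return_result=True`` for the full :class:`SeasonResult` (conservation
    totals, optional per-day trace via ``collect_trace``).  ``irrigation``
    is an optional array of added mm/day aligned with the season days
    (default: rainfed, all zeros).
    """
    season = w.window(m.plant_doy, m.harvest_doy)
    n_days = len(season)
    if irrigation is None:
        irr = [0.0] * n_days
    else:
        irr = [float(v) for v in irrigation]
        if len(irr) != n_days:
            raise InvalidInputError("irrigation array must match season length")

    eff_cap = soil.capacity_mm * s.sw_cap_scale
    plant_area = m.plant_area_m2
    state = CropState(
        soil_water=soil.init_fraction * eff_cap,
        leaf_mass=constants.seed_leaf,
        root_mass=constants.seed_root,
        stem_mass=constants.seed_stem,
    )
    init_sw = state.soil_water
    totals = {k: 0.0 for k in ("prcp", "runoff", "uptake_mm", "evaporation", "net_gain", "debits")}
    rows: list[dict] = []

    tmax_a, tmin_a = season.tmax, season.tmin
    prcp_a, srad_a, vp_a = season.prcp, season.srad, season.vp
    sat_level = constants.saturation_fraction * eff_cap

    for i in range(n_days):
        tmax, tmin = float(tmax_a[i]), float(tmin_a[i])
        prcp = float(prcp_a[i]) + irr[i]
        srad, ea = float(srad_a[i]), float(vp_a[i])

        gdd = growing_degree_days(tmax, tmin, constants.tbase, constants.tcap)
        advance_phenology(state, gdd, g)
        if state.stage is Stage.MATURE:
            break

        vpd = vapor_pressure_deficit(tmax, tmin, ea)
        lai = state.leaf_mass * g.sla / plant_area
        f_int = intercepted_fraction(lai, constants.k_ext)
        uptake, drought = water_uptake(
            state, vpd, g, eff_cap, plant_area, constants.wilting_fraction
        )
        uptake_mm = uptake / plant_area
        new_sw, runoff, evap = soil_water_step(
            state, prcp, uptake_mm, vpd, f_int, s, eff_cap
        )
        state.soil_water = new_sw
        if new_sw >= sat_level:
            state.consecutive_saturated_days += 1
        else:
            state.consecutive_saturated_days = 0

        heat, flood = stress_factors(
            state, tmax, drought, g,
            constants.flood_threshold_days, constants.heat_span,
            constants.flood_penalty,
        )
        gross = daily_biomass(
            srad, f_int, uptake, vpd, (heat, drought, flood), g, plant_area,
            constants.vpd_floor,
        )
        resp = maintenance_respiration(
            state.total_mass, 0.5 * (tmax + tmin), constants.m0, constants.q10
        )
        net = gross - resp
        d_leaf, d_root, d_stem, d_grain = partition(net, state.stage, g, state)
        state.leaf_mass += d_leaf
        state.root_mass += d_root
        state.stem_mass += d_stem
        state.grain_mass += d_grain

        totals["prcp"] += prcp
        totals["runoff"] += runoff
        totals["uptake_mm"] += uptake_mm
        totals["evaporation"] += evap
        applied = d_leaf + d_root + d_stem + d_grain
        if applied >= 0:
            totals["net_gain"] += applied
        else:
            totals["debits"] += -applied
        if collect_trace:
            rows.append({
                "doy": int(season.doy[i]), "stage": state.stage.value,
                "cum_gdd": state.cum_gdd, "soil_water": state.soil_water,
                "uptake_mm": uptake_mm, "runoff": runoff, "evaporation": evap,
                "lai": lai, "f_int": f_int, "vpd": vpd,
                "heat": heat, "drought": drought, "flood": flood,
                "gross": gross, "respiration": resp,
                "leaf": state.leaf_mass, "root": state.root_mass,
                "stem": state.stem_mass, "grain": state.grain_mass,
            })

    yield_mg_ha = state.grain_mass * m.density * 1e-6
    if yield_mg_ha < 0:
        raise InternalConsistencyError("negative yield")
    if not return_result:
        return yield_mg_ha
    return SeasonResult(
        yield_mg_ha=yield_mg_ha,
        final_state=state,
        initial_soil_water=init_sw,
        totals=totals,
        trace=pd.DataFrame(rows) if collect_trace else None,
    )
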