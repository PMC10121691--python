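"""Model constants and biological parameter bounds.

The calibrated vector is kept deliberately low-dimensional: everything that
is not plausibly a varietal (genotypic) trait or a county soil property is a
fixed constant collected in :class:`SimConstants`.  The genotype bounds below
are round numbers spanning the ranges reported for commercial dent maize in
the agronomy literature (e.g. RUE near 3 g/MJ intercepted, transpiration
efficiency coefficient near 9 Pa when expressed as biomass*VPD/water).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SimConstants:
    """Fixed (non-calibrated) constants of the daily growth engine.

    Attributes
    ----------
    tbase, tcap : float
        Base and ceiling temperatures (degC) for thermal-time accumulation.
    k_ext : float
        Canopy light extinction coefficient (Beer-Lambert).
    q10, m0 : float
        Maintenance respiration: rate ``m0`` (per day, at 20 degC) scaled by
        ``q10`` per 10 degC.
    vpd_floor : float
        Lower bound (kPa) on the VPD used in the water-limited growth branch,
        guarding against division blow-up on humid days.
    heat_span : float
        Width (degC) of the linear heat-stress ramp above the genotype's
        heat-stress onset temperature.
    flood_threshold_days, flood_penalty : int, float
        Consecutive days at soil saturation before flooding stress applies,
        and the multiplicative penalty once it does.
    wilting_fraction : float
        Fraction of effective capacity below which roots cannot extract water.
    saturation_fraction : float
        Fraction of effective capacity counted as "saturated" for flooding.
    seed_leaf, seed_root, seed_stem : float
        Initial organ masses (g/plant) at planting.
    """

    tbase: float = 10.0
    tcap: float = 30.0
    k_ext: float = 0.6
    q10: float = 2.0
    m0: float = 0.008
    vpd_floor: float = 0.1
    heat_span: float = 10.0
    flood_threshold_days: int = 3
    flood_penalty: float = 0.5
    wilting_fraction: float = 0.1
    saturation_fraction: float = 0.99
    seed_leaf: float = 0.5
    seed_root: float = 2.0
    seed_stem: float = 0.3


DEFAULT_CONSTANTS = SimConstants()

# Genotype component -> (lower, upper) biological bounds.  Units as in
# ddcrop.types.Genotype.
GENOTYPE_BOUNDS: dict[str, tuple[float, float]] = {
    "gdd_flower": (600.0, 1100.0),   # degC day to start of grain fill
    "gdd_mature": (1200.0, 2000.0),  # degC day to physiological maturity
    "rue": (1.5, 4.5),               # g biomass per MJ intercepted
    "te": (5.0, 14.0),               # g kPa per L transpired
    "sla": (0.012, 0.035),           # m2 leaf per g leaf
    "p_leaf": (0.2, 0.6),            # vegetative partition fraction to leaf
    "p_root": (0.03, 0.15),          # vegetative partition fraction to root
    "u_max": (0.02, 0.12),           # L per g root per kPa per day
    "t_heat": (30.0, 38.0),          # degC heat-stress onset
}

# Typical mid-range maize genotype used as the synthetic-data truth center.
DEFAULT_GENOTYPE_VALUES: dict[str, float] = {
    "gdd_flower": 800.0,
    "gdd_mature": 1500.0,
    "rue": 3.0,
    "te": 9.0,
    "sla": 0.022,
    "p_leaf": 0.45,
    "p_root": 0.06,
    "u_max": 0.055,
    "t_heat": 34.0,
}

SOIL_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "sw_cap_scale": (0.5, 2.0),      # multiplier on profile capacity
    "runoff_coeff": (0.05, 0.6),     # fraction of rainfall lost to runoff
    "evap_coeff": (0.2, 3.0),        # mm/day per kPa of demand, bare soil
}

DEFAULT_SOIL_PARAM_VALUES: dict[str, float] = {
    "sw_cap_scale": 1.0,
    "runoff_coeff": 0.2,
    "evap_coeff": 1.0,
}
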