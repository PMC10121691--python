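"""Seeded synthetic county-year data: weather, soil, management, genotypes.

The generator is a statistical twin of the public county-level sources the
model is designed for (county yield surveys, gridded daily weather, soil
survey water-holding summaries), built so the whole pipeline — calibration,
extrapolation, what-if analysis — runs with no download and with a known
ground truth:

* weather: sinusoidal seasonal temperature with Gaussian daily noise,
  Bernoulli wet days with exponential depths, a clear-sky radiation curve
  scaled by a uniform cloudiness factor, and vapour pressure from the
  dew-point ~ tmin approximation;
* counties: multiplicative offsets on soil capacity and rainfall plus planar
  centroid coordinates, so spatial extrapolation is non-trivial;
* genotypes: a mid-range maize genotype perturbed per county-year in log
  space (optionally with an upward "genetic gain" drift in RUE), then
  projected so the ratio-band constraints hold by construction;
* observed yields: the simulator's output under the true parameters plus
  additive Gaussian observation noise, floored at zero.

Everything is a pure function of the configuration, including its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import DEFAULT_RHO, project_to_feasible
from .errors import InvalidConfigError, InvalidInputError
from .params import (
    DEFAULT_GENOTYPE_VALUES,
    DEFAULT_SOIL_PARAM_VALUES,
    GENOTYPE_BOUNDS,
)
from .simulator import saturation_vapor_pressure, simulate_season
from .types import (
    Genotype,
    Key,
    Management,
    SoilParams,
    SoilProfile,
    SyntheticDataset,
    WeatherSeries,
)

__all__ = [
    "WeatherParams",
    "SynthConfig",
    "generate_weather",
    "generate_soil_profile",
    "generate_management",
    "generate_genotype_table",
    "generate_soil_params",
    "generate_dataset",
]

# Salt constants keep the per-purpose RNG streams independent.
_SALT_WEATHER, _SALT_COUNTY, _SALT_MGMT, _SALT_GENO, _SALT_NOISE, _SALT_SOILP = range(6)


@dataclass(frozen=True)
class WeatherParams:
    """Means/amplitudes/noise scales of the daily weather generator.

    Defaults approximate a humid central Corn Belt climatology: annual mean
    10 degC with a 15 degC seasonal swing peaking near late July, ~4 mm/day
    mean rainfall, midsummer clear-sky radiation near 28 MJ m-2 day-1.
    """

    t_mean_annual: float = 10.0   # degC
    t_amp: float = 15.0           # degC seasonal amplitude
    t_peak_doy: int = 205
    diurnal_range: float = 8.0    # degC tmax - tmin
    t_noise_sd: float = 2.0       # degC daily noise
    wet_prob: float = 0.35
    wet_mean_mm: float = 12.0     # mean depth on wet days
    srad_max: float = 28.0        # MJ m-2 day-1, clear-sky midsummer
    srad_min: float = 6.0         # clear-sky midwinter
    cloud_min: float = 0.55       # cloudiness factor ~ U(cloud_min, 1)

    @property
    def mean_daily_prcp(self) -> float:
        return self.wet_prob * self.wet_mean_mm


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic county-year data generator."""

    n_counties: int = 5
    years: tuple[int, int] = (2001, 2006)  # inclusive
    season_length: int = 160
    weather: WeatherParams = field(default_factory=WeatherParams)
    genotype_spread: float = 0.04   # log-sd of per-cell genotype perturbation
    rue_drift_per_year: float = 0.0  # fractional genetic-gain drift in RUE
    yield_noise_sd: float = 0.5     # Mg/ha observation noise
    rho: float = DEFAULT_RHO
    soil_capacity_mean: float = 250.0  # mm plant-available
    soil_capacity_spread: float = 0.15  # log-sd across counties
    rain_spread: float = 0.15           # log-sd of county rainfall multiplier
    init_soil_fraction: float = 0.85
    plant_doy: int = 120
    density: float = 75_000.0           # plants/ha
    area_mean: float = 20_000.0         # ha planted
    area_spread: float = 0.3            # log-sd of planted area
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise InvalidConfigError("n_counties must be >= 1")
        if self.years[1] < self.years[0]:
            raise InvalidConfigError("year range is empty")
        if self.season_length <= 0:
            raise InvalidConfigError("season_length must be > 0")
        if self.yield_noise_sd < 0:
            raise InvalidConfigError("yield_noise_sd must be >= 0")
        if self.genotype_spread < 0:
            raise InvalidConfigError("genotype_spread must be >= 0")
        # the ratio band has log half-width ln(rho)/2; demand the perturbation
        # scale fit comfortably inside so feasibility holds by construction
        if self.genotype_spread >= 0.5 * math.log(self.rho):
            raise InvalidConfigError(
                f"genotype_spread {self.genotype_spread} incompatible with rho {self.rho}"
            )
        n_years = self.years[1] - self.years[0]
        if n_years > 0 and (1 + self.rue_drift_per_year) ** n_years > self.rho:
            raise InvalidConfigError("rue drift over the year range exceeds the ratio bound")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def harvest_doy(self) -> int:
        return self.plant_doy + self.season_length


def _rng(*ints: int) -> np.random.Generator:
    return np.random.default_rng([int(i) for i in ints])


def _county_multipliers(config: SynthConfig, county: int) -> tuple[float, float]:
    """(rain multiplier, soil-capacity multiplier) for one county."""
    rng = _rng(config.rng_seed, _SALT_COUNTY, county)
    rain = math.exp(config.rain_spread * rng.standard_normal())
    cap = math.exp(config.soil_capacity_spread * rng.standard_normal())
    return rain, cap


def generate_weather(config: SynthConfig, year: int, county: int) -> WeatherSeries:
    """Daily weather for one county-year, covering the full calendar year.

    Deterministic in (rng_seed, year, county).
    """
    wp = config.weather
    rng = _rng(config.rng_seed, _SALT_WEATHER, year, county)
    rain_mult, _ = _county_multipliers(config, county)

    doy = np.arange(1, 366)
    phase = 2.0 * math.pi * (doy - wp.t_peak_doy) / 365.0
    tmean = wp.t_mean_annual + wp.t_amp * np.cos(phase)
    noise_hi = wp.t_noise_sd * rng.standard_normal(365)
    noise_lo = wp.t_noise_sd * rng.standard_normal(365)
    tmax = tmean + 0.5 * wp.diurnal_range + noise_hi
    tmin = tmean - 0.5 * wp.diurnal_range + noise_lo
    swap = tmax < tmin
    tmax[swap], tmin[swap] = tmin[swap].copy(), tmax[swap].copy()

    wet = rng.random(365) < wp.wet_prob
    depth = rng.exponential(wp.wet_mean_mm, 365)
    prcp = np.where(wet, depth, 0.0) * rain_mult

    solstice_phase = 2.0 * math.pi * (doy - 172) / 365.0
    clear_sky = wp.srad_min + (wp.srad_max - wp.srad_min) * 0.5 * (1.0 + np.cos(solstice_phase))
    cloud = rng.uniform(wp.cloud_min, 1.0, 365)
    srad = clear_sky * cloud

    # dew point ~ tmin: ambient vapour pressure from the Tetens curve at tmin
    vp = np.array([saturation_vapor_pressure(t) for t in tmin])
    vp = np.maximum(vp, 1e-3)

    return WeatherSeries(doy=doy, tmax=tmax, tmin=tmin, prcp=prcp, srad=srad, vp=vp)


def generate_soil_profile(config: SynthConfig, county: int) -> SoilProfile:
    """Static soil descriptors; counties sit on a jittered planar grid."""
    _, cap_mult = _county_multipliers(config, county)
    rng = _rng(config.rng_seed, _SALT_COUNTY, county, 1)
    side = max(1, int(math.ceil(math.sqrt(config.n_counties))))
    x = (county % side) * 50.0 + rng.uniform(-5, 5)
    y = (county // side) * 50.0 + rng.uniform(-5, 5)
    return SoilProfile(
        capacity_mm=config.soil_capacity_mean * cap_mult,
        init_fraction=config.init_soil_fraction,
        x=float(x), y=float(y),
    )


def generate_management(config: SynthConfig, year: int, county: int) -> Management:
    rng = _rng(config.rng_seed, _SALT_MGMT, year, county)
    area = config.area_mean * math.exp(config.area_spread * rng.standard_normal())
    harvest = config.harvest_doy
    if harvest <= config.plant_doy or harvest > 365:
        raise InvalidConfigError(
            f"management season invalid: plant doy {config.plant_doy}, harvest doy {harvest}"
        )
    return Management(
        plant_doy=config.plant_doy,
        harvest_doy=harvest,
        density=config.density,
        area=float(area),
    )


def generate_genotype_table(config: SynthConfig) -> dict[Key, Genotype]:
    """True genotypes per (year, county), feasible for the ratio band.

    Each component of a mid-range maize genotype is perturbed per cell by
    exp(spread * z); RUE can additionally drift upward over years to mimic
    genetic gain.  The table is then projected onto the ratio band (a no-op
    for small spreads) so feasibility holds by construction.
    """
    base = dict(DEFAULT_GENOTYPE_VALUES)
    y0 = config.years[0]
    table: dict[Key, Genotype] = {}
    for year in config.year_list:
        for county in range(config.n_counties):
            rng = _rng(config.rng_seed, _SALT_GENO, year, county)
            vals = {}
            for name, v in base.items():
                z = rng.standard_normal()
                lo, hi = GENOTYPE_BOUNDS[name]
                vals[name] = float(np.clip(v * math.exp(config.genotype_spread * z), lo, hi))
            if config.rue_drift_per_year:
                lo, hi = GENOTYPE_BOUNDS["rue"]
                vals["rue"] = float(np.clip(
                    vals["rue"] * (1 + config.rue_drift_per_year) ** (year - y0), lo, hi
                ))
            table[(year, county)] = Genotype.from_dict(vals)
    return project_to_feasible(table, config.rho, GENOTYPE_BOUNDS)


def generate_soil_params(config: SynthConfig, county: int) -> SoilParams:
    """True calibrated-soil parameters, mildly county-specific."""
    rng = _rng(config.rng_seed, _SALT_SOILP, county)
    vals = {}
    for name, v in DEFAULT_SOIL_PARAM_VALUES.items():
        vals[name] = float(np.clip(v * math.exp(0.05 * rng.standard_normal()),
                                   0.01, 0.99 if name == "runoff_coeff" else np.inf))
    return SoilParams.from_dict(vals)


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Full synthetic dataset: inputs, ground truth, and noisy observed yields.

    observed = max(0, simulate(truth) + Normal(0, yield_noise_sd)).
    """
    weather: dict[Key, WeatherSeries] = {}
    management: dict[Key, Management] = {}
    soil: dict[int, SoilProfile] = {}
    true_soil_params: dict[int, SoilParams] = {}
    for county in range(config.n_counties):
        soil[county] = generate_soil_profile(config, county)
        true_soil_params[county] = generate_soil_params(config, county)

    true_genotypes = generate_genotype_table(config)
    observed: dict[Key, float] = {}
    true_yields: dict[Key, float] = {}
    for year in config.year_list:
        for county in range(config.n_counties):
            key = (year, county)
            try:
                weather[key] = generate_weather(config, year, county)
                management[key] = generate_management(config, year, county)
                y_true = simulate_season(
                    weather[key], management[key], soil[county],
                    true_genotypes[key], true_soil_params[county],
                )
            except InvalidInputError as exc:
                raise InvalidConfigError(f"generation failed at {key}: {exc}") from exc
            noise = 0.0
            if config.yield_noise_sd > 0:
                rng = _rng(config.rng_seed, _SALT_NOISE, year, county)
                noise = config.yield_noise_sd * rng.standard_normal()
            true_yields[key] = y_true
            observed[key] = max(0.0, y_true + noise)

    states = {c: f"S{c % 3}" for c in range(config.n_counties)}
    ds = SyntheticDataset(
        weather=weather, soil=soil, management=management,
        observed_yields=observed, states=states,
        true_genotypes=true_genotypes, true_soil_params=true_soil_params,
        true_yields=true_yields,
    )
    ds.validate_keys()
    return ds
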