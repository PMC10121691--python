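import numpy as np
import pytest

from ddcrop.params import DEFAULT_GENOTYPE_VALUES, DEFAULT_SOIL_PARAM_VALUES, SimConstants
from ddcrop.synth import SynthConfig, generate_dataset
from ddcrop.types import Genotype, Management, SoilParams, SoilProfile, WeatherSeries


@pytest.fixture(scope="session")
def default_genotype() -> Genotype:
    return Genotype.from_dict(DEFAULT_GENOTYPE_VALUES)


@pytest.fixture(scope="session")
def default_soil_params() -> SoilParams:
    return SoilParams.from_dict(DEFAULT_SOIL_PARAM_VALUES)


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Small noise-free dataset with identical genotypes everywhere."""
    return SynthConfig(n_counties=3, years=(2001, 2003),
                       yield_noise_sd=0.0, genotype_spread=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)


@pytest.fixture(scope="session")
def noisy_config() -> SynthConfig:
    return SynthConfig(n_counties=4, years=(2001, 2004), rng_seed=11)


@pytest.fixture(scope="session")
def noisy_dataset(noisy_config):
    return generate_dataset(noisy_config)


@pytest.fixture(scope="session")
def noise_only_dataset():
    """Observation noise is the only error source: identical true genotypes."""
    return generate_dataset(SynthConfig(
        n_counties=3, years=(2001, 2003), yield_noise_sd=0.5,
        genotype_spread=0.0, rng_seed=17,
    ))


def make_constant_weather(n_days, tmax=28.0, tmin=18.0, prcp=0.0, srad=20.0,
                          vp=1.5, start_doy=1):
    doy = np.arange(start_doy, start_doy + n_days)
    const = lambda v: np.full(n_days, float(v)) if np.isscalar(v) else np.asarray(v, float)
    return WeatherSeries(doy=doy, tmax=const(tmax), tmin=const(tmin),
                         prcp=const(prcp), srad=const(srad), vp=const(vp))


@pytest.fixture
def toy_season():
    """5-day constant-weather season crossing into grain fill on day 2."""
    weather = make_constant_weather(5, prcp=[0.0, 20.0, 0.0, 0.0, 0.0])
    management = Management(plant_doy=1, harvest_doy=5, density=75_000.0, area=100.0)
    soil = SoilProfile(capacity_mm=100.0, init_fraction=0.8)
    genotype = Genotype(
        gdd_flower=26.0, gdd_mature=100.0, rue=3.0, te=9.0, sla=0.022,
        p_leaf=0.45, p_root=0.06, u_max=0.055, t_heat=34.0,
    )
    soil_params = SoilParams(sw_cap_scale=1.0, runoff_coeff=0.2, evap_coeff=1.0)
    constants = SimConstants()
    return weather, management, soil, genotype, soil_params, constants
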