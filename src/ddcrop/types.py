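"""Core domain containers: weather, management, soil, genotype, crop state.

All containers are light dataclasses around plain floats / numpy arrays so a
season simulation stays cheap; tabular persistence lives in
:mod:`ddcrop.io`.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import InvalidInputError, MissingDataError
from .params import GENOTYPE_BOUNDS, SOIL_PARAM_BOUNDS

Key = tuple[int, int]  # (year, county)


class Stage(str, enum.Enum):
    VEGETATIVE = "vegetative"
    REPRODUCTIVE = "reproductive"
    MATURE = "mature"


GENOTYPE_COMPONENTS = (
    "gdd_flower",
    "gdd_mature",
    "rue",
    "te",
    "sla",
    "p_leaf",
    "p_root",
    "u_max",
    "t_heat",
)

SOIL_PARAM_COMPONENTS = ("sw_cap_scale", "runoff_coeff", "evap_coeff")


@dataclass(frozen=True)
class Genotype:
    """Environment-independent genetic parameter vector.

    gdd_flower / gdd_mature : degC day
        Thermal-time thresholds for the vegetative->reproductive transition
        and the end of grain fill.
    rue : g/MJ
        Radiation-use efficiency on intercepted shortwave.
    te : g kPa / L
        Transpiration-efficiency coefficient (biomass per litre, scaled by
        1/VPD).
    sla : m2/g
        Specific leaf area.
    p_leaf, p_root : fraction
        Vegetative-stage partitioning to leaf and root.
    u_max : L / g(root) / kPa / day
        Water-uptake coefficient.
    t_heat : degC
        Daily-maximum temperature at which heat stress begins.
    """

    gdd_flower: float
    gdd_mature: float
    rue: float
    te: float
    sla: float
    p_leaf: float
    p_root: float
    u_max: float
    t_heat: float

    def __post_init__(self) -> None:
        for name in GENOTYPE_COMPONENTS:
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"genotype component {name} must be > 0")
        if self.p_leaf + self.p_root >= 1:
            raise InvalidInputError("p_leaf + p_root must be < 1")
        if self.gdd_flower >= self.gdd_mature:
            raise InvalidInputError("gdd_flower must be < gdd_mature")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GENOTYPE_COMPONENTS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GENOTYPE_COMPONENTS])

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "Genotype":
        return cls(**{n: float(values[n]) for n in GENOTYPE_COMPONENTS})

    def replace(self, **kwargs: float) -> "Genotype":
        return replace(self, **kwargs)

    def within_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        bounds = bounds or GENOTYPE_BOUNDS
        return all(
            bounds[n][0] <= getattr(self, n) <= bounds[n][1] for n in bounds
        )


@dataclass(frozen=True)
class SoilParams:
    """Calibrated per-county soil parameters."""

    sw_cap_scale: float
    runoff_coeff: float
    evap_coeff: float

    def __post_init__(self) -> None:
        for name in SOIL_PARAM_COMPONENTS:
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"soil parameter {name} must be > 0")
        if self.runoff_coeff > 1:
            raise InvalidInputError("runoff_coeff must be <= 1")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in SOIL_PARAM_COMPONENTS}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "SoilParams":
        return cls(**{n: float(values[n]) for n in SOIL_PARAM_COMPONENTS})

    def within_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        bounds = bounds or SOIL_PARAM_BOUNDS
        return all(bounds[n][0] <= getattr(self, n) <= bounds[n][1] for n in bounds)


@dataclass(frozen=True)
class SoilProfile:
    """Static soil descriptors for one county.

    capacity_mm is the nominal plant-available water-holding capacity of the
    rooting zone; init_fraction is the soil-water status at planting as a
    fraction of capacity; (x, y) are planar centroid coordinates used for
    nearest-county logic.
    """

    capacity_mm: float
    init_fraction: float
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0:
            raise InvalidInputError("soil capacity must be > 0")
        if not 0.0 <= self.init_fraction <= 1.0:
            raise InvalidInputError("initial soil-water fraction must be in [0, 1]")


@dataclass(frozen=True)
class Management:
    """Per county-year management: dates, stand density, planted area."""

    plant_doy: int
    harvest_doy: int
    density: float  # plants per hectare
    area: float = 0.0  # planted hectares (weighting in calibration)

    def __post_init__(self) -> None:
        if self.plant_doy >= self.harvest_doy:
            raise InvalidInputError("plant_doy must precede harvest_doy")
        if self.density <= 0:
            raise InvalidInputError("plant density must be > 0")
        if self.area < 0:
            raise InvalidInputError("planted area must be >= 0")

    @property
    def plant_area_m2(self) -> float:
        """Ground area per plant (m2); 1e4 m2 per hectare."""
        return 1e4 / self.density


@dataclass
class WeatherSeries:
    """One county-year of daily weather.

    Arrays are aligned on ``doy`` (1-based day of year, contiguous).
    tmax/tmin degC, prcp mm/day, srad MJ m-2 day-1, vp kPa.
    """

    doy: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    prcp: np.ndarray
    srad: np.ndarray
    vp: np.ndarray

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        for name in ("tmax", "tmin", "prcp", "srad", "vp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.doy)
        if any(len(getattr(self, v)) != n for v in ("tmax", "tmin", "prcp", "srad", "vp")):
            raise InvalidInputError("weather arrays must have equal length")
        if n and np.any(np.diff(self.doy) != 1):
            raise InvalidInputError("weather days must be contiguous")
        if np.any(self.tmax < self.tmin):
            raise InvalidInputError("tmax < tmin in weather series")
        if np.any(self.prcp < 0) or np.any(self.srad < 0) or np.any(self.vp <= 0):
            raise InvalidInputError("negative prcp/srad or non-positive vp")

    def __len__(self) -> int:
        return len(self.doy)

    def window(self, start_doy: int, end_doy: int) -> "WeatherSeries":
        """Contiguous sub-series covering [start_doy, end_doy] inclusive."""
        if start_doy < self.doy[0] or end_doy > self.doy[-1]:
            raise MissingDataError(
                f"weather covers doy {self.doy[0]}..{self.doy[-1]}, "
                f"requested {start_doy}..{end_doy}"
            )
        i0 = int(start_doy - self.doy[0])
        i1 = int(end_doy - self.doy[0]) + 1
        return WeatherSeries(
            self.doy[i0:i1], self.tmax[i0:i1], self.tmin[i0:i1],
            self.prcp[i0:i1], self.srad[i0:i1], self.vp[i0:i1],
        )


@dataclass
class CropState:
    """Mutable per-plant state advanced by the daily loop."""

    cum_gdd: float = 0.0
    stage: Stage = Stage.VEGETATIVE
    soil_water: float = 0.0  # mm in the bucket
    leaf_mass: float = 0.0   # g/plant
    root_mass: float = 0.0
    stem_mass: float = 0.0
    grain_mass: float = 0.0
    consecutive_saturated_days: int = 0

    @property
    def total_mass(self) -> float:
        return self.leaf_mass + self.root_mass + self.stem_mass + self.grain_mass


@dataclass
class Dataset:
    """In-memory bundle of county-year tables keyed by (year, county)."""

    weather: dict[Key, WeatherSeries]
    soil: dict[int, SoilProfile]
    management: dict[Key, Management]
    observed_yields: dict[Key, float]  # Mg/ha
    states: dict[int, str] = field(default_factory=dict)  # county -> state label

    def keys(self) -> list[Key]:
        return sorted(self.observed_yields)

    def years(self) -> list[int]:
        return sorted({t for t, _ in self.observed_yields})

    def counties(self) -> list[int]:
        return sorted({c for _, c in self.observed_yields})

    def area(self, key: Key) -> float:
        return self.management[key].area

    def coords(self) -> dict[int, tuple[float, float]]:
        return {c: (p.x, p.y) for c, p in self.soil.items()}

    def validate_keys(self) -> None:
        for key in self.observed_yields:
            if key not in self.weather:
                raise MissingDataError(f"no weather for {key}")
            if key not in self.management:
                raise MissingDataError(f"no management for {key}")
            if key[1] not in self.soil:
                raise MissingDataError(f"no soil profile for county {key[1]}")

    def subset(self, keys: Iterator[Key]) -> "Dataset":
        keys = set(keys)
        return Dataset(
            weather={k: v for k, v in self.weather.items() if k in keys},
            soil=dict(self.soil),
            management={k: v for k, v in self.management.items() if k in keys},
            observed_yields={k: v for k, v in self.observed_yields.items() if k in keys},
            states=dict(self.states),
        )


@dataclass
class SyntheticDataset(Dataset):
    """Dataset plus the generating ground truth (for recovery experiments)."""

    true_genotypes: dict[Key, Genotype] = field(default_factory=dict)
    true_soil_params: dict[int, SoilParams] = field(default_factory=dict)
    true_yields: dict[Key, float] = field(default_factory=dict)


def euclidean(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])
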