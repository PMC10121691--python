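"""Extrapolation experiments and naive benchmarks.

Two holdout designs mirror how a calibrated county-year yield model is
stress-tested:

* spatial: each county in turn is carved out entirely, the model is refit on
  the remainder, and the held-out county's yields are predicted with
  transferred parameters; the naive benchmark predicts each county-year with
  the nearest county's observed yield that year;
* temporal: each year is carved out; the benchmark averages the county's
  observed yields in the adjacent years t-1 and t+1.

Errors are planting-area-weighted RMSEs, optionally expressed as RRMSE
(percent of a reference mean yield).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationProblem,
    CalibrationResult,
    FitOptions,
    fit,
    weighted_rmse,
)
from .errors import InvalidInputError, MissingDataError
from .types import Dataset, GENOTYPE_COMPONENTS, Genotype, Key, SOIL_PARAM_COMPONENTS, SoilParams, euclidean
from .simulator import simulate_season

logger = logging.getLogger(__name__)

__all__ = [
    "rrmse",
    "nearest_county_benchmark",
    "nearest_year_benchmark",
    "holdout_fit",
    "transfer_genotype_spatial",
    "transfer_genotype_temporal",
    "spatial_extrapolation",
    "temporal_extrapolation",
    "ExtrapolationReport",
]


def rrmse(rmse: float, reference_yield: float) -> float:
    """Relative RMSE in percent of a reference mean yield."""
    if reference_yield <= 0:
        raise InvalidInputError("reference yield must be > 0")
    if rmse < 0:
        raise InvalidInputError("rmse must be >= 0")
    return 100.0 * rmse / reference_yield


def nearest_county_benchmark(
    target_county: int,
    year: int,
    yields: dict[Key, float],
    coords: dict[int, tuple[float, float]],
) -> float:
    """Observed yield of the closest other county with data in that year.

    Distance is Euclidean between county centroids; ties break toward the
    smaller county identifier; counties without data that year are skipped.
    """
    target_xy = coords[target_county]
    candidates = sorted(
        c for (t, c) in yields
        if t == year and c != target_county and c in coords
    )
    if not candidates:
        raise MissingDataError(f"no other county has a yield in year {year}")
    best = min(candidates, key=lambda c: (euclidean(coords[c], target_xy), c))
    return yields[(year, best)]


def nearest_year_benchmark(county: int, year: int, yields: dict[Key, float]) -> float:
    """Mean of the county's observed yields in years t-1 and t+1."""
    neighbors = [
        yields[(t, county)] for t in (year - 1, year + 1) if (t, county) in yields
    ]
    if not neighbors:
        raise MissingDataError(
            f"county {county} has no yields in years {year - 1} or {year + 1}"
        )
    return float(np.mean(neighbors))


def _geometric_mean_genotype(
    genotypes: list[Genotype], weights: list[float] | None = None
) -> Genotype:
    if weights is None or sum(weights) == 0:
        weights = [1.0] * len(genotypes)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    vals = {}
    for comp in GENOTYPE_COMPONENTS:
        logs = np.array([math.log(getattr(g, comp)) for g in genotypes])
        vals[comp] = math.exp(float(np.dot(w, logs)))
    return Genotype.from_dict(vals)


def _geometric_mean_soil(
    params: list[SoilParams], weights: list[float] | None = None
) -> SoilParams:
    if weights is None or sum(weights) == 0:
        weights = [1.0] * len(params)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    vals = {}
    for comp in SOIL_PARAM_COMPONENTS:
        logs = np.array([math.log(getattr(s, comp)) for s in params])
        vals[comp] = math.exp(min(float(np.dot(w, logs)), 0.0) if comp == "runoff_coeff" else float(np.dot(w, logs)))
    return SoilParams.from_dict(vals)


def transfer_genotype_spatial(
    calib: CalibrationResult,
    dataset: Dataset,
    target_county: int,
    year: int,
    k: int = 3,
) -> Genotype:
    """Genotype for a county absent from training: area-weighted geometric
    mean of the fitted genotypes of the k nearest training counties with a
    fit in the same year."""
    coords = dataset.coords()
    target_xy = coords[target_county]
    fitted = [
        (c, euclidean(coords[c], target_xy))
        for (t, c) in calib.genotypes
        if t == year and c != target_county
    ]
    if not fitted:
        raise MissingDataError(f"no fitted genotypes in year {year}")
    fitted.sort(key=lambda pair: (pair[1], pair[0]))
    chosen = [c for c, _ in fitted[:k]]
    genos = [calib.genotypes[(year, c)] for c in chosen]
    weights = [dataset.area((year, c)) if (year, c) in dataset.management else 1.0 for c in chosen]
    return _geometric_mean_genotype(genos, weights)


def transfer_soil_spatial(
    calib: CalibrationResult,
    dataset: Dataset,
    target_county: int,
    k: int = 3,
) -> SoilParams:
    """Soil parameters for an unseen county: geometric mean over the k
    nearest calibrated counties."""
    coords = dataset.coords()
    target_xy = coords[target_county]
    fitted = sorted(
        ((c, euclidean(coords[c], target_xy)) for c in calib.soil_params if c != target_county),
        key=lambda pair: (pair[1], pair[0]),
    )
    if not fitted:
        raise MissingDataError("no calibrated soil parameters to transfer")
    chosen = [c for c, _ in fitted[:k]]
    return _geometric_mean_soil([calib.soil_params[c] for c in chosen])


def transfer_genotype_temporal(
    calib: CalibrationResult, county: int, year: int
) -> Genotype:
    """Genotype for an unseen year: geometric mean of the county's fitted
    genotypes in years t-1 and t+1 (one of them if only one exists)."""
    neighbors = [
        calib.genotypes[(t, county)]
        for t in (year - 1, year + 1)
        if (t, county) in calib.genotypes
    ]
    if not neighbors:
        raise MissingDataError(
            f"county {county} has no fitted genotypes in years {year - 1}/{year + 1}"
        )
    return _geometric_mean_genotype(neighbors)


@dataclass
class ExtrapolationReport:
    """Per-held-out-unit errors plus area-weighted summary statistics."""

    axis: str  # "county" or "year"
    per_unit: pd.DataFrame  # unit, model_rmse, benchmark_rmse, training_rmse, area
    reference_yield: float
    failures: dict = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, float]:
        df = self.per_unit.dropna(subset=["model_rmse"])
        w = df["area"].to_numpy()
        if w.sum() == 0:
            w = np.ones(len(df))
        out = {}
        for col in ("model_rmse", "benchmark_rmse", "training_rmse"):
            avg = float(np.average(df[col].to_numpy(), weights=w))
            out[col.replace("_rmse", "_rmse_avg")] = avg
            out[col.replace("_rmse", "_rrmse_pct")] = rrmse(avg, self.reference_yield)
        return out


def default_reference_yield(dataset: Dataset) -> float:
    """Area-weighted mean observed yield in the dataset's last year."""
    last = dataset.years()[-1]
    keys = [k for k in dataset.keys() if k[0] == last]
    y = np.array([dataset.observed_yields[k] for k in keys])
    a = np.array([dataset.area(k) for k in keys])
    if a.sum() == 0:
        a = np.ones(len(keys))
    return float(np.average(y, weights=a))


def holdout_fit(
    dataset: Dataset,
    held_out,
    axis: str,
    options: FitOptions | None = None,
    **problem_kwargs,
) -> CalibrationResult:
    """Refit the model with one county or year removed from training.

    The held-out unit's observed yields never enter the objective.
    """
    if axis == "county":
        train_keys = [k for k in dataset.keys() if k[1] != held_out]
    elif axis == "year":
        train_keys = [k for k in dataset.keys() if k[0] != held_out]
    else:
        raise InvalidInputError(f"unknown holdout axis {axis!r}")
    if not train_keys:
        raise InvalidInputError("holdout removes the entire dataset")
    problem = CalibrationProblem(dataset.subset(train_keys), **problem_kwargs)
    return fit(problem, options)


def spatial_extrapolation(
    dataset: Dataset,
    options: FitOptions | None = None,
    k_neighbors: int = 3,
    reference_yield: float | None = None,
    **problem_kwargs,
) -> ExtrapolationReport:
    """Leave-one-county-out evaluation against the nearest-county benchmark."""
    counties = dataset.counties()
    if len(counties) < 2:
        raise InvalidInputError("spatial extrapolation needs at least 2 counties")
    reference = reference_yield or default_reference_yield(dataset)
    coords = dataset.coords()
    rows, failures = [], {}
    for held in counties:
        keys = [k for k in dataset.keys() if k[1] == held]
        try:
            calib = holdout_fit(dataset, held, "county", options, **problem_kwargs)
            soil_p = transfer_soil_spatial(calib, dataset, held, k_neighbors)
            preds, bench, obs, areas = [], [], [], []
            for (t, c) in keys:
                g = transfer_genotype_spatial(calib, dataset, held, t, k_neighbors)
                preds.append(simulate_season(
                    dataset.weather[(t, c)], dataset.management[(t, c)],
                    dataset.soil[c], g, soil_p,
                ))
                bench.append(nearest_county_benchmark(held, t, dataset.observed_yields, coords))
                obs.append(dataset.observed_yields[(t, c)])
                areas.append(dataset.area((t, c)))
            rows.append({
                "unit": held,
                "model_rmse": weighted_rmse(obs, preds, areas),
                "benchmark_rmse": weighted_rmse(obs, bench, areas),
                "training_rmse": calib.objective,
                "area": float(np.mean(areas)),
            })
        except Exception as exc:  # refit failure: report and continue
            logger.warning("spatial holdout failed for county %s: %s", held, exc)
            failures[held] = str(exc)
            rows.append({"unit": held, "model_rmse": np.nan,
                         "benchmark_rmse": np.nan, "training_rmse": np.nan,
                         "area": np.nan})
    return ExtrapolationReport("county", pd.DataFrame(rows), reference, failures)


def temporal_extrapolation(
    dataset: Dataset,
    options: FitOptions | None = None,
    reference_yield: float | None = None,
    **problem_kwargs,
) -> ExtrapolationReport:
    """Leave-one-year-out evaluation against the nearest-year benchmark."""
    years = dataset.years()
    if len(years) < 2:
        raise InvalidInputError("temporal extrapolation needs at least 2 years")
    reference = reference_yield or default_reference_yield(dataset)
    rows, failures = [], {}
    for held in years:
        keys = [k for k in dataset.keys() if k[0] == held]
        try:
            calib = holdout_fit(dataset, held, "year", options, **problem_kwargs)
            preds, bench, obs, areas = [], [], [], []
            for (t, c) in keys:
                g = transfer_genotype_temporal(calib, c, held)
                preds.append(simulate_season(
                    dataset.weather[(t, c)], dataset.management[(t, c)],
                    dataset.soil[c], g, calib.soil_params[c],
                ))
                bench.append(nearest_year_benchmark(c, held, dataset.observed_yields))
                obs.append(dataset.observed_yields[(t, c)])
                areas.append(dataset.area((t, c)))
            rows.append({
                "unit": held,
                "model_rmse": weighted_rmse(obs, preds, areas),
                "benchmark_rmse": weighted_rmse(obs, bench, areas),
                "training_rmse": calib.objective,
                "area": float(np.mean(areas)),
            })
        except Exception as exc:
            logger.warning("temporal holdout failed for year %s: %s", held, exc)
            failures[held] = str(exc)
            rows.append({"unit": held, "model_rmse": np.nan,
                         "benchmark_rmse": np.nan, "training_rmse": np.nan,
                         "area": np.nan})
    return ExtrapolationReport("year", pd.DataFrame(rows), reference, failures)
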