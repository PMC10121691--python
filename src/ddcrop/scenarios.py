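"""What-if analyses: genotype x environment matrices and seed selection.

Because the calibrated genotype vector is environment-independent, any
historical genotype can be re-grown in silico under any other year's
weather and management.  This module builds the full genotype-year by
environment-year predicted-yield matrix and solves the two seed-selection
problems:

* known weather: pick the (source county d, source year r) genotype that
  maximises the predicted yield in target county c and year t under the
  realized year-t weather, with r ranging over the first data year..t;
* unknown weather: pick the genotype maximising the mean predicted yield
  over all historical weather years tau < t in county c, with r ranging
  over (first data year + 1)..t.

Both optimizers are exhaustive enumerations; ties break toward the earlier
source year, then the smaller county identifier.  The target county keeps
its own soil (profile and calibrated parameters) throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .errors import InvalidInputError
from .simulator import simulate_season
from .types import Dataset, Key

__all__ = [
    "GxEMatrix",
    "SeedSelectionResult",
    "gxe_matrix",
    "select_seed_known_weather",
    "select_seed_unknown_weather",
    "yield_gain_summary",
]


@dataclass
class GxEMatrix:
    """Square matrix of predicted yields: genotype year (rows) x weather year
    (columns), area-weighted averaged over counties.  The diagonal equals the
    aggregated fitted training yields."""

    values: pd.DataFrame  # index = genotype year, columns = environment year
    missing: list[tuple[int, int, int]] = field(default_factory=list)  # (t1, t2, county)

    @property
    def years(self) -> list[int]:
        return list(self.values.index)

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.values.index)


def gxe_matrix(
    calib: CalibrationResult,
    dataset: Dataset,
    county_set: list[int] | None = None,
    years: list[int] | None = None,
) -> GxEMatrix:
    """Predicted yield of every genotype year grown in every environment year.

    Cell (t1, t2) is the area-weighted mean over counties c of the simulated
    yield with genotype g_{t1,c} under weather/management of (t2, c) and the
    county's own soil.  Counties missing either key are skipped for that
    cell (and recorded); a cell with no county at all is NaN.
    """
    counties = county_set or dataset.counties()
    yrs = years or sorted({t for t, _ in calib.genotypes})
    mat = pd.DataFrame(np.nan, index=yrs, columns=yrs, dtype=float)
    missing: list[tuple[int, int, int]] = []
    for t1 in yrs:
        for t2 in yrs:
            vals, weights = [], []
            for c in counties:
                if (t1, c) not in calib.genotypes or (t2, c) not in dataset.weather:
                    missing.append((t1, t2, c))
                    continue
                y = simulate_season(
                    dataset.weather[(t2, c)], dataset.management[(t2, c)],
                    dataset.soil[c], calib.genotypes[(t1, c)],
                    calib.soil_params[c],
                )
                vals.append(y)
                weights.append(dataset.area((t2, c)))
            if vals:
                w = np.asarray(weights)
                if w.sum() == 0:
                    w = np.ones(len(vals))
                mat.loc[t1, t2] = float(np.average(vals, weights=w))
    return GxEMatrix(values=mat, missing=missing)


@dataclass(frozen=True)
class SeedSelectionResult:
    """Outcome of one seed-selection decision for (county, year)."""

    county: int
    year: int
    source_county: int
    source_year: int
    predicted: float        # yield of the chosen genotype under year-t weather
    reference: float        # yield of the county's own-year genotype
    gain: float             # predicted - reference
    criterion: float        # value of the maximised objective
    scenario: str           # "known" or "unknown"


def _pool(calib: CalibrationResult, t: int, r_start: int) -> list[Key]:
    pool = sorted(
        ((r, d) for (r, d) in calib.genotypes if r_start <= r <= t),
        key=lambda rd: (rd[0], rd[1]),
    )
    return [(r, d) for r, d in pool]


def _simulate_with_genotype(dataset: Dataset, calib: CalibrationResult,
                            c: int, t: int, g) -> float:
    return simulate_season(
        dataset.weather[(t, c)], dataset.management[(t, c)],
        dataset.soil[c], g, calib.soil_params[c],
    )


def select_seed_known_weather(
    c: int,
    t: int,
    calib: CalibrationResult,
    dataset: Dataset,
    pool: list[Key] | None = None,
    r_start: int | None = None,
) -> SeedSelectionResult:
    """Best genotype for (c, t) given the realized year-t weather.

    Enumerates every (source year r, source county d) in the pool
    (default: all calibrated genotypes with r from the first data year
    through t) and maximises the simulated yield; ties break toward earlier
    r then smaller d.
    """
    if (t, c) not in dataset.weather:
        raise InvalidInputError(f"no weather for target {(t, c)}")
    if pool is None:
        first = min(r for r, _ in calib.genotypes)
        pool = _pool(calib, t, r_start if r_start is not None else first)
    if not pool:
        raise InvalidInputError("empty seed-selection pool")
    best_rd, best_val = None, -np.inf
    for r, d in pool:
        val = _simulate_with_genotype(dataset, calib, c, t, calib.genotypes[(r, d)])
        if val > best_val:
            best_rd, best_val = (r, d), val
    reference = (
        _simulate_with_genotype(dataset, calib, c, t, calib.genotypes[(t, c)])
        if (t, c) in calib.genotypes else np.nan
    )
    r, d = best_rd
    return SeedSelectionResult(
        county=c, year=t, source_county=d, source_year=r,
        predicted=best_val, reference=reference,
        gain=best_val - reference, criterion=best_val, scenario="known",
    )


def select_seed_unknown_weather(
    c: int,
    t: int,
    calib: CalibrationResult,
    dataset: Dataset,
    pool: list[Key] | None = None,
    r_start: int | None = None,
) -> SeedSelectionResult:
    """Best genotype for (c, t) without foresight of the year-t weather.

    Maximises the mean simulated yield over all historical weather years
    tau < t in county c; r defaults to (first data year + 1)..t.  The
    reported ``predicted`` value is the chosen genotype's yield under the
    realized year-t weather; ``criterion`` is the maximised historical mean.
    """
    first = min(r for r, _ in calib.genotypes)
    history = [tau for tau in range(first, t) if (tau, c) in dataset.weather]
    if not history:
        raise InvalidInputError(f"no historical weather before year {t} for county {c}")
    if pool is None:
        pool = _pool(calib, t, r_start if r_start is not None else first + 1)
    if not pool:
        raise InvalidInputError("empty seed-selection pool")
    best_rd, best_val = None, -np.inf
    for r, d in pool:
        g = calib.genotypes[(r, d)]
        vals = [_simulate_with_genotype(dataset, calib, c, tau, g) for tau in history]
        val = float(np.mean(vals))
        if val > best_val:
            best_rd, best_val = (r, d), val
    r, d = best_rd
    chosen = calib.genotypes[(r, d)]
    realized = (
        _simulate_with_genotype(dataset, calib, c, t, chosen)
        if (t, c) in dataset.weather else np.nan
    )
    reference = (
        _simulate_with_genotype(dataset, calib, c, t, calib.genotypes[(t, c)])
        if (t, c) in calib.genotypes else np.nan
    )
    return SeedSelectionResult(
        county=c, year=t, source_county=d, source_year=r,
        predicted=realized, reference=reference,
        gain=realized - reference, criterion=best_val, scenario="unknown",
    )


def yield_gain_summary(
    results: list[SeedSelectionResult],
    dataset: Dataset,
) -> dict[str, float]:
    """Area-weighted gain summary over a set of selection decisions.

    Reports the mean observed yield, the mean yield under selection, and the
    gain both against observed yields and against the model-predicted
    own-genotype reference (two conventions; the latter is non-negative by
    construction under known weather when the own genotype is in the pool).
    """
    if not results:
        raise InvalidInputError("no selection results to summarise")
    obs = np.array([dataset.observed_yields[(r.year, r.county)] for r in results])
    sel = np.array([r.predicted for r in results])
    ref = np.array([r.reference for r in results])
    w = np.array([dataset.area((r.year, r.county)) for r in results])
    if w.sum() == 0:
        w = np.ones(len(results))
    mean_obs = float(np.average(obs, weights=w))
    mean_sel = float(np.average(sel, weights=w))
    mean_ref = float(np.average(ref, weights=w))
    return {
        "mean_observed": mean_obs,
        "mean_selected": mean_sel,
        "mean_reference_predicted": mean_ref,
        "gain_vs_observed": mean_sel - mean_obs,
        "gain_vs_observed_pct": 100.0 * (mean_sel - mean_obs) / mean_obs,
        "gain_vs_predicted": mean_sel - mean_ref,
        "gain_vs_predicted_pct": 100.0 * (mean_sel - mean_ref) / mean_ref,
        "n": float(len(results)),
    }
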