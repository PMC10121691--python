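"""Constrained calibration of genotypic and soil parameters.

The fit minimises the planting-area-weighted RMSE between observed and
simulated county-year yields,

    sqrt( sum_k a_k^2 (y_k - yhat_k)^2 / sum_k a_k^2 ),

with a_k the planted area, subject to pairwise ratio constraints on every
genotype component: within a county across years, and within a year across
counties, no two values may differ by more than a factor rho (default 1.25).
The simulator has no useful gradients, so the solver is a derivative-free
block-coordinate scheme:

  (i)   Nelder-Mead on the shared (log-scale) values of the free genotype
        components;
  (ii)  per-county Nelder-Mead on the soil parameters (the weighted squared
        error decomposes by county, so each county's block can be fit on its
        own residuals);
  (iii) an optional greedy sweep of per-(year, county) log deviations,
        re-projected onto the ratio band after every accepted move;

repeated until the relative objective improvement drops below tolerance.
Every accepted iterate is feasible and the objective trace is
non-increasing by construction (the incumbent is kept on ties).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidInputError, ProjectionFailureError
from .params import (
    DEFAULT_CONSTANTS,
    DEFAULT_SOIL_PARAM_VALUES,
    GENOTYPE_BOUNDS,
    SOIL_PARAM_BOUNDS,
    SimConstants,
)
from .simulator import simulate_season
from .types import (
    Dataset,
    GENOTYPE_COMPONENTS,
    Genotype,
    Key,
    SOIL_PARAM_COMPONENTS,
    SoilParams,
)

logger = logging.getLogger(__name__)

DEFAULT_RHO = 1.25

__all__ = [
    "DEFAULT_RHO",
    "weighted_rmse",
    "ratio_constraints_check",
    "project_to_feasible",
    "CalibrationProblem",
    "FitOptions",
    "CalibrationResult",
    "fit",
]


def weighted_rmse(observed, predicted, areas) -> float:
    """Area-weighted RMSE with squared-area weights.

    Equals the plain RMSE when all areas are equal.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    a = np.asarray(areas, dtype=float)
    if not (len(y) == len(yhat) == len(a)) or len(y) == 0:
        raise InvalidInputError("observed/predicted/areas must be equal-length, non-empty")
    if np.any(a < 0):
        raise InvalidInputError("areas must be >= 0")
    w = a * a
    tot = w.sum()
    if tot == 0:
        raise InvalidInputError("areas must not all be zero")
    return float(np.sqrt((w * (y - yhat) ** 2).sum() / tot))


@dataclass(frozen=True)
class RatioViolation:
    component: str
    kind: str           # "temporal" (within county) or "spatial" (within year)
    key_hi: Key
    key_lo: Key
    ratio: float


def ratio_constraints_check(
    genotypes: dict[Key, Genotype],
    rho: float = DEFAULT_RHO,
    rtol: float = 1e-9,
) -> list[RatioViolation]:
    """Brute-force check of the pairwise ratio band (inclusive at rho).

    Flags, per component, every ordered pair within a county across years
    and within a year across counties whose ratio strictly exceeds rho.
    An empty list means the table is feasible.
    """
    if not genotypes:
        raise InvalidInputError("empty genotype table")
    keys = sorted(genotypes)
    violations: list[RatioViolation] = []
    by_county: dict[int, list[Key]] = {}
    by_year: dict[int, list[Key]] = {}
    for t, c in keys:
        by_county.setdefault(c, []).append((t, c))
        by_year.setdefault(t, []).append((t, c))
    groups = [("temporal", grp) for grp in by_county.values()] + [
        ("spatial", grp) for grp in by_year.values()
    ]
    for comp in GENOTYPE_COMPONENTS:
        for kind, grp in groups:
            for i, k1 in enumerate(grp):
                v1 = getattr(genotypes[k1], comp)
                for k2 in grp[i + 1:]:
                    v2 = getattr(genotypes[k2], comp)
                    hi, lo = (k1, k2) if v1 >= v2 else (k2, k1)
                    ratio = max(v1, v2) / min(v1, v2)
                    if ratio > rho * (1.0 + rtol):
                        violations.append(RatioViolation(comp, kind, hi, lo, ratio))
    return violations


def _band_clip(mat: np.ndarray, half_width: float, axis: int) -> np.ndarray:
    """Clip each slice along ``axis`` into +/- half_width around its midrange.

    Feasible slices (range <= 2*half_width) lie inside that interval already,
    so they pass through unchanged (fixed point).
    """
    hi = np.nanmax(mat, axis=axis, keepdims=True)
    lo = np.nanmin(mat, axis=axis, keepdims=True)
    mid = 0.5 * (hi + lo)
    return np.clip(mat, mid - half_width, mid + half_width)


def project_to_feasible(
    genotypes: dict[Key, Genotype],
    rho: float = DEFAULT_RHO,
    bounds: dict[str, tuple[float, float]] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> dict[Key, Genotype]:
    """Map a positive genotype table onto the ratio band and bounds.

    Works per component in log space, alternately clipping each county's
    across-year values and each year's across-county values into a
    +/- ln(rho)/2 interval centred on the slice midrange (the geometric mean
    of the slice extremes), then clipping to bounds, until convergence.
    Already-feasible tables are returned unchanged.
    """
    if not genotypes:
        raise InvalidInputError("empty genotype table")
    bounds = bounds or GENOTYPE_BOUNDS
    keys = sorted(genotypes)
    years = sorted({t for t, _ in keys})
    counties = sorted({c for _, c in keys})
    yi = {t: i for i, t in enumerate(years)}
    ci = {c: j for j, c in enumerate(counties)}
    half = 0.5 * math.log(rho)

    out_vals: dict[str, np.ndarray] = {}
    for comp in GENOTYPE_COMPONENTS:
        mat = np.full((len(years), len(counties)), np.nan)
        for t, c in keys:
            v = getattr(genotypes[(t, c)], comp)
            if v <= 0:
                raise InvalidInputError(f"non-positive {comp} at {(t, c)}")
            mat[yi[t], ci[c]] = math.log(v)
        lo = math.log(bounds[comp][0]) if comp in bounds else -math.inf
        hi = math.log(bounds[comp][1]) if comp in bounds else math.inf
        for _ in range(max_iter):
            prev = mat.copy()
            mat = _band_clip(mat, half, axis=0)   # temporal: within county
            mat = _band_clip(mat, half, axis=1)   # spatial: within year
            mat = np.clip(mat, lo, hi)
            if np.nanmax(np.abs(mat - prev)) < tol:
                break
        else:
            raise ProjectionFailureError(f"projection did not converge for {comp}")
        out_vals[comp] = mat

    result: dict[Key, Genotype] = {}
    for t, c in keys:
        vals = {comp: math.exp(out_vals[comp][yi[t], ci[c]]) for comp in GENOTYPE_COMPONENTS}
        result[(t, c)] = _make_valid_genotype(vals)
    return result


def _make_valid_genotype(vals: dict[str, float]) -> Genotype:
    """Construct a Genotype, nudging structural constraints if needed."""
    if vals["gdd_flower"] >= vals["gdd_mature"]:
        vals["gdd_flower"] = 0.95 * vals["gdd_mature"]
    ptot = vals["p_leaf"] + vals["p_root"]
    if ptot >= 1.0:
        scale = 0.95 / ptot
        vals["p_leaf"] *= scale
        vals["p_root"] *= scale
    return Genotype.from_dict(vals)


@dataclass
class CalibrationProblem:
    """Dataset plus bounds, ratio bound and pinned components."""

    dataset: Dataset
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GENOTYPE_BOUNDS)
    )
    soil_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SOIL_PARAM_BOUNDS)
    )
    rho: float = DEFAULT_RHO
    fixed_components: dict[str, float] = field(default_factory=dict)
    fixed_soil: dict[int, SoilParams] | None = None
    constants: SimConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.rho <= 1:
            raise InvalidInputError("rho must be > 1")
        if not self.dataset.observed_yields:
            raise InvalidInputError("empty dataset")
        self.dataset.validate_keys()

    @property
    def free_components(self) -> list[str]:
        return [c for c in GENOTYPE_COMPONENTS if c not in self.fixed_components]


@dataclass
class FitOptions:
    """Optimizer settings; all phases are deterministic given the seed."""

    seed: int = 0
    max_outer: int = 3
    rel_tol: float = 1e-4
    nm_maxiter: int = 120
    grid_init: bool = True
    grid_points: int = 7
    soil_nm_maxiter: int = 60
    cell_sweeps: int = 1
    cell_step: float = 0.05
    fit_soil: bool = True
    init_genotype: Genotype | None = None
    init_soil: dict[int, SoilParams] | None = None


@dataclass
class CalibrationResult:
    genotypes: dict[Key, Genotype]
    soil_params: dict[int, SoilParams]
    objective: float
    fitted_yields: dict[Key, float]
    trace: list[float]


class _Fitter:
    def __init__(self, problem: CalibrationProblem, options: FitOptions):
        self.p = problem
        self.o = options
        self.ds = problem.dataset
        self.keys = self.ds.keys()
        self.counties = self.ds.counties()
        self.obs = np.array([self.ds.observed_yields[k] for k in self.keys])
        self.areas = np.array([self.ds.area(k) for k in self.keys])
        if np.all(self.areas == 0):
            raise InvalidInputError("all planted areas are zero")
        self.free = problem.free_components
        self.county_idx = {
            c: [i for i, k in enumerate(self.keys) if k[1] == c] for c in self.counties
        }
        self._cache: dict[tuple, float] = {}

    # -- simulation ---------------------------------------------------------
    def _predict_key(self, key: Key, g: Genotype, s: SoilParams) -> float:
        cache_key = (key, g, s)
        val = self._cache.get(cache_key)
        if val is None:
            try:
                val = simulate_season(
                    self.ds.weather[key], self.ds.management[key],
                    self.ds.soil[key[1]], g, s, self.p.constants,
                )
            except Exception as exc:  # surfaced with the offending key
                raise InvalidInputError(f"simulator failed for {key}: {exc}") from exc
            self._cache[cache_key] = val
        return val

    def predict_all(self, genotypes, soils) -> np.ndarray:
        return np.array([
            self._predict_key(k, genotypes[k], soils[k[1]]) for k in self.keys
        ])

    def objective(self, genotypes, soils) -> float:
        return weighted_rmse(self.obs, self.predict_all(genotypes, soils), self.areas)

    # -- parameter construction --------------------------------------------
    def _base_from_logx(self, x: np.ndarray) -> dict[str, float]:
        vals = dict(self.p.fixed_components)
        for name, xi in zip(self.free, x):
            lo, hi = self.p.bounds[name]
            vals[name] = float(np.clip(math.exp(xi), lo, hi))
        return vals

    def _table_from_base(
        self, base: dict[str, float], deltas: dict[Key, np.ndarray]
    ) -> dict[Key, Genotype]:
        table = {}
        for k in self.keys:
            vals = dict(base)
            for j, name in enumerate(self.free):
                lo, hi = self.p.bounds[name]
                vals[name] = float(np.clip(vals[name] * math.exp(deltas[k][j]), lo, hi))
            table[k] = _make_valid_genotype(vals)
        if self.free:
            table = project_to_feasible(table, self.p.rho, self.p.bounds)
        return table

    def _soil_from_logx(self, x: np.ndarray) -> SoilParams:
        vals = {}
        for name, xi in zip(SOIL_PARAM_COMPONENTS, x):
            lo, hi = self.p.soil_bounds[name]
            vals[name] = float(np.clip(math.exp(xi), lo, min(hi, 1.0) if name == "runoff_coeff" else hi))
        return SoilParams.from_dict(vals)

    # -- phases -------------------------------------------------------------
    def _grid_start(self, f, x0: np.ndarray) -> np.ndarray:
        """Coarse log-space grid over the free components' bounds.

        The season simulator's objective can have compensation ridges
        (e.g. radiation-use efficiency against flowering time); a cheap grid
        scan keeps Nelder-Mead out of the wrong basin.  Only used while the
        free dimension is small enough to enumerate.
        """
        dim = len(self.free)
        if dim > 3:
            return x0
        pts = {1: max(self.o.grid_points, 9), 2: self.o.grid_points, 3: 5}[dim]
        axes = []
        for name in self.free:
            lo, hi = self.p.bounds[name]
            pad = 0.02 * (math.log(hi) - math.log(lo))
            axes.append(np.linspace(math.log(lo) + pad, math.log(hi) - pad, pts))
        best_x, best_val = x0, f(x0)
        for combo in np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, dim):
            val = f(combo)
            if val < best_val:
                best_x, best_val = combo, val
        return np.asarray(best_x, dtype=float)

    def phase_genotype(self, base, deltas, soils, incumbent):
        if not self.free:
            return base, incumbent
        x0 = np.array([math.log(base[n]) for n in self.free])

        def f(x):
            table = self._table_from_base(self._base_from_logx(x), deltas)
            return self.objective(table, soils)

        if self.o.grid_init:
            x0 = self._grid_start(f, x0)
        res = minimize(
            f, x0, method="Nelder-Mead",
            options={"maxiter": self.o.nm_maxiter, "xatol": 1e-4, "fatol": 1e-8},
        )
        cand = self._base_from_logx(res.x)
        cand_obj = self.objective(self._table_from_base(cand, deltas), soils)
        if cand_obj < incumbent:
            return cand, cand_obj
        return base, incumbent

    def phase_soil(self, base, deltas, soils, incumbent):
        table = self._table_from_base(base, deltas)
        soils = dict(soils)
        for c in self.counties:
            if self.p.fixed_soil is not None and c in self.p.fixed_soil:
                continue
            idx = self.county_idx[c]
            if not idx:
                continue
            obs_c = self.obs[idx]
            area_c = self.areas[idx]
            if np.all(area_c == 0):
                continue
            keys_c = [self.keys[i] for i in idx]

            def f(x, c=c, keys_c=keys_c, obs_c=obs_c, area_c=area_c):
                sp = self._soil_from_logx(x)
                pred = np.array([self._predict_key(k, table[k], sp) for k in keys_c])
                return weighted_rmse(obs_c, pred, area_c)

            x0 = np.array([math.log(getattr(soils[c], n)) for n in SOIL_PARAM_COMPONENTS])
            res = minimize(
                f, x0, method="Nelder-Mead",
                options={"maxiter": self.o.soil_nm_maxiter, "xatol": 1e-4, "fatol": 1e-8},
            )
            cand = self._soil_from_logx(res.x)
            if f(res.x) < f(x0):
                soils[c] = cand
        new_obj = self.objective(table, soils)
        if new_obj < incumbent:
            return soils, new_obj
        return soils, incumbent

    def phase_cells(self, base, deltas, soils, incumbent):
        """Greedy per-cell log-deviation sweep with re-projection."""
        if not self.free:
            return deltas, incumbent
        step = self.o.cell_step
        for k in self.keys:
            for j in range(len(self.free)):
                best_d, best_obj = deltas[k][j], incumbent
                for cand in (deltas[k][j] + step, deltas[k][j] - step):
                    deltas[k][j] = cand
                    obj = self.objective(self._table_from_base(base, deltas), soils)
                    if obj < best_obj:
                        best_d, best_obj = cand, obj
                deltas[k][j] = best_d
                incumbent = best_obj
        return deltas, incumbent

    # -- driver -------------------------------------------------------------
    def run(self) -> CalibrationResult:
        if self.o.init_genotype is not None:
            base = self.o.init_genotype.as_dict()
            base.update(self.p.fixed_components)
        else:
            base = dict(self.p.fixed_components)
            for name in self.free:
                lo, hi = self.p.bounds[name]
                base[name] = math.sqrt(lo * hi)  # geometric midpoint
            for name in GENOTYPE_COMPONENTS:
                if name not in base:
                    lo, hi = self.p.bounds[name]
                    base[name] = math.sqrt(lo * hi)
        base = _make_valid_genotype(base).as_dict()

        if self.p.fixed_soil is not None:
            soils = {c: self.p.fixed_soil[c] for c in self.counties}
        elif self.o.init_soil is not None:
            soils = {c: self.o.init_soil[c] for c in self.counties}
        else:
            nominal = SoilParams.from_dict(DEFAULT_SOIL_PARAM_VALUES)
            soils = {c: nominal for c in self.counties}

        deltas = {k: np.zeros(len(self.free)) for k in self.keys}
        obj = self.objective(self._table_from_base(base, deltas), soils)
        trace = [obj]

        for outer in range(self.o.max_outer):
            start = obj
            base, obj = self.phase_genotype(base, deltas, soils, obj)
            if obj < trace[-1]:
                trace.append(obj)
            if self.o.fit_soil and self.p.fixed_soil is None:
                soils, obj = self.phase_soil(base, deltas, soils, obj)
                if obj < trace[-1]:
                    trace.append(obj)
            for _ in range(self.o.cell_sweeps):
                deltas, obj = self.phase_cells(base, deltas, soils, obj)
                if obj < trace[-1]:
                    trace.append(obj)
            if start > 0 and (start - obj) / start < self.o.rel_tol:
                break

        table = self._table_from_base(base, deltas)
        fitted = {k: self._predict_key(k, table[k], soils[k[1]]) for k in self.keys}
        final_obj = weighted_rmse(
            self.obs, np.array([fitted[k] for k in self.keys]), self.areas
        )
        if final_obj < trace[-1]:
            trace.append(final_obj)
        return CalibrationResult(
            genotypes=table,
            soil_params=soils,
            objective=final_obj,
            fitted_yields=fitted,
            trace=trace,
        )


def fit(problem: CalibrationProblem, options: FitOptions | None = None) -> CalibrationResult:
    """Calibrate genotype tables and soil parameters against observed yields.

    Deterministic given ``options.seed`` (all phases are in fact
    deterministic; the seed is reserved for stochastic search variants).
    The returned trace of accepted objective values is non-increasing and
    the genotype table satisfies the ratio band and bounds.
    """
    options = options or FitOptions()
    return _Fitter(problem, options).run()
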