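"""Readers/writers for the tabular inputs and outputs, plus imputation.

All tables are comma-separated text with mandatory headers and a sidecar
``units.yaml`` contract, matching the export shapes of the public sources
(county yield surveys, gridded daily weather, soil survey summaries).
Dates are (year, 1-based day-of-year) integers; densities are stored per
hectare (a per-acre column is converted on load).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult
from .errors import ImputationError, LoadError
from .types import (
    Dataset,
    GENOTYPE_COMPONENTS,
    Genotype,
    Management,
    SOIL_PARAM_COMPONENTS,
    SoilParams,
    SoilProfile,
    WeatherSeries,
)

logger = logging.getLogger(__name__)

ACRE_PER_HA = 2.47105

SCHEMAS: dict[str, list[str]] = {
    "yields": ["year", "county", "state", "yield_mg_ha", "area_ha"],
    "weather": ["county", "year", "doy", "tmax_c", "tmin_c", "prcp_mm",
                "srad_mj_m2", "vp_kpa"],
    "soil": ["county", "capacity_mm", "init_fraction", "x", "y"],
    "management": ["year", "county", "plant_doy", "harvest_doy", "density_per_ha"],
}

UNITS: dict[str, dict[str, str]] = {
    "yields": {"yield_mg_ha": "Mg/ha", "area_ha": "ha"},
    "weather": {"tmax_c": "degC", "tmin_c": "degC", "prcp_mm": "mm/day",
                "srad_mj_m2": "MJ/m2/day", "vp_kpa": "kPa"},
    "soil": {"capacity_mm": "mm", "init_fraction": "fraction"},
    "management": {"density_per_ha": "plants/ha"},
}


@dataclass
class DatasetBundle:
    """The four delimited tables as DataFrames."""

    yields: pd.DataFrame
    weather: pd.DataFrame
    soil: pd.DataFrame
    management: pd.DataFrame


def daymet_radiation_to_daily_total(srad_wm2, daylength_s):
    """Convert a daylight-mean shortwave flux (W/m2) and day length (s) to a
    daily total in MJ m-2 day-1."""
    srad = np.asarray(srad_wm2, dtype=float)
    dl = np.asarray(daylength_s, dtype=float)
    if np.any(srad < 0) or np.any(dl < 0):
        raise LoadError("srad and daylength must be >= 0")
    out = srad * dl / 1e6
    return float(out) if out.ndim == 0 else out


def _check_header(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in SCHEMAS[table] if c not in df.columns]
    if missing:
        raise LoadError(f"{table} table is missing column(s): {', '.join(missing)}")


def save_bundle(bundle: DatasetBundle, directory: str | Path) -> None:
    """Write the four CSV tables and the units sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        getattr(bundle, name).to_csv(directory / f"{name}.csv", index=False)
    with open(directory / "units.yaml", "w") as fh:
        yaml.safe_dump(UNITS, fh)


def load_bundle(directory: str | Path, drop_missing_yields: bool = True) -> DatasetBundle:
    """Load and validate the four CSV tables.

    Header mismatches, unit-contract mismatches and duplicate (year, county)
    yield rows raise :class:`LoadError`; rows with a missing yield are
    dropped (and counted in the log), mirroring how survey gaps are excluded
    upstream.
    """
    directory = Path(directory)
    frames = {}
    for name in SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise LoadError(f"missing table file {path}")
        frames[name] = pd.read_csv(path)
        _check_header(frames[name], name)
    units_path = directory / "units.yaml"
    if units_path.exists():
        with open(units_path) as fh:
            declared = yaml.safe_load(fh) or {}
        for table, cols in UNITS.items():
            for col, unit in cols.items():
                got = declared.get(table, {}).get(col)
                if got is not None and got != unit:
                    raise LoadError(
                        f"unit mismatch for {table}.{col}: file says {got!r}, expected {unit!r}"
                    )

    ydf = frames["yields"]
    dup = ydf.duplicated(subset=["year", "county"])
    if dup.any():
        raise LoadError(f"duplicate (year, county) yield rows: {int(dup.sum())}")
    if drop_missing_yields:
        n0 = len(ydf)
        ydf = ydf.dropna(subset=["yield_mg_ha"]).reset_index(drop=True)
        dropped = n0 - len(ydf)
        if dropped:
            logger.info("dropped %d yield rows with missing values", dropped)
        frames["yields"] = ydf

    mdf = frames["management"]
    if "density_per_acre" in mdf.columns and "density_per_ha" not in mdf.columns:
        mdf["density_per_ha"] = mdf["density_per_acre"] * ACRE_PER_HA
    return DatasetBundle(**frames)


def impute_density(management: pd.DataFrame) -> pd.DataFrame:
    """Fill missing plant densities with the state mean, else the global mean.

    Requires a ``state`` column (state-level management broadcast to
    counties).  Adds a ``density_imputed`` provenance column
    ("observed" / "state_mean" / "global_mean").
    """
    df = management.copy()
    if "state" not in df.columns:
        raise LoadError("impute_density requires a 'state' column")
    col = "density_per_ha"
    if df[col].notna().sum() == 0:
        raise ImputationError("all plant densities are missing")
    df["density_imputed"] = np.where(df[col].notna(), "observed", "state_mean")
    state_means = df.groupby("state")[col].transform("mean")
    global_mean = df[col].mean()
    filled = df[col].fillna(state_means)
    df.loc[filled.isna(), "density_imputed"] = "global_mean"
    df[col] = filled.fillna(global_mean)
    return df


# -- bundle <-> in-memory dataset -------------------------------------------

def dataset_to_bundle(ds: Dataset) -> DatasetBundle:
    yrows, wrows, srows, mrows = [], [], [], []
    for (t, c), y in sorted(ds.observed_yields.items()):
        yrows.append({
            "year": t, "county": c, "state": ds.states.get(c, ""),
            "yield_mg_ha": y, "area_ha": ds.management[(t, c)].area,
        })
    for (t, c), w in sorted(ds.weather.items()):
        for i in range(len(w)):
            wrows.append({
                "county": c, "year": t, "doy": int(w.doy[i]),
                "tmax_c": w.tmax[i], "tmin_c": w.tmin[i], "prcp_mm": w.prcp[i],
                "srad_mj_m2": w.srad[i], "vp_kpa": w.vp[i],
            })
    for c, p in sorted(ds.soil.items()):
        srows.append({"county": c, "capacity_mm": p.capacity_mm,
                      "init_fraction": p.init_fraction, "x": p.x, "y": p.y})
    for (t, c), m in sorted(ds.management.items()):
        mrows.append({"year": t, "county": c, "plant_doy": m.plant_doy,
                      "harvest_doy": m.harvest_doy, "density_per_ha": m.density})
    return DatasetBundle(
        yields=pd.DataFrame(yrows), weather=pd.DataFrame(wrows),
        soil=pd.DataFrame(srows), management=pd.DataFrame(mrows),
    )


def bundle_to_dataset(bundle: DatasetBundle) -> Dataset:
    soil = {
        int(r.county): SoilProfile(r.capacity_mm, r.init_fraction, r.x, r.y)
        for r in bundle.soil.itertuples()
    }
    areas = {
        (int(r.year), int(r.county)): float(r.area_ha)
        for r in bundle.yields.itertuples()
    }
    management = {}
    for r in bundle.management.itertuples():
        key = (int(r.year), int(r.county))
        management[key] = Management(
            plant_doy=int(r.plant_doy), harvest_doy=int(r.harvest_doy),
            density=float(r.density_per_ha), area=areas.get(key, 0.0),
        )
    weather = {}
    for (t, c), grp in bundle.weather.groupby(["year", "county"]):
        grp = grp.sort_values("doy")
        weather[(int(t), int(c))] = WeatherSeries(
            doy=grp["doy"].to_numpy(), tmax=grp["tmax_c"].to_numpy(),
            tmin=grp["tmin_c"].to_numpy(), prcp=grp["prcp_mm"].to_numpy(),
            srad=grp["srad_mj_m2"].to_numpy(), vp=grp["vp_kpa"].to_numpy(),
        )
    observed = {
        (int(r.year), int(r.county)): float(r.yield_mg_ha)
        for r in bundle.yields.itertuples()
    }
    states = {int(r.county): str(r.state) for r in bundle.yields.itertuples()}
    ds = Dataset(weather=weather, soil=soil, management=management,
                 observed_yields=observed, states=states)
    ds.validate_keys()
    return ds


# -- calibration result persistence -----------------------------------------

def save_calibration(calib: CalibrationResult, directory: str | Path) -> None:
    """Persist a calibration as long-format CSVs plus a JSON meta file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grows = [
        {"year": t, "county": c, "component": comp, "value": getattr(g, comp)}
        for (t, c), g in sorted(calib.genotypes.items())
        for comp in GENOTYPE_COMPONENTS
    ]
    pd.DataFrame(grows).to_csv(directory / "genotypes.csv", index=False)
    srows = [
        {"county": c, "component": comp, "value": getattr(s, comp)}
        for c, s in sorted(calib.soil_params.items())
        for comp in SOIL_PARAM_COMPONENTS
    ]
    pd.DataFrame(srows).to_csv(directory / "soil_params.csv", index=False)
    frows = [
        {"year": t, "county": c, "fitted_yield_mg_ha": y}
        for (t, c), y in sorted(calib.fitted_yields.items())
    ]
    pd.DataFrame(frows).to_csv(directory / "fitted_yields.csv", index=False)
    with open(directory / "calibration.json", "w") as fh:
        json.dump({"objective": calib.objective, "trace": calib.trace}, fh, indent=2)


def load_calibration(directory: str | Path) -> CalibrationResult:
    directory = Path(directory)
    gdf = pd.read_csv(directory / "genotypes.csv")
    genotypes = {}
    for (t, c), grp in gdf.groupby(["year", "county"]):
        vals = dict(zip(grp["component"], grp["value"]))
        genotypes[(int(t), int(c))] = Genotype.from_dict(vals)
    sdf = pd.read_csv(directory / "soil_params.csv")
    soil_params = {}
    for c, grp in sdf.groupby("county"):
        soil_params[int(c)] = SoilParams.from_dict(dict(zip(grp["component"], grp["value"])))
    fdf = pd.read_csv(directory / "fitted_yields.csv")
    fitted = {
        (int(r.year), int(r.county)): float(r.fitted_yield_mg_ha)
        for r in fdf.itertuples()
    }
    with open(directory / "calibration.json") as fh:
        meta = json.load(fh)
    return CalibrationResult(
        genotypes=genotypes, soil_params=soil_params,
        objective=meta["objective"], fitted_yields=fitted, trace=meta["trace"],
    )
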