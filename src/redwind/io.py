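"""Reading and writing the pipeline's file formats.

Areas travel as GeoJSON FeatureCollections (geometry via shapely's GeoJSON
mapping), tabular stages as CSV, and ground truth as JSON.  Generator and
emissions CSVs accept EIA-860 / eGRID-style column names through an
optional column-mapping block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import GroundTruth
from .wind import WindGrid

__all__ = [
    "write_areas_geojson",
    "read_areas_geojson",
    "write_csv",
    "read_generators_csv",
    "read_emissions_csv",
    "write_wind_csv",
    "read_wind_csv",
    "write_ground_truth",
    "read_ground_truth",
]

AREA_PROPERTIES = [
    "area_id", "city", "state", "region", "grade", "city_population_1940",
    "pct_foreign_born", "pct_black", "median_household_income",
    "median_building_age", "occupation", "repair_status", "mortgage_availability",
]

#: EIA-860-like column synonyms accepted on read.
GENERATOR_COLUMN_MAP = {
    "plant_code": "plant_id",
    "nameplate_capacity": "nameplate_capacity_mw",
    "energy_source_1": "energy_source",
    "operating_year": "first_operation_year",
    "retirement_year": "retirement_year",
}

EMISSIONS_COLUMN_MAP = {
    "orispl": "plant_id",
    "plnox": "nox_tons",
    "plso2": "so2_tons",
    "plpm25": "pm25_tons",
}


def write_areas_geojson(areas: pd.DataFrame, path) -> None:
    features = []
    for rec in areas.to_dict("records"):
        geom = rec.pop("geometry")
        props = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in rec.items()
        }
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_areas_geojson(path, drop_e_grade: bool = True) -> pd.DataFrame:
    """Load graded neighbourhood polygons; E-graded areas are dropped at
    ingest (they were excluded from the analysis) with their count logged."""
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        rec = dict(feat["properties"])
        rec["geometry"] = shape(feat["geometry"])
        rows.append(rec)
    df = pd.DataFrame(rows)
    if drop_e_grade and "grade" in df:
        df = df.loc[df["grade"].isin(["A", "B", "C", "D"])].reset_index(drop=True)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _apply_column_map(df: pd.DataFrame, default_map: dict, user_map: dict | None):
    rename = {k: v for k, v in default_map.items() if k in df.columns}
    if user_map:
        rename.update(user_map)
    return df.rename(columns=rename)


def read_generators_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _apply_column_map(df, GENERATOR_COLUMN_MAP, column_map)


def read_emissions_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _apply_column_map(df, EMISSIONS_COLUMN_MAP, column_map)


def write_wind_csv(grid: WindGrid, path) -> None:
    grid.to_dataframe().to_csv(path, index=False)


def read_wind_csv(path) -> WindGrid:
    return WindGrid.from_dataframe(pd.read_csv(path))


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
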