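"""Reading, validating and writing county-level prevalence tables and area polygons.

The analysis operates on one record per area: an identifier, an observed
prevalence proportion strictly inside (0, 1), and a vector of covariates in
percent units. Geometry arrives as GeoJSON polygons (used for contiguity and
choropleths) or is bypassed entirely with a plain adjacency edge list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.geometry

logger = logging.getLogger("betabym")

__all__ = [
    "CountyTable",
    "PolygonSet",
    "ValidationReport",
    "read_county_table",
    "county_table_from_frame",
    "write_county_table",
    "validate_county_table",
    "read_polygons",
    "write_polygons",
]


class SchemaError(ValueError):
    """A required column is missing or the schema is inconsistent."""


class DomainError(ValueError):
    """A value lies outside the domain the model requires."""


class IntegrityError(ValueError):
    """Duplicate identifiers or misaligned inputs."""


@dataclass
class CountyTable:
    """County-level outcome and covariates, in the canonical area order.

    ``y`` holds the observed prevalence proportions (strictly in (0, 1));
    ``X`` is an (n_areas, k) covariate matrix in percent units, rows aligned
    with ``area_id``. Every downstream module uses this row order.
    """

    area_id: list[str]
    area_name: list[str]
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.size == 0:
            self.X = np.zeros((len(self.y), 0))
        if self.X.shape[0] != len(self.y):
            self.X = self.X.T
        if self.X.shape[0] != len(self.y):
            raise IntegrityError(
                f"covariate matrix has {self.X.shape[0]} rows for {len(self.y)} areas"
            )

    @property
    def n_areas(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": self.area_id, "area_name": self.area_name, "y": self.y})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df


@dataclass
class PolygonSet:
    """One (multi)polygon per area, keyed by area_id."""

    area_id: list[str]
    geometry: list  # shapely (Multi)Polygon, aligned with area_id

    def __len__(self) -> int:
        return len(self.area_id)

    def aligned_to(self, ids: list[str]) -> "PolygonSet":
        """Reorder to match an external id order; every id must be present."""
        lookup = dict(zip(self.area_id, self.geometry))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise IntegrityError(f"areas without geometry: {missing}")
        return PolygonSet(list(ids), [lookup[i] for i in ids])


@dataclass
class ValidationReport:
    issues: list[tuple[str, str, str]] = field(default_factory=list)  # (severity, where, message)

    @property
    def status(self) -> str:
        return "fail" if any(sev == "error" for sev, _, _ in self.issues) else "pass"

    @property
    def ok(self) -> bool:
        return self.status == "pass"


def _check_outcome(values: np.ndarray, ids: list[str], unit: str) -> np.ndarray:
    lo, hi = (0.0, 100.0) if unit == "percent" else (0.0, 1.0)
    bad = ~(np.isfinite(values) & (values > lo) & (values < hi))
    if bad.any():
        offenders = [ids[i] for i in np.flatnonzero(bad)]
        raise DomainError(
            f"outcome must lie strictly in ({lo}, {hi}) for unit={unit}; "
            f"violated by area_id {offenders}"
        )
    return values / 100.0 if unit == "percent" else values.copy()


def county_table_from_frame(
    df: pd.DataFrame,
    *,
    id_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    name_col: str | None = None,
    outcome_unit: str = "percent",
    standardize: bool = False,
) -> CountyTable:
    """Build a CountyTable from a DataFrame, converting percent outcomes to proportions."""
    if outcome_unit not in ("percent", "proportion"):
        raise ValueError("outcome_unit must be 'percent' or 'proportion'")
    needed = [id_col, outcome_col] + (covariate_cols or []) + ([name_col] if name_col else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}; available: {list(df.columns)}")

    ids = [str(v) for v in df[id_col]]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise IntegrityError(f"duplicate area_id: {dupes}")
    names = [str(v) for v in df[name_col]] if name_col else list(ids)

    y = _check_outcome(df[outcome_col].to_numpy(dtype=float), ids, outcome_unit)

    cov = covariate_cols or []
    X = df[cov].to_numpy(dtype=float) if cov else np.zeros((len(ids), 0))
    if np.isnan(X).any():
        bad_cols = [c for c in cov if df[c].isna().any()]
        raise DomainError(f"missing covariate values in column(s): {bad_cols}")
    if standardize and X.shape[1]:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    return CountyTable(ids, names, y, X, list(cov))


def read_county_table(
    path,
    *,
    id_col: str,
    outcome_col: str,
    covariate_cols: list[str] | None = None,
    name_col: str | None = None,
    outcome_unit: str = "percent",
    standardize: bool = False,
) -> CountyTable:
    """Read a UTF-8 CSV with a header row into a validated CountyTable.

    Outcomes given as percentages are divided by 100; values on or outside the
    boundary of the open interval are rejected (the beta likelihood has no mass
    at 0 or 1). Missing covariate cells raise rather than being imputed.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if covariate_cols is None:
        reserved = {id_col, outcome_col, name_col}
        covariate_cols = [
            c for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
        dropped = [c for c in df.columns if c not in reserved and c not in covariate_cols]
        if dropped:
            logger.info("ignoring non-numeric column(s) %s", dropped)
    return county_table_from_frame(
        df,
        id_col=id_col,
        outcome_col=outcome_col,
        covariate_cols=covariate_cols,
        name_col=name_col,
        outcome_unit=outcome_unit,
        standardize=standardize,
    )


def write_county_table(table: CountyTable, path) -> None:
    """Write the table as CSV (proportions, full float precision)."""
    table.to_frame().to_csv(path, index=False)


def validate_county_table(table: CountyTable) -> ValidationReport:
    """Report every invariant violation; zero-variance covariates are warnings."""
    report = ValidationReport()
    seen: set[str] = set()
    for aid in table.area_id:
        if aid in seen:
            report.issues.append(("error", aid, "duplicate area_id"))
        seen.add(aid)
    bad = ~(np.isfinite(table.y) & (table.y > 0) & (table.y < 1))
    for i in np.flatnonzero(bad):
        report.issues.append(("error", table.area_id[i], f"outcome {table.y[i]} not in (0,1)"))
    if np.isnan(table.X).any():
        for j in np.flatnonzero(np.isnan(table.X).any(axis=0)):
            report.issues.append(("error", table.covariate_names[j], "missing covariate values"))
    for j in range(table.n_covariates):
        col = table.X[:, j]
        if np.isfinite(col).all() and np.ptp(col) == 0:
            report.issues.append(
                ("warning", table.covariate_names[j], "covariate has zero variance")
            )
    return report


def read_polygons(path, id_property: str) -> PolygonSet:
    """Read a GeoJSON FeatureCollection; invalid geometries are repaired by buffer(0)."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    features = gj.get("features")
    if features is None:
        raise SchemaError("not a GeoJSON FeatureCollection (no 'features' key)")
    ids: list[str] = []
    geoms: list = []
    for idx, feat in enumerate(features):
        props = feat.get("properties") or {}
        if id_property not in props or props[id_property] is None:
            raise SchemaError(f"feature {idx} lacks id property '{id_property}'")
        aid = str(props[id_property])
        if aid in ids:
            raise IntegrityError(f"two features share area_id '{aid}'")
        geom = shapely.geometry.shape(feat["geometry"])
        if not geom.is_valid:
            logger.warning("repairing invalid geometry for area %s via buffer(0)", aid)
            geom = geom.buffer(0)
        ids.append(aid)
        geoms.append(geom)
    return PolygonSet(ids, geoms)


def write_polygons(polygons: PolygonSet, path, id_property: str = "area_id") -> None:
    features = [
        {
            "type": "Feature",
            "properties": {id_property: aid},
            "geometry": shapely.geometry.mapping(geom),
        }
        for aid, geom in zip(polygons.area_id, polygons.geometry)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
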