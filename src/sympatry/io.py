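"""Readers and writers for pair tables, polygons, configs and truth files.

All tables are comma-separated UTF-8 with a header row and '.' decimals.
Polygon coordinates are planar equal-area units; no CRS handling happens
here (projection is upstream of the package).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as _wkt

from .geometry import InvalidGeometryError, RangePolygon, classify_overlap
from .simulator import SimConfig

__all__ = [
    "PairRecord",
    "SchemaError",
    "RowError",
    "read_pair_table",
    "write_pair_table",
    "read_polygons",
    "write_polygons",
    "read_sweep",
    "write_sweep",
    "load_config",
    "save_config",
    "save_truth",
]


class SchemaError(ValueError):
    """The file is structurally unusable (missing columns, empty, ...)."""


class RowError(ValueError):
    """A row violates an invariant; the message carries the line number."""


@dataclass(frozen=True)
class PairRecord:
    """One sister-species comparison."""

    pair_id: str
    species_a: str
    species_b: str
    branch_length_my: float
    overlap_index: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.branch_length_my <= 0:
            raise ValueError(
                f"pair {self.pair_id}: branch_length_my must be positive"
            )
        if self.overlap_index is not None:
            if not 0 <= self.overlap_index <= 1:
                raise ValueError(
                    f"pair {self.pair_id}: overlap_index "
                    f"{self.overlap_index} outside [0, 1]"
                )
            object.__setattr__(self, "category", classify_overlap(self.overlap_index))


_REQUIRED = ["pair_id", "species_a", "species_b", "branch_length_my"]


def read_pair_table(path: str | Path) -> list[PairRecord]:
    """Read and validate a sister-pair CSV.

    Required columns: pair_id, species_a, species_b, branch_length_my;
    overlap_index is optional (absent when polygons are supplied
    instead).  Rows failing invariants raise :class:`RowError` naming
    the offending line and field.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    has_overlap = "overlap_index" in df.columns
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            bl = float(row["branch_length_my"])
        except (TypeError, ValueError) as exc:
            raise RowError(
                f"{path}:{line}: unparsable branch_length_my "
                f"{row['branch_length_my']!r}"
            ) from exc
        overlap = None
        if has_overlap and not pd.isna(row["overlap_index"]):
            try:
                overlap = float(row["overlap_index"])
            except (TypeError, ValueError) as exc:
                raise RowError(
                    f"{path}:{line}: unparsable overlap_index "
                    f"{row['overlap_index']!r}"
                ) from exc
        try:
            records.append(
                PairRecord(
                    pair_id=str(row["pair_id"]),
                    species_a=str(row["species_a"]),
                    species_b=str(row["species_b"]),
                    branch_length_my=bl,
                    overlap_index=overlap,
                )
            )
        except ValueError as exc:
            raise RowError(f"{path}:{line}: {exc}") from exc
    return records


def write_pair_table(records, path: str | Path) -> None:
    """Write pair records (or an equivalent DataFrame) as CSV."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, index=False)


def _polygon_from_geojson(feature: dict, path: Path) -> tuple[str, RangePolygon]:
    props = feature.get("properties") or {}
    if "species_id" not in props:
        raise SchemaError(f"{path}: feature lacks a species_id property")
    sp = str(props["species_id"])
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise SchemaError(f"{path}: geometry for {sp} is not a Polygon")
    rings = geom.get("coordinates") or []
    if not rings:
        raise SchemaError(f"{path}: empty coordinates for {sp}")
    exterior = [tuple(pt) for pt in rings[0]]
    if len(exterior) > 1 and exterior[0] == exterior[-1]:
        exterior = exterior[:-1]  # drop the GeoJSON closing vertex
    return sp, RangePolygon(vertices=tuple(exterior), species_id=sp)


def read_polygons(path: str | Path) -> dict[str, RangePolygon]:
    """Read species range polygons from GeoJSON or a species_id/wkt CSV.

    GeoJSON input is a FeatureCollection of Polygon features (exterior
    ring only) each carrying a ``species_id`` property; the CSV variant
    has columns ``species_id`` and ``wkt`` with POLYGON geometries.
    Duplicate species and invalid rings are reported by species name.
    """
    path = Path(path)
    out: dict[str, RangePolygon] = {}

    def _add(sp: str, poly: RangePolygon) -> None:
        if sp in out:
            raise SchemaError(f"{path}: duplicate species_id {sp!r}")
        out[sp] = poly

    if path.suffix.lower() in (".json", ".geojson"):
        data = json.loads(path.read_text())
        feats = data.get("features")
        if data.get("type") != "FeatureCollection" or feats is None:
            raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
        for feature in feats:
            _add(*_polygon_from_geojson(feature, path))
    else:
        df = pd.read_csv(path)
        for col in ("species_id", "wkt"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing column {col!r}")
        for _, row in df.iterrows():
            sp = str(row["species_id"])
            geom = _wkt.loads(row["wkt"])
            if geom.geom_type != "Polygon":
                raise InvalidGeometryError(f"{path}: {sp}: not a POLYGON")
            coords = tuple(geom.exterior.coords)[:-1]
            _add(sp, RangePolygon(vertices=coords, species_id=sp))
    if not out:
        raise SchemaError(f"{path}: no polygons found")
    return out


def write_polygons(polygons: dict[str, RangePolygon], path: str | Path) -> None:
    """Write polygons as a GeoJSON FeatureCollection."""
    features = []
    for sp, poly in polygons.items():
        ring = [list(v) for v in poly.vertices] + [list(poly.vertices[0])]
        features.append(
            {
                "type": "Feature",
                "properties": {"species_id": sp},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_sweep(path: str | Path) -> pd.DataFrame:
    """Read a simulation sweep table written by :func:`write_sweep`."""
    df = pd.read_csv(path)
    needed = {"n_sympatric", "z", "c", "bimodality"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"{path}: not a sweep table (needs {sorted(needed)})")
    return df


def write_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    sweep.to_csv(path, index=False)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimConfig)} - {"split_sampler"}


def load_config(path: str | Path) -> SimConfig:
    """Load a flat YAML mapping of SimConfig fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return SimConfig(**data)


def save_config(config: SimConfig, path: str | Path) -> None:
    data = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k in _CONFIG_FIELDS and v is not None
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_truth(truth: dict[str, Any], path: str | Path) -> None:
    """Write a generator truth dictionary as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=_default))
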