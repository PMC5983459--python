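"""Readers, writers and run configuration.

Tabular data is CSV (UTF-8, comma-separated, mandatory header, decimal
point regardless of locale); vector data is GeoJSON. Validation never
silently mutates input: every dropped row and repaired geometry is counted
and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from . import __version__
from .geo_core import Grid, LandraceRecord, is_geographic_crs, repair
from .indices import LandCoverPolygon

logger = logging.getLogger(__name__)

SUPPORTED_VECTOR_FORMATS = (".geojson", ".json")

_RECORD_COLUMNS = ("record_id", "landrace_name", "species")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, loadable from a YAML file."""

    records_path: str | None = None
    protected_paths: list[str] = field(default_factory=list)
    landcover_path: str | None = None
    territory_path: str | None = None
    crs_id: str = "EPSG:32632"
    cell_size: float = 20_000.0
    landcover_code_field: str = "clc_code"
    non_artificial_classes: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    # threshold overrides (None -> defaults: 1 / median H' / 20% / 90%)
    ldi_min: float = 1.0
    h_min: float | None = None
    pws_min_pct: float = 20.0
    aed_min_pct: float = 90.0
    # normalization maxima (None -> recompute from the index table)
    ldi_max: float | None = None
    h_max: float | None = None
    output_dir: str = "outputs"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not set(self.non_artificial_classes) <= {1, 2, 3, 4, 5}:
            raise ValueError("non_artificial_classes must be a subset of 1..5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)


def load_records(path: str | Path, crs_id: str | None = None) -> list[LandraceRecord]:
    """Read landrace occurrence records from CSV.

    Requires columns ``record_id, landrace_name, species, x, y`` with
    projected metre coordinates. Geographic coordinates are not accepted:
    a ``lat``/``lon`` file or a declared geographic CRS raises, since all
    computation runs in one projected CRS and inputs must arrive in it.
    Rows with missing species or unparseable coordinates are dropped, with
    one logged count per reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"records file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if {"lat", "lon"} <= set(df.columns) or (crs_id and is_geographic_crs(crs_id)):
        raise ValueError(
            "geographic (lat/lon) coordinates are not supported: supply "
            "projected metre x/y in the working CRS"
        )
    missing = [c for c in (*_RECORD_COLUMNS, "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} is missing columns: {missing}")
    if df.empty:
        logger.warning("records file %s holds a header but no rows", path)
        return []

    n_no_species = df["species"].isna() | (df["species"].str.strip() == "")
    coords = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    n_bad_coord = coords["x"].isna() | coords["y"].isna()
    keep = ~(n_no_species | n_bad_coord)
    if n_no_species.any():
        logger.warning("dropped %d row(s) lacking species", int(n_no_species.sum()))
    if n_bad_coord.any():
        logger.warning(
            "dropped %d row(s) with unparseable coordinates", int(n_bad_coord.sum())
        )
    out = []
    for row, x, y in zip(
        df.loc[keep].itertuples(index=False), coords.loc[keep, "x"], coords.loc[keep, "y"]
    ):
        out.append(
            LandraceRecord(
                record_id=str(row.record_id),
                landrace_name=str(row.landrace_name),
                species=str(row.species),
                x=float(x),
                y=float(y),
            )
        )
    return out


def load_polygons(
    path: str | Path, crs_id: str | None = None, code_field: str | None = None
) -> list[BaseGeometry] | list[LandCoverPolygon]:
    """Read a polygon layer from GeoJSON.

    Invalid geometries are repaired (with a logged count); when
    ``code_field`` is given each polygon carries its class code and the
    return type is ``LandCoverPolygon``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    if path.suffix.lower() not in SUPPORTED_VECTOR_FORMATS:
        raise ValueError(
            f"unsupported vector format {path.suffix!r}: supported formats are "
            + ", ".join(SUPPORTED_VECTOR_FORMATS)
        )
    if crs_id and is_geographic_crs(crs_id):
        raise ValueError("geographic CRS layers are not supported; reproject first")
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]

    n_repaired = 0
    geoms: list[BaseGeometry] = []
    codes: list[str] = []
    for feat in features:
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = repair(geom)
            n_repaired += 1
        geoms.append(geom)
        if code_field is not None:
            props = feat.get("properties") or {}
            if code_field not in props:
                raise ValueError(
                    f"code field {code_field!r} not found; available fields: "
                    f"{sorted(props)}"
                )
            codes.append(str(props[code_field]))
    if n_repaired:
        logger.warning("repaired %d invalid geometry(ies) in %s", n_repaired, path)
    if code_field is None:
        return geoms
    return [LandCoverPolygon(g, c) for g, c in zip(geoms, codes)]


def write_geojson(
    path: str | Path,
    geometries: Sequence[BaseGeometry],
    properties: Sequence[Mapping] | None = None,
) -> None:
    features = []
    for i, geom in enumerate(geometries):
        props = dict(properties[i]) if properties is not None else {}
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    output_dir: str | Path,
    *,
    index_table: pd.DataFrame,
    mapa_result: pd.DataFrame,
    grid: Grid,
    composition_rs: pd.DataFrame | None = None,
    composition_as: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    strategy: str = "both",
) -> dict[str, Path]:
    """Write all run artifacts and a metadata JSON; returns written paths.

    Floating values are written at full precision — rounding is for
    reports only. The metadata echoes the configuration, the seed, input
    checksums and library versions so a run can be reproduced exactly.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out / "indices.csv"
    index_table.to_csv(p, index=False)
    written["indices"] = p

    p = out / "mapa_result.csv"
    mapa_result.to_csv(p, index=False)
    written["mapa_result"] = p

    geom_by_id = {q.id: q.geometry for q in grid}
    for strat, col in (("rs", "rs_pass"), ("as", "as_pass")):
        if strategy not in ("both", strat):
            continue
        sel = mapa_result.loc[mapa_result[col], "quadrant_id"]
        p = out / f"mapas_{strat}.geojson"
        write_geojson(
            p,
            [geom_by_id[q] for q in sel],
            [{"quadrant_id": q, "strategy": strat.upper()} for q in sel],
        )
        written[f"mapas_{strat}"] = p

    for name, comp in (("rs", composition_rs), ("as", composition_as)):
        if comp is None or strategy not in ("both", name):
            continue
        p = out / f"species_composition_{name}.csv"
        comp.to_csv(p, index=False)
        written[f"composition_{name}"] = p

    import numpy as np
    import pandas
    import shapely

    checksums = {}
    if config is not None:
        for attr in ("records_path", "landcover_path", "territory_path"):
            value = getattr(config, attr)
            if value and Path(value).exists():
                checksums[attr] = _sha256(Path(value))
        for i, pp in enumerate(config.protected_paths):
            if Path(pp).exists():
                checksums[f"protected_{i}"] = _sha256(Path(pp))
    metadata = {
        "config": asdict(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "general_threshold": mapa_result.attrs.get("general_threshold"),
        "input_checksums": checksums,
        "versions": {
            "agromapa": __version__,
            "numpy": np.__version__,
            "pandas": pandas.__version__,
            "shapely": shapely.__version__,
        },
    }
    p = out / "run_metadata.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, default=str)
    written["metadata"] = p
    return written
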