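"""End-to-end orchestration: inputs -> grid -> indices -> MAPA selection."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geo_core import Grid, Territory, assign_records, build_grid, union_layer
from .indices import compute_all_indices
from .io_config import PipelineConfig, load_polygons, load_records
from .prioritize import (
    NormalizationParams,
    ThresholdSet,
    additive_select,
    species_composition,
)
from .synth_data import Scene


@dataclass
class PipelineResult:
    grid: Grid
    index_table: pd.DataFrame
    mapa_result: pd.DataFrame
    composition_rs: pd.DataFrame
    composition_as: pd.DataFrame
    n_assigned: int
    n_unassigned: int


def run_on_scene(
    scene: Scene,
    thresholds: ThresholdSet | None = None,
    norm: NormalizationParams | None = None,
) -> PipelineResult:
    """Run the full prioritization on an in-memory scene."""
    grid = build_grid(scene.territory, scene.config.cell_size)
    index_table = compute_all_indices(
        grid, scene.records, [scene.protected_a, scene.protected_b], scene.landcover
    )
    mapa = additive_select(index_table, thresholds or ThresholdSet(), norm)
    assignment, unassigned = assign_records(scene.records, grid)
    rs_ids = set(mapa.loc[mapa["rs_pass"], "quadrant_id"])
    as_ids = set(mapa.loc[mapa["as_pass"], "quadrant_id"])
    return PipelineResult(
        grid=grid,
        index_table=index_table,
        mapa_result=mapa,
        composition_rs=species_composition(rs_ids, scene.records, assignment),
        composition_as=species_composition(as_ids, scene.records, assignment),
        n_assigned=len(scene.records) - len(unassigned),
        n_unassigned=len(unassigned),
    )


def run_from_config(config: PipelineConfig) -> PipelineResult:
    """Run the full prioritization from files named in ``config``."""
    if config.territory_path is None:
        raise ValueError("config.territory_path is required")
    territory_geoms = load_polygons(config.territory_path, config.crs_id)
    territory = Territory(
        boundary=union_layer([territory_geoms]), crs_id=config.crs_id
    )
    grid = build_grid(territory, config.cell_size)

    records = (
        load_records(config.records_path, config.crs_id)
        if config.records_path
        else []
    )
    protected = [
        load_polygons(p, config.crs_id) for p in config.protected_paths
    ]
    landcover = (
        load_polygons(
            config.landcover_path, config.crs_id, code_field=config.landcover_code_field
        )
        if config.landcover_path
        else []
    )
    index_table = compute_all_indices(
        grid,
        records,
        protected,
        landcover,
        non_artificial=frozenset(config.non_artificial_classes),
    )
    thresholds = ThresholdSet(
        ldi_min=config.ldi_min,
        h_min=config.h_min,
        pws_min_pct=config.pws_min_pct,
        aed_min_pct=config.aed_min_pct,
    )
    norm = None
    if config.ldi_max is not None and config.h_max is not None:
        norm = NormalizationParams(ldi_max=config.ldi_max, h_max=config.h_max)
    mapa = additive_select(index_table, thresholds, norm)
    assignment, unassigned = assign_records(records, grid)
    rs_ids = set(mapa.loc[mapa["rs_pass"], "quadrant_id"])
    as_ids = set(mapa.loc[mapa["as_pass"], "quadrant_id"])
    return PipelineResult(
        grid=grid,
        index_table=index_table,
        mapa_result=mapa,
        composition_rs=species_composition(rs_ids, records, assignment),
        composition_as=species_composition(as_ids, records, assignment),
        n_assigned=len(records) - len(unassigned),
        n_unassigned=len(unassigned),
    )


def write_scene(scene: Scene, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a scene to the exact formats the pipeline consumes
    (CSV records + GeoJSON layers), so synthetic runs exercise the real
    I/O path."""
    from .io_config import write_geojson

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = out / "records.csv"
    pd.DataFrame(
        [
            (r.record_id, r.landrace_name, r.species, r.x, r.y)
            for r in scene.records
        ],
        columns=["record_id", "landrace_name", "species", "x", "y"],
    ).to_csv(p, index=False)
    written["records"] = p

    p = out / "territory.geojson"
    write_geojson(p, [scene.territory.boundary])
    written["territory"] = p
    for name, layer in (("protected_a", scene.protected_a), ("protected_b", scene.protected_b)):
        p = out / f"{name}.geojson"
        write_geojson(p, list(layer))
        written[name] = p
    p = out / "landcover.geojson"
    write_geojson(
        p,
        [lc.geometry for lc in scene.landcover],
        [{"clc_code": lc.clc_code} for lc in scene.landcover],
    )
    written["landcover"] = p
    return written


def scene_config(scene_dir: str | Path, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at a directory written by ``write_scene``."""
    d = Path(scene_dir)
    defaults = dict(
        records_path=str(d / "records.csv"),
        territory_path=str(d / "territory.geojson"),
        protected_paths=[str(d / "protected_a.geojson"), str(d / "protected_b.geojson")],
        landcover_path=str(d / "landcover.geojson"),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
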