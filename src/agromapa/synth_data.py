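"""Synthetic landscapes for end-to-end testing of the MAPA pipeline.

Generates all four inputs — territory, landrace occurrence records, two
protected-area layers with controlled mutual overlap, and a land-cover
mosaic with controlled class proportions — with every random draw tied to
one seed. Protected areas and land cover are built from axis-aligned
rectangles/tiles so every expected area is closed-form and hand-checkable;
no attempt is made at realistic landscape shapes.

Default parameters emulate, at reduced extent, the study system the
pipeline targets: a 100x100 km territory gridded into 25 quadrants of
20x20 km; ~240 landraces of ~33 species (about 7 landraces per species and
2 accessions per landrace, the ratios of the Italian landrace inventory);
protected cover around 20% of the territory (Natura 2000 covers ~22% of
Italy) with the two protected layers overlapping heavily; land cover
dominated by agriculture and forest/semi-natural classes with ~5%
artificial surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geo_core import LandraceRecord, Territory
from .indices import LandCoverPolygon

#: Representative 3-digit codes, one per level-1 land-cover class.
_LEVEL1_CODES = {1: "112", 2: "211", 3: "311", 4: "411", 5: "511"}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic scene generator (distances in metres)."""

    seed: int = 0
    territory_size: float = 100_000.0
    cell_size: float = 20_000.0
    n_species: int = 33
    n_landraces: int = 240
    accessions_per_landrace: float = 2.0
    species_abundance: float = 0.5  # Dirichlet concentration over species
    n_clusters: int = 8
    cluster_dispersion: float = 10_000.0
    protected_fraction: float = 0.20
    protected_overlap: float = 0.5  # fraction of layer 2 inside layer 1
    landcover_class_props: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.45, 3: 0.45, 4: 0.02, 5: 0.03}
    )
    crs_id: str = "EPSG:32632"

    def __post_init__(self) -> None:
        if not 0.0 <= self.protected_fraction <= 1.0:
            raise ValueError("protected_fraction must lie in [0, 1]")
        if not 0.0 <= self.protected_overlap <= 1.0:
            raise ValueError("protected_overlap must lie in [0, 1]")
        props = self.landcover_class_props
        if any(p < 0 for p in props.values()) or sum(props.values()) > 1.0 + 1e-9:
            raise ValueError(
                "landcover class proportions must be non-negative and sum to <= 1"
            )
        if any(c not in (1, 2, 3, 4, 5) for c in props):
            raise ValueError("landcover classes must be in 1..5")


@dataclass(frozen=True)
class Scene:
    """One generated landscape: the pipeline's four inputs plus config."""

    territory: Territory
    records: tuple[LandraceRecord, ...]
    protected_a: tuple[BaseGeometry, ...]
    protected_b: tuple[BaseGeometry, ...]
    landcover: tuple[LandCoverPolygon, ...]
    config: SynthConfig


def _sample_records(
    rng: np.random.Generator, cfg: SynthConfig
) -> tuple[LandraceRecord, ...]:
    """Dirichlet-multinomial species assignment, clustered accession points."""
    probs = rng.dirichlet(np.full(cfg.n_species, cfg.species_abundance))
    species_of = rng.choice(cfg.n_species, size=cfg.n_landraces, p=probs)
    centres = rng.uniform(0, cfg.territory_size, size=(cfg.n_clusters, 2))
    home = rng.integers(0, cfg.n_clusters, size=cfg.n_landraces)

    records: list[LandraceRecord] = []
    rid = 0
    for lr in range(cfg.n_landraces):
        n_acc = 1 + rng.poisson(max(cfg.accessions_per_landrace - 1.0, 0.0))
        cx, cy = centres[home[lr]]
        for _ in range(n_acc):
            # truncated Gaussian scatter: resample until inside the territory
            for _ in range(1000):
                x, y = rng.normal((cx, cy), cfg.cluster_dispersion)
                if 0 <= x < cfg.territory_size and 0 <= y < cfg.territory_size:
                    break
            records.append(
                LandraceRecord(
                    record_id=f"acc{rid:05d}",
                    landrace_name=f"landrace_{lr:04d}",
                    species=f"species_{species_of[lr]:03d}",
                    x=float(x),
                    y=float(y),
                )
            )
            rid += 1
    return tuple(records)


def _rects_to_target_area(
    rng: np.random.Generator,
    region: BaseGeometry,
    target_area: float,
    size: float,
    *,
    clip_to: BaseGeometry | None = None,
    max_rects: int = 2000,
) -> list[BaseGeometry]:
    """Accumulate random rectangles clipped to ``clip_to`` until their union
    area reaches ``target_area``, then shrink the last rectangle (binary
    search on its scale about its centre) to land within 0.1% of target."""
    if target_area <= 0:
        return []
    minx, miny, maxx, maxy = region.bounds
    rects: list[BaseGeometry] = []
    union = None
    last_centre = None
    for _ in range(max_rects):
        w, h = rng.uniform(0.4 * size, 1.2 * size, size=2)
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        r = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        r = r.intersection(region if clip_to is None else clip_to)
        if r.is_empty or r.area == 0:
            continue
        rects.append(r)
        last_centre = (cx, cy)
        union = unary_union(rects)
        if union.area >= target_area:
            break
    else:
        raise RuntimeError("could not reach target coverage; enlarge rectangles")

    # scale the final rectangle so the union hits the target almost exactly
    base_union = unary_union(rects[:-1]) if len(rects) > 1 else None
    base_area = base_union.area if base_union is not None else 0.0
    last = rects[-1]
    lo, hi = 0.0, 1.0
    from shapely.affinity import scale as _scale

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cand = _scale(last, xfact=mid, yfact=mid, origin=last.centroid)
        area = (
            unary_union([base_union, cand]).area
            if base_union is not None
            else cand.area
        )
        if area < target_area:
            lo = mid
        else:
            hi = mid
        if abs(area - target_area) <= 1e-3 * target_area:
            break
    rects[-1] = _scale(last, xfact=hi, yfact=hi, origin=last.centroid)
    return rects


def _protected_layers(
    rng: np.random.Generator, cfg: SynthConfig, territory: Territory
) -> tuple[tuple[BaseGeometry, ...], tuple[BaseGeometry, ...]]:
    """Two protected layers with target coverage and mutual overlap.

    Layer A is random rectangles reaching ``protected_fraction`` of the
    territory. Layer B reaches the same fraction, built in two parts so
    that a share ``protected_overlap`` of its area lies inside A: one batch
    of rectangles clipped to A, one clipped to the complement of A.
    """
    terr_area = territory.boundary.area
    target = cfg.protected_fraction * terr_area
    if target <= 0:
        return (), ()
    size = 0.12 * cfg.territory_size
    layer_a = _rects_to_target_area(
        rng, territory.boundary, target, size, clip_to=territory.boundary
    )
    union_a = unary_union(layer_a)
    inside = _rects_to_target_area(
        rng, territory.boundary, cfg.protected_overlap * target, size, clip_to=union_a
    )
    outside_region = territory.boundary.difference(union_a)
    outside = _rects_to_target_area(
        rng,
        territory.boundary,
        (1.0 - cfg.protected_overlap) * target,
        size,
        clip_to=outside_region,
    )
    return tuple(layer_a), tuple(inside + outside)


def _landcover_mosaic(
    rng: np.random.Generator, cfg: SynthConfig, territory: Territory
) -> tuple[LandCoverPolygon, ...]:
    """Tile the territory with small squares, draw each tile's level-1
    class from the configured proportions (remainder = unmapped gap), and
    dissolve per class. Class areas approximate the targets with standard
    multinomial error, shrinking as the tile count grows."""
    tile = cfg.cell_size / 10.0
    n = int(round(cfg.territory_size / tile))
    classes = sorted(cfg.landcover_class_props)
    probs = [cfg.landcover_class_props[c] for c in classes]
    gap = 1.0 - sum(probs)
    choices = classes + [0]  # 0 = unmapped gap
    draw = rng.choice(choices, size=(n, n), p=probs + [max(gap, 0.0)])

    polygons: list[LandCoverPolygon] = []
    for cls in classes:
        rows, cols = np.nonzero(draw == cls)
        if len(rows) == 0:
            continue
        tiles = [
            box(c * tile, r * tile, (c + 1) * tile, (r + 1) * tile)
            for r, c in zip(rows, cols)
        ]
        merged = unary_union(tiles).intersection(territory.boundary)
        if not merged.is_empty:
            polygons.append(
                LandCoverPolygon(geometry=merged, clc_code=_LEVEL1_CODES[cls])
            )
    return tuple(polygons)


def generate_scene(config: SynthConfig) -> Scene:
    """Generate a full synthetic scene, reproducible from ``config.seed``.

    Independent sub-streams drive records, protected areas and land cover,
    so changing one component's parameters does not perturb the others.
    """
    root = np.random.SeedSequence(config.seed)
    s_rec, s_prot, s_lc = (np.random.default_rng(s) for s in root.spawn(3))
    territory = Territory(
        boundary=box(0, 0, config.territory_size, config.territory_size),
        crs_id=config.crs_id,
    )
    records = _sample_records(s_rec, config)
    prot_a, prot_b = _protected_layers(s_prot, config, territory)
    landcover = _landcover_mosaic(s_lc, config, territory)
    return Scene(
        territory=territory,
        records=records,
        protected_a=prot_a,
        protected_b=prot_b,
        landcover=landcover,
        config=config,
    )


def worked_fixture() -> tuple[Scene, pd.DataFrame]:
    """A fully hand-checkable 3x3-quadrant scene with its expected indices.

    Territory: 60x60 km square at the origin, 20 km cells -> 9 quadrants.
    Every geometry is an axis-aligned rectangle with corner coordinates on
    whole kilometres, so all areas are closed-form. The expected per-
    quadrant table (LDI, H', PWS%, AED%) was computed by hand at design
    time and is returned alongside the scene.

    Hand bookkeeping (coordinates in km):

    * q0_0 holds landraces L1..L6 (L1 twice): species A carries 2 distinct
      landraces, B carries 4 -> LDI 6, H' = -(1/3 ln 1/3 + 2/3 ln 2/3).
    * q0_1 holds L7 (one species) -> LDI 1, H' 0. The record for L12 sits
      exactly on the edge x = 40 km and belongs to q0_2 (half-open cells).
    * q1_1 holds L8 (A), L9 (C), L10-L11 (D) -> LDI 4,
      H' = -(2 * 1/4 ln 1/4 + 1/2 ln 1/2).
    * Protected layer A: (0,0)-(20,10) and (20,20)-(30,40); layer B:
      (0,5)-(20,15) and (45,45)-(55,55). Their union covers 300 km2 of
      q0_0 (75%), 200 km2 of q1_1 (50%) and 100 km2 of q2_2 (25%).
    * Land cover tiles the territory exactly: artificial (0,0)-(10,10);
      agriculture (10,0)-(60,20); forest (0,10)-(10,20) and (0,20)-(60,60).
      AED is 75% in q0_0 and 100% elsewhere.
    """
    km = 1000.0
    territory = Territory(boundary=box(0, 0, 60 * km, 60 * km))

    def rec(rid, lr, sp, x, y):
        return LandraceRecord(rid, lr, sp, x * km, y * km)

    records = (
        rec("r01", "L1", "A", 5, 5),
        rec("r02", "L1", "A", 6, 6),
        rec("r03", "L2", "A", 7, 5),
        rec("r04", "L3", "B", 10, 10),
        rec("r05", "L4", "B", 12, 12),
        rec("r06", "L5", "B", 14, 8),
        rec("r07", "L6", "B", 3, 15),
        rec("r08", "L7", "C", 25, 5),
        rec("r09", "L8", "A", 25, 25),
        rec("r10", "L9", "C", 30, 30),
        rec("r11", "L10", "D", 35, 35),
        rec("r12", "L11", "D", 38, 26),
        rec("r13", "L12", "E", 40, 10),  # on the q0_1 | q0_2 edge -> q0_2
    )
    protected_a = (
        box(0, 0, 20 * km, 10 * km),
        box(20 * km, 20 * km, 30 * km, 40 * km),
    )
    protected_b = (
        box(0, 5 * km, 20 * km, 15 * km),
        box(45 * km, 45 * km, 55 * km, 55 * km),
    )
    landcover = (
        LandCoverPolygon(box(0, 0, 10 * km, 10 * km), "112"),
        LandCoverPolygon(box(10 * km, 0, 60 * km, 20 * km), "211"),
        LandCoverPolygon(box(0, 10 * km, 10 * km, 20 * km), "311"),
        LandCoverPolygon(box(0, 20 * km, 60 * km, 60 * km), "311"),
    )
    scene = Scene(
        territory=territory,
        records=records,
        protected_a=protected_a,
        protected_b=protected_b,
        landcover=landcover,
        config=SynthConfig(seed=0, territory_size=60 * km, cell_size=20 * km),
    )

    h_q00 = -((1 / 3) * math.log(1 / 3) + (2 / 3) * math.log(2 / 3))
    h_q11 = -(2 * 0.25 * math.log(0.25) + 0.5 * math.log(0.5))
    expected = pd.DataFrame(
        [
            ("q0_0", 6, h_q00, 75.0, 75.0),
            ("q0_1", 1, 0.0, 0.0, 100.0),
            ("q0_2", 1, 0.0, 0.0, 100.0),
            ("q1_0", 0, 0.0, 0.0, 100.0),
            ("q1_1", 4, h_q11, 50.0, 100.0),
            ("q1_2", 0, 0.0, 0.0, 100.0),
            ("q2_0", 0, 0.0, 0.0, 100.0),
            ("q2_1", 0, 0.0, 0.0, 100.0),
            ("q2_2", 0, 0.0, 25.0, 100.0),
        ],
        columns=["quadrant_id", "ldi", "h_prime", "pws_pct", "aed_pct"],
    )
    return scene, expected
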