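"""Geometric substrate: territory gridding, point-to-quadrant assignment,
polygon union and percent-coverage overlays.

All geometry is handled in a single projected coordinate reference system
with metre units (e.g. a UTM zone). Grids are regular square lattices
anchored at the componentwise floor of the territory bounding box to a
multiple of the cell size, so the same territory always yields the same
grid regardless of run order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from shapely import STRtree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Coordinate-reference identifiers we recognise as geographic (degree
#: units) and therefore reject: all computation is metric.
_GEOGRAPHIC_CRS_IDS = {"EPSG:4326", "WGS84", "EPSG:4258", "CRS84", "OGC:CRS84"}


def is_geographic_crs(crs_id: str) -> bool:
    """True when the identifier names a geographic (lat/lon, degrees) CRS."""
    return crs_id.strip().upper().replace(" ", "") in _GEOGRAPHIC_CRS_IDS


def repair(geometry: BaseGeometry) -> BaseGeometry:
    """Return a valid version of ``geometry``, fixing self-intersections.

    Equivalent to the classic zero-width buffer fix but using
    ``shapely.validation.make_valid``, which preserves all area under the
    even-odd interpretation. Raises ``ValueError`` if the geometry cannot
    be repaired.
    """
    if geometry.is_valid:
        return geometry
    fixed = make_valid(geometry)
    if not fixed.is_valid:  # pragma: no cover - make_valid guarantees validity
        raise ValueError("geometry could not be repaired")
    logger.info("repaired invalid geometry (%s)", geometry.geom_type)
    return fixed


@dataclass(frozen=True)
class Territory:
    """A study-area boundary polygon in a projected metric CRS."""

    boundary: BaseGeometry
    crs_id: str = "EPSG:32632"

    def __post_init__(self) -> None:
        if self.boundary is None or self.boundary.is_empty:
            raise ValueError("empty territory")
        if is_geographic_crs(self.crs_id):
            raise ValueError("CRS must be projected/metric")
        if not self.boundary.is_valid:
            object.__setattr__(self, "boundary", repair(self.boundary))


@dataclass(frozen=True)
class Quadrant:
    """One square grid cell: the unit of all index computation.

    ``cell_area`` is the nominal full-cell area (side squared); percentages
    computed against a quadrant always use this denominator, including for
    cells only partially inside the territory.
    """

    id: str
    row: int
    col: int
    geometry: BaseGeometry
    cell_area: float


@dataclass(frozen=True)
class Grid:
    """A regular square-lattice grid clipped to the cells that intersect a
    territory with positive area."""

    quadrants: tuple[Quadrant, ...]
    cell_size: float
    origin: tuple[float, float]
    crs_id: str = "EPSG:32632"
    _by_rowcol: Mapping[tuple[int, int], Quadrant] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        ids = [q.id for q in self.quadrants]
        if len(ids) != len(set(ids)):
            raise ValueError("quadrant ids are not unique")
        object.__setattr__(
            self, "_by_rowcol", {(q.row, q.col): q for q in self.quadrants}
        )

    def __len__(self) -> int:
        return len(self.quadrants)

    def __iter__(self):
        return iter(self.quadrants)

    def get(self, row: int, col: int) -> Quadrant | None:
        return self._by_rowcol.get((row, col))


@dataclass(frozen=True)
class LandraceRecord:
    """One georeferenced landrace accession (projected metre coordinates)."""

    record_id: str
    landrace_name: str
    species: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"record {self.record_id}: non-finite coordinates")
        if not self.species or not self.species.strip():
            raise ValueError(f"record {self.record_id}: empty species")


def build_grid(territory: Territory, cell_size: float) -> Grid:
    """Lay a regular square grid over ``territory``.

    The lattice origin is the componentwise floor of the territory
    bounding-box minimum to a multiple of ``cell_size``. A cell belongs to
    the grid iff it intersects the territory with positive area; boundary
    cells are kept as full squares (their nominal area stays side²).

    Parameters
    ----------
    territory
        Boundary polygon in a projected metric CRS.
    cell_size
        Cell side length in metres (20_000 emulates 20x20 km quadrants).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    boundary = repair(territory.boundary)
    minx, miny, maxx, maxy = boundary.bounds
    x0 = math.floor(minx / cell_size) * cell_size
    y0 = math.floor(miny / cell_size) * cell_size
    ncols = int(math.ceil((maxx - x0) / cell_size))
    nrows = int(math.ceil((maxy - y0) / cell_size))

    quadrants: list[Quadrant] = []
    for row in range(nrows):
        for col in range(ncols):
            cell = box(
                x0 + col * cell_size,
                y0 + row * cell_size,
                x0 + (col + 1) * cell_size,
                y0 + (row + 1) * cell_size,
            )
            if not cell.intersects(boundary):
                continue
            if cell.intersection(boundary).area <= 0.0:
                continue  # touching along an edge only
            quadrants.append(
                Quadrant(
                    id=f"q{row}_{col}",
                    row=row,
                    col=col,
                    geometry=cell,
                    cell_area=cell_size * cell_size,
                )
            )
    return Grid(
        quadrants=tuple(quadrants),
        cell_size=cell_size,
        origin=(x0, y0),
        crs_id=territory.crs_id,
    )


def assign_records(
    records: Iterable[LandraceRecord], grid: Grid
) -> tuple[dict[str, list[LandraceRecord]], list[LandraceRecord]]:
    """Assign each record to the quadrant containing it.

    Cells are half-open, lower/left inclusive:
    [x0+c·s, x0+(c+1)·s) × [y0+r·s, y0+(r+1)·s), so a point on a shared
    edge belongs to exactly one cell (the one on its right/above).

    Returns
    -------
    (assignment, unassigned)
        ``assignment`` maps every quadrant id (including empty ones) to its
        record list; ``unassigned`` collects records outside all grid cells,
        with the count logged.
    """
    x0, y0 = grid.origin
    s = grid.cell_size
    assignment: dict[str, list[LandraceRecord]] = {q.id: [] for q in grid}
    unassigned: list[LandraceRecord] = []
    for rec in records:
        col = math.floor((rec.x - x0) / s)
        row = math.floor((rec.y - y0) / s)
        quadrant = grid.get(row, col)
        if quadrant is None:
            unassigned.append(rec)
        else:
            assignment[quadrant.id].append(rec)
    if unassigned:
        logger.info("%d record(s) fall outside the grid", len(unassigned))
    return assignment, unassigned


def union_layer(layers: Sequence[Iterable[BaseGeometry]]) -> BaseGeometry:
    """Dissolve one or more polygon layers into a single geometry.

    The result's area is at most the sum of the input areas, with equality
    iff the inputs are pairwise disjoint — overlap between layers (e.g. a
    national protected-area inventory and Natura 2000 sites covering the
    same park) is counted once.
    """
    geoms = [repair(g) for layer in layers for g in layer]
    if not geoms:
        return box(0, 0, 0, 0).buffer(0)  # empty geometry
    return unary_union(geoms)


def coverage_percent(quadrant: Quadrant, layer: BaseGeometry) -> float:
    """Percent of the quadrant's nominal area covered by ``layer``.

    The denominator is always the full cell area, also for coastal or
    boundary quadrants that lie only partially inside the territory.
    """
    if layer is None or layer.is_empty:
        return 0.0
    pct = 100.0 * quadrant.geometry.intersection(layer).area / quadrant.cell_area
    return min(max(pct, 0.0), 100.0)


def coverage_percent_table(
    grid: Grid, layer: BaseGeometry
) -> dict[str, float]:
    """``coverage_percent`` for every quadrant, using a spatial index over
    the dissolved layer's parts to skip non-intersecting cells."""
    if layer is None or layer.is_empty:
        return {q.id: 0.0 for q in grid}
    parts = list(getattr(layer, "geoms", [layer]))
    tree = STRtree(parts)
    out: dict[str, float] = {}
    for q in grid:
        idx = tree.query(q.geometry)
        if len(idx) == 0:
            out[q.id] = 0.0
            continue
        inter_area = sum(q.geometry.intersection(parts[i]).area for i in idx)
        out[q.id] = min(max(100.0 * inter_area / q.cell_area, 0.0), 100.0)
    return out
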