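"""Per-quadrant agro-biodiversity indices.

Three criteria, four indices:

* C1, landrace diversity — LDI (count of distinct landraces in the
  quadrant) and the Shannon diversity H' in nats over species, with
  p_i = distinct landraces of species i / total distinct landraces.
* C2, presence of wild species — PWS, the percent of the quadrant covered
  by the dissolved protected-area layer (proxy for wild-species presence).
* C3, agro-ecosystem ecological diversity — AED, the percent of the
  quadrant covered by non-artificial land-cover classes (hierarchical
  level-1 classes 2..5: agriculture, forest/semi-natural, wetland, water).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .geo_core import (
    Grid,
    LandraceRecord,
    Quadrant,
    assign_records,
    coverage_percent,
    coverage_percent_table,
    union_layer,
)

#: Level-1 land-cover classes counted as non-artificial by default.
NON_ARTIFICIAL_CLASSES = frozenset({2, 3, 4, 5})

INDEX_COLUMNS = ["quadrant_id", "ldi", "h_prime", "pws_pct", "aed_pct"]


@dataclass(frozen=True)
class LandCoverPolygon:
    """A land-cover patch tagged with a 3-digit hierarchical class code
    whose first digit is the level-1 class (1..5)."""

    geometry: BaseGeometry
    clc_code: str

    def __post_init__(self) -> None:
        if not self.clc_code or self.clc_code[0] not in "12345":
            raise ValueError(
                f"invalid land-cover code {self.clc_code!r}: first digit must be 1-5"
            )

    @property
    def level1(self) -> int:
        return int(self.clc_code[0])


def _normalize_name(name: str) -> str:
    """Trimmed, case-folded exact matching for species/landrace labels."""
    return name.strip().casefold()


def ldi(records_in_quadrant: Iterable[LandraceRecord], *, count_accessions: bool = False) -> int:
    """Landrace Density Index: distinct landraces recorded in a quadrant.

    Several accessions of one landrace in the same quadrant count once; a
    landrace recorded in two quadrants counts in each. Set
    ``count_accessions`` for a sensitivity variant counting raw accessions.
    """
    records = list(records_in_quadrant)
    if count_accessions:
        return len(records)
    return len({_normalize_name(r.landrace_name) for r in records})


def species_landrace_counts(
    records_in_quadrant: Iterable[LandraceRecord],
) -> Counter:
    """Distinct landraces per species within one quadrant."""
    pairs = {
        (_normalize_name(r.species), _normalize_name(r.landrace_name))
        for r in records_in_quadrant
    }
    return Counter(sp for sp, _ in pairs)


def shannon_index(records_in_quadrant: Iterable[LandraceRecord]) -> float:
    """Shannon diversity H' = −Σ p_i ln p_i in nats.

    p_i is the fraction of the quadrant's distinct landraces belonging to
    species i. Returns 0 for an empty quadrant (so additive scoring is
    defined everywhere) and 0 when a single species is present.
    """
    counts = species_landrace_counts(records_in_quadrant)
    n_total = sum(counts.values())
    if n_total == 0:
        return 0.0
    h = 0.0
    for n_i in counts.values():
        p = n_i / n_total
        h -= p * math.log(p)
    return max(h, 0.0)  # clamp -0.0 from the single-species case


def pws(quadrant: Quadrant, protected_union: BaseGeometry) -> float:
    """Percent of the quadrant covered by the dissolved protected-area
    layer. The layer must already be a union so overlapping source layers
    are not double-counted."""
    return coverage_percent(quadrant, protected_union)


def aed(
    quadrant: Quadrant,
    landcover: Iterable[LandCoverPolygon],
    non_artificial: frozenset[int] = NON_ARTIFICIAL_CLASSES,
) -> float:
    """Percent of the quadrant covered by non-artificial land cover.

    Unmapped gaps (e.g. sea) count as non-covered area and reduce the
    index, consistent with the full nominal-area denominator.
    """
    selected = [p.geometry for p in landcover if p.level1 in non_artificial]
    return coverage_percent(quadrant, union_layer([selected]))


def compute_all_indices(
    grid: Grid,
    records: Iterable[LandraceRecord],
    protected_layers: Sequence[Iterable[BaseGeometry]],
    landcover: Iterable[LandCoverPolygon],
    non_artificial: frozenset[int] = NON_ARTIFICIAL_CLASSES,
    *,
    count_accessions: bool = False,
) -> pd.DataFrame:
    """One row of (LDI, H', PWS%, AED%) per quadrant, in grid order.

    The protected layers are dissolved into a single union first; the
    land-cover layer is filtered to the non-artificial classes and likewise
    dissolved, so duplicated polygons cannot inflate either percentage.
    """
    assignment, _ = assign_records(records, grid)
    protected_union = union_layer(protected_layers)
    lc_list = list(landcover)
    na_union = union_layer(
        [[p.geometry for p in lc_list if p.level1 in non_artificial]]
    )
    pws_table = coverage_percent_table(grid, protected_union)
    aed_table = coverage_percent_table(grid, na_union)

    rows = []
    for q in grid:
        recs = assignment[q.id]
        rows.append(
            {
                "quadrant_id": q.id,
                "ldi": ldi(recs, count_accessions=count_accessions),
                "h_prime": shannon_index(recs),
                "pws_pct": pws_table[q.id],
                "aed_pct": aed_table[q.id],
            }
        )
    if not rows:
        return pd.DataFrame(columns=INDEX_COLUMNS)
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def h_threshold_from_median(index_table: pd.DataFrame) -> float:
    """Default Shannon threshold: the median H' over quadrants that hold at
    least one landrace (LDI ≥ 1). Quadrants with no landrace data carry no
    information about intraspecific diversity and are excluded.

    An even number of contributing quadrants yields the mean of the two
    central order statistics.
    """
    eligible = index_table.loc[index_table["ldi"] >= 1, "h_prime"]
    if eligible.empty:
        raise ValueError("no quadrant with ldi >= 1: H' threshold undefined")
    return float(np.median(eligible.to_numpy()))
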