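# Methods

## Procedure

The pipeline scores square grid quadrants on four indices and selects
conservation-priority quadrants (MAPAs) under two strategies.

1. **Gridding.** A regular lattice of side `cell_size` (default 20 km) is
   anchored at the componentwise floor of the territory bounding-box
   minimum to a multiple of the cell size, making grids reproducible
   across runs for the same territory. A cell joins the grid iff it
   intersects the territory with positive area; cells that merely touch
   the boundary are excluded. Boundary cells are kept as full squares and
   every percentage uses the full nominal denominator (side², 400 km² at
   the default), so a coastal quadrant half at sea can never report more
   than ~50 % cover. The original national application anchors its grid to
   an official 2×2 km lattice whose origin is not recoverable; the
   floor-snapped origin is this package's reproducible emulation, and
   quadrant counts for an irregular national territory are therefore not
   expected to match the original bit-exact.
2. **Assignment.** Occurrence points are mapped to quadrants
   arithmetically (`floor((x − x0)/s)`), with half-open cells (lower/left
   edge inclusive) so a point on a shared edge has exactly one home.
   Points outside every cell go to an "unassigned" bucket with a logged
   count; they are never an error.
3. **Indices.** LDI counts *distinct* landraces (the inventory the method
   targets distinguishes accessions from landraces; a configurable
   accession-counting variant exists for sensitivity analysis). H′ uses
   distinct landraces per species as its abundance unit — the same unit as
   LDI — and natural logarithms; H′ := 0 for quadrants with no landraces
   so the additive score is defined everywhere (the restrictive sieve
   never consults H′ there, since LDI ≥ 1 removes those quadrants first).
   Species and landrace names match after trimming and case-folding; no
   taxonomic synonym resolution is attempted. PWS and AED are polygon-
   overlay percentages against dissolved unions, so duplicated or
   overlapping source polygons are counted once. Land-cover gaps (unmapped
   area) reduce AED.
4. **Normalization.** The additive score uses arcsin(√p) expressed in
   degrees. The scaling that makes counts and H′ proportions divides by
   their observed across-grid maxima; published reference maxima (315
   landraces, H′ = 2.525) can be pinned via `NormalizationParams` or the
   `--ldi-max/--h-max` CLI flags. The degree scale is adopted because the
   published normalized thresholds (3.2, 36.5, total 137.9) are reproduced
   exactly by arcsin(√(1/315)) = 3.23° and arcsin(√(0.893/2.525)) = 36.49°,
   whereas radians would give 0.056 and 0.637. Published tabulations list
   26.6 for AED (90 %) and 71.6 for PWS (20 %); mathematically
   arcsin(√0.90) = 71.57° and arcsin(√0.20) = 26.57°, so those two printed
   values are swapped relative to their rows. The implementation follows
   the mathematics; the four-term total is unaffected.
5. **Selection.** RS is the intersection of the four per-criterion pass
   sets (hence provably order-invariant); AS compares the summed
   normalized score against the summed normalized thresholds. All
   comparisons are ≥ and all decisions are made on unrounded values;
   one-decimal rounding is presentation-only. Because arcsin(√·) is
   strictly increasing, RS ⊆ AS holds whenever the general threshold is
   the sum of the normalized RS thresholds — the package asserts this on
   every synthetic run.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `cell_size` | 20 000 | m | 400 km² quadrants, the scale of the reference method |
| `ldi_min` | 1 | landraces | keep every quadrant with any landrace record |
| `h_min` | median H′ over LDI ≥ 1 quadrants | nats | data-driven midpoint; even counts average the central pair |
| `pws_min_pct` | 20 | % | ≥ 80 km² protected per quadrant |
| `aed_min_pct` | 90 | % | ≥ 360 km² non-artificial cover per quadrant |
| `ldi_max`, `h_max` | observed maxima | — | recomputed per run; pin to 315 / 2.525 to reproduce the reference scaling |
| `non_artificial_classes` | {2,3,4,5} | level-1 codes | everything except artificial surfaces |

## Synthetic data

The generator (`agromapa.synth_data`) produces the four pipeline inputs
from one seed, with independent sub-streams per component so changing one
component's parameters leaves the others untouched. Defaults emulate the
study system at reduced extent: a 100×100 km square territory (25
quadrants); 240 landraces of 33 species (≈7 landraces/species and ≈2
accessions/landrace, the ratios of the reference inventory of 4 803
accessions / 2 365 landraces / 329 species) with species drawn from a
Dirichlet-multinomial (concentration 0.5, giving a realistic dominance of
a few species) and accessions scattered around 8 cluster centres with
10 km truncated-Gaussian dispersion; two protected layers each targeting
20 % territory coverage (Natura 2000 alone covers ~22 % of the reference
country) with 50 % mutual overlap; and a land-cover mosaic of
2 km tiles drawn as 5 % artificial, 45 % agricultural, 45 %
forest/semi-natural, 2 % wetland, 3 % water.

Protected layers are random rectangles accumulated until the target union
area is reached, with the final rectangle shrunk by binary search to land
within 0.1 % of the target; the second layer is built from rectangles
clipped inside (share = overlap fraction) and outside the first. Land
cover draws each tile's class independently, so achieved class areas
carry multinomial error that shrinks with the tile count (±3 points at
the default 2 500 tiles).

What the generator does **not** emulate: realistic coastline or terrain,
road networks, spatially autocorrelated land-cover patches, taxonomic
noise in names, or positional error in records. Passing tests on
synthetic scenes therefore demonstrate the correctness of the geometry,
indices and selection logic — not robustness to dirty real-world
inventories, which must still be validated per dataset.

The 3×3 worked fixture (`worked_fixture()`) is fully hand-computed:
rectangle corners on whole kilometres give closed-form areas, and the
expected index table, selections, additive scores and species composition
ship with the scene.

## Numerical choices and degenerate inputs

- Invalid polygons are repaired with `shapely.make_valid` (even-odd area
  interpretation, the standard fix for self-intersecting protected-area
  polygons); irreparable geometry is a hard error. Every repair and every
  dropped record row is counted and logged — validation never silently
  mutates data.
- `arcsine_normalize` clamps values above the scaling maximum to 90° with
  a warning (can occur when maxima are pinned to published values while
  the data exceed them) and rejects negative values.
- Percent coverages are clipped to [0, 100] against floating-point
  overshoot; a quadrant with zero protected or land-cover intersection is
  0 exactly, a fully tiled quadrant 100 exactly for rectangle inputs.
- With no quadrant at LDI ≥ 1 the median-H′ threshold is undefined and
  raises rather than defaulting.
- Empty MAPA sets report index ranges as undefined, never as zeros.

## Design scope

All computation happens in a single projected metric CRS supplied by the
caller; geographic (lat/lon) inputs are rejected with an explicit error
rather than guessed at or reprojected — reprojection is out of scope and
upstream tooling (GDAL, pyproj) does it better. Vector I/O is GeoJSON;
tabular I/O is UTF-8 comma-separated CSV with mandatory headers. No
raster processing, no taxonomic synonym resolution, no rarity or
endemism weighting, no alternative normalizations, and no
optimization-based site selection: the method is deliberately a simple,
transparent multi-criteria sieve/score over a grid.

## Limitations

- The reference national grid cannot be reproduced exactly (unknown
  origin), so headline MAPA counts from the original national datasets
  are out of reach by construction; the package instead verifies every
  desk-recomputable published number and the method's structural
  properties (sieve order invariance, RS ⊆ AS, Shannon bounds) on
  synthetic scenes.
- PWS is a proxy: protected-area coverage stands in for wild-species
  presence; AED likewise proxies ecological diversity by non-artificial
  cover share, not by a patch-diversity metric.
- Scaling maxima recomputed per run make additive scores comparable
  within a run but not across territories; pin the maxima for
  cross-territory comparisons.
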