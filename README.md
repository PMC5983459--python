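# agromapa

Grid-based identification and prioritization of agro-biodiversity hotspots
— "Most Appropriate Areas" (MAPAs) — for in situ conservation of plant
genetic resources.

The package is for conservation planners and biodiversity informaticians
who hold three kinds of spatial evidence over a territory: georeferenced
landrace occurrence records (an inventory of locally adapted crop
populations), protected-area polygon layers (a national inventory such as
EUAP plus the Natura 2000 network), and a hierarchical land-cover map
(Corine Land Cover-style polygons). It grids the territory into fixed-size
square quadrants (20×20 km, 400 km² by default), scores each quadrant on
four indices, and selects MAPAs under two strategies.

## The model

Per quadrant *q*:

- **LDI** — Landrace Density Index: the number of distinct landraces
  recorded in *q* (accessions of the same landrace count once).
- **H′** — Shannon diversity over species cultivated as landraces,
  H′ = −Σᵢ pᵢ ln pᵢ (nats), with pᵢ = distinct landraces of species *i* /
  total distinct landraces in *q*; H′ = 0 for empty or single-species
  quadrants.
- **PWS** — percent of the quadrant's nominal area covered by the
  dissolved union of all protected-area layers (a proxy for the presence
  of wild species; layer overlap is counted once).
- **AED** — percent covered by non-artificial land-cover classes
  (level-1 classes 2–5: agriculture, forest/semi-natural, wetland, water),
  a proxy for agro-ecosystem ecological diversity.

**Restrictive Strategy (RS):** a quadrant is a MAPA iff LDI ≥ 1,
H′ ≥ median(H′ over quadrants with LDI ≥ 1), PWS ≥ 20 % and AED ≥ 90 %
(all thresholds configurable, all comparisons ≥). The sieve is
order-independent.

**Additive Strategy (AS):** each index value *v* with scaling maximum *m*
is normalized to degrees by the arcsine-square-root transform
arcsin(√(v/m)) · 180/π ∈ [0, 90] (LDI and H′ are scaled by their
across-grid maxima; percentages are proportions with *m* = 1). The four
normalized values are summed, and a quadrant is a MAPA iff its sum reaches
the general threshold: the sum of the four normalized RS thresholds. With
the reference maxima 315 (LDI) and 2.525 (H′), the four thresholds
normalize to 3.2°, 36.5°, 26.6° and 71.6°, totalling **137.9°**. Because
the transform is strictly increasing, every RS MAPA is also an AS MAPA.

## Worked example

Run the full pipeline on a built-in synthetic landscape (25 quadrants of
20×20 km, ~240 landraces of ~33 species in clustered accessions, ~20 %
protected cover in two overlapping layers, a five-class land-cover
mosaic):

```sh
agromapa --quiet run --seed 1 --out outputs/
```

prints

```
Run summary
===========
quadrants: 25
records assigned/unassigned: 486/0

Thresholds (Restrictive Strategy)  |  normalized (Additive)
  LDI  >= 1
  H'   >= 2.3026
  PWS  >= 20%
  AED  >= 90%
scaling maxima: LDI 37, H' 2.6780
general threshold (AS): 175.6 degrees

MAPAs: RS 8, AS 20 (RS subset of AS: True)

Index ranges over selected MAPAs (min - max)
index                       RS                  AS
ldi                13.0 - 36.0          8.0 - 37.0
h_prime              2.3 - 2.7           1.5 - 2.7
pws_pct            24.7 - 63.1          4.8 - 63.1
aed_pct            92.0 - 97.0         91.0 - 97.0
```

Reading this: the H′ sieve threshold (2.3026) is the median Shannon index
over quadrants holding at least one landrace, recomputed from the data;
the scaling maxima are the observed across-grid maxima; 8 of 25 quadrants
pass all four sieves (RS), while 20 reach the 175.6° additive threshold —
the AS also admits quadrants with little or no landrace data but strong
protected-area and land-cover scores, and always contains the RS set. Full
per-quadrant values land in `outputs/indices.csv` and
`outputs/mapa_result.csv`, selected quadrants as GeoJSON, and the species
make-up of the MAPAs in `outputs/species_composition_*.csv`.

Other subcommands: `agromapa synth` (write a synthetic scene to disk),
`grid`, `indices`, `prioritize`, `report`; `--help` on each. The same
functionality is available as a library — see `agromapa.pipeline.run_on_scene`
and the module docstrings.

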