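# climoccur

Semiquantitative climatic characterization of plant taxa from point-occurrence
databases.

Large occurrence compilations (GBIF, BIEN, herbarium exports, …) are noisy:
cross-source replicates, truncated coordinates, points in the sea, cultivated
specimens, and records far outside a taxon's native range all distort any
climate-preference summary built on top of them. `climoccur` implements, as a
tested and reusable library, the full workflow that turns such compilations
into per-taxon climatic profiles:

1. **Rule-based cleaning** — administrative harmonization against TDWG
   level-3 "botanical country" and ISO country polygons; replicate removal on
   a nine-field key (species, year, country code, locality, longitude and
   latitude text, elevation, catalog number, basis of record); a textual
   coordinate-precision filter (both coordinates need ≥ 2 decimals); a 10-km
   coastal rule that snaps misplaced offshore points (≤ 10 km from land) to
   the nearest land cell and removes erroneous ones (> 10 km); flagging of
   cultivated records by a multilingual, diacritic-folded keyword list; and a
   native-range filter on TDWG codes. Every stage conserves records
   (input = kept + removed) and is reported per stage and per genus, with
   Loss% = 100·(input − kept)/input.
2. **Bioclimatic regionalizations** — categorical layers of a study grid for
   five classification systems: latitudinal zonation (boundaries 23.5°, 40°,
   66.5°, hemispherically symmetric); Holdridge life-zone belts from
   biotemperature, BioT = (1/12)·Σ clamp(tₘ; 0, 30 °C), with belts
   tropical [24, 30], subtropical [17, 24), warm temperate [12, 17),
   cool temperate [6, 12), boreal [3, 6), subpolar [1.5, 3), polar [0, 1.5);
   Köppen–Geiger main classes (A tropical, B dry, C temperate, D continental,
   ET tundra, EF polar); GEnS broad biomes (consumed as a supplied layer);
   and simplified ecoregions (14 biomes merged to 9 categories).
3. **Climatic profiles** — per-genus category percentages after
   one-record-per-coordinate deduplication; a taxon is *unequivocally
   assigned* when one category holds strictly more than 75% of its records,
   otherwise "equivocal". Clade-level profiles reduce oversampled genera
   (> 1500 records) to 1000 spatially regular picks before pooling, and
   profiles can be scored against qualitative tropical/temperate labels.
4. **Sampling effort and range size** — 1° occurrence-count grids classified
   by exact Fisher–Jenks natural breaks; classes whose counts reach 25% of
   the regional per-cell maximum are sampling hotspots; AOO (4 km² per
   occupied 2-km equal-area cell), EOO (geodesic convex-hull area), and
   restricted (< 2000 km², the IUCN B2 vulnerable bound) / intermediate /
   widespread (> 10 000 km²) size classes; cumulative temporal series from
   1900 with 25/50/75% quartile years; genus richness per botanical country.
5. **Synthetic data** — seeded generators for every input (multi-source
   occurrence tables with disjoint planted defects and a withheld truth
   table, monthly temperature grids with analytically invertible gradients,
   polygon tilings with a consistent land mask), so the whole pipeline is
   testable offline with known ground truth.

Rasters are plain-text ASCII grids with JSON legend sidecars; polygon layers
are GeoJSON; tables are CSV.

## Worked example

`python examples/clean_occurrences.py` generates a 227-record synthetic
compilation (5 genera, 200 clean records plus planted defects) and cleans it:

```
planted defects: {'clean': 200, 'duplicate': 10, 'low_precision': 5,
                  'coastal': 3, 'offshore': 3, 'cultivated': 2, 'out_of_range': 4}

stage accounting (input = kept + removed at every stage):
  harmonize     {'input': 227, 'removed': 0, 'kept': 227, 'flagged_no_polygon': 6}
  deduplicate   {'input': 227, 'removed': 10, 'kept': 217}
  precision     {'input': 217, 'removed': 5, 'kept': 212}
  land          {'input': 212, 'removed': 3, 'kept': 209, 'snapped': 3}
  cultivated    {'input': 209, 'removed': 2, 'kept': 207, 'flagged': 2}
  native_range  {'input': 207, 'removed': 4, 'kept': 203, 'removed_outside': 4, ...}

kept 203 records (clean + coastal records snapped to the nearest land cell)
 genus  input  kept  loss_percent
GenusA     50    41         18.00
```

Each stage removed exactly its planted defect class: 10 replicates, 5
low-precision records, 3 offshore errors (with the 3 coastal points snapped
and kept), 2 cultivated localities, 4 out-of-range records — leaving the 200
clean records plus 3 snapped coastal ones. GenusA's 18% loss is
100·(50 − 41)/50.

The other examples show the remaining capabilities:
`examples/build_regionalizations.py` (Holdridge belts appear at the
closed-form latitudes implied by the temperature gradient),
`examples/profile_genera.py` (shares, the strict >75% rule, clade pooling
with regular subsampling), and `examples/range_and_hotspots.py` (Jenks
classes, the 25%-of-max hotspot rule, AOO/EOO).

A thin CLI chains the stages end to end and writes a checksummed manifest:

```
climoccur all --out run1 --seed 1
```

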