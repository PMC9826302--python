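# Methods

This note documents the models, rules and numerical choices behind
`climoccur`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real occurrence databases.

## Cleaning pipeline

The pipeline runs six stages in a fixed order: harmonize → deduplicate →
precision filter → land/coastal → cultivated → native range. The order
matters: harmonization must precede deduplication (the replicate key includes
the harmonized country code) and the native-range filter (which consumes TDWG
codes); the precision filter must precede the coastal snap (snapping rewrites
coordinate text).

**Harmonization.** Country codes are always overwritten by point-in-polygon
lookup against the supplied TDWG level-3 and ISO layers, which also corrects
typographical country errors in source data. Boundary points are assigned to
the polygon with the lexicographically smallest code — an arbitrary but
deterministic tie-break. Records matching no polygon keep a missing code and
are flagged; they are typically offshore points handled by the land stage.
After the coastal snap moves a record onto land, it is re-harmonized —
otherwise a legitimately snapped record would carry an empty code into the
native-range stage and be dropped there for the wrong reason.

**Replicate key.** Nine fields: species name, year, TDWG country code,
locality, longitude text, latitude text, elevation, catalog number, basis of
record. Text fields are whitespace-trimmed, case- and diacritic-folded;
missing fields compare equal as empty strings, because source databases
differ in voucher completeness and a missing-vs-missing mismatch would hide
true replicates. Coordinates compare by their textual form so that "12.3" and
"12.30" — identical numbers, different claimed precision — do not collapse.
The first record in input order is kept; input order is the user's
source-priority order.

**Precision filter.** The "at least two decimals" rule is defined on the
textual representation, where it is unambiguous: trailing zeros count
("12.30" passes, "12.3" fails). A numeric reading would make the rule
float-representation-dependent. This is why records carry both the verbatim
coordinate text and the parsed value.

**Land/coastal rule (10 km).** Land is defined by the data cells of a
template raster (in production use, a climate layer: a record in a NoData
cell of the climate stack cannot be climatically characterized anyway).
Distance is great-circle distance to data-cell centers, which is reproducible
and matches the subsequent snap target (the nearest climatic cell). The rule
is only meaningful when cells are small relative to the 10-km threshold —
with 0.05° (~5.5 km) cells, as the synthetic land masks use, the center of a
coastal cell is at most ~3.9 km from any point of the cell, so the
center-distance and true coast-distance differ by less than half a cell
diagonal. On a coarse (≥ 0.5°) template the same rule would remove nearly all
near-shore points; the template resolution is therefore part of the study
design, not a free parameter.

**Cultivated flagging.** Substring matching of 12 keywords (cultivated,
cultivado, park, parque, garden, jardín, castel, castillo, golf, cementerio,
zoo, farm) after case- and diacritic-folding, so "Jardin" matches "jardín".
Flagging and removal are separate: localities such as "Parque Nacional …"
are known false positives (native stands), and the original workflow
re-checked flags manually before deletion. `run_cleaning` removes flagged
records by default (`remove_flagged_cultivated=True`) because the synthetic
generator plants only true positives; on real data users should review the
flagged subset first.

**Accounting.** Every stage satisfies input = kept + removed (snapped records
are counted within kept); per-genus loss is 100·(input − kept)/input rounded
to two decimals. Raw counts are always exposed so users can audit
discrepancies in their own compilations rather than trusting a single
aggregate.

## Regionalizations

**Biotemperature.** BioT = mean over 12 months of tₘ clamped to [0, 30] °C
(values outside the range contribute 0, not a truncated value). Output is
bounded in [0, 30] by construction; NoData in any month propagates.

**Holdridge belts.** tropical [24, 30], subtropical [17, 24), warm temperate
[12, 17), cool temperate [6, 12), boreal [3, 6), subpolar [1.5, 3),
polar [0, 1.5). Two conventions are ours: (i) each boundary belongs to the
warmer belt (the printed interval descriptions are ambiguous at their
endpoints, and a partition needs a rule); (ii) the subpolar upper bound is
3 °C, not the sometimes-printed 3.5 °C, which would overlap the boreal belt's
stated 3–6 °C — we treat the 3.5 as a typographical slip and keep the belts
contiguous. Only the biotemperature belts are implemented, not the full
three-axis Holdridge life-zone hexagon (no precipitation or
evapotranspiration axis).

**Latitudinal zonation.** |lat| < 23.5 tropical, [23.5, 40) subtropical,
[40, 66.5) temperate, ≥ 66.5 polar, symmetric about the equator; each
boundary belongs to the poleward zone (same warmer/colder convention as
above, applied to latitude).

**Köppen–Geiger.** Aggregation of an existing coded layer to six main
classes by first letter, except the polar group: published layers encode it
as E with subtypes ET/EF, which map to tundra and polar respectively. No
precipitation-based classification from raw climate data is performed.

**Ecoregions.** The 14 terrestrial biomes are reduced to 9 categories: four
tropical/subtropical forest and grassland biomes merge to "tropical and
subtropical", three temperate biomes merge to "temperate", the remaining
seven pass through. **GEnS** is consumed as a supplied 7-biome categorical
layer; the underlying 42-variable stratification is not re-derived.

**Grids.** Cells are half-open [x, x+Δ) × [y, y+Δ), so every point belongs to
at most one cell; classification uses cell centers. Rasters are plain-text
ASCII grids with JSON legend sidecars — adequate at the coarse (≤ 1°)
resolutions the test grids use; production-scale 30-arc-second global grids
would need a binary raster format and are outside this package's scope.

## Climatic profiles

Per-genus profiles first keep one record per exact (longitude, latitude)
pair — a literal "one record per coordinate", not a grid-cell thinning —
then compute category percentages. Unclassifiable points (NoData cells,
off-grid) are excluded from the denominator but reported (`n_unclassified`),
so a spurious "unclassified" category never dilutes the shares while the
information is preserved. Assignment is strict: a category must hold > 75%
(75.00% exactly is equivocal), mirroring "more than 75%" read literally; the
same strictness applies to the clade-level oversampling cap (> 1500 records
subsampled, exactly 1500 not).

**Regular subsampling.** The spatially regular selection lays a systematic
grid of ≈ target nodes over the genus's bounding box (aspect-ratio-matched;
origin jittered deterministically from the seed), takes the nearest unused
record per node, and adjusts to exactly the target count by dropping the
picks farthest from their nodes or adding the closest unused records. This
is a documented stand-in for R's `sp::spsample(type = "regular")`, whose
exact picks are not reproducible bit-for-bit from its description; the
property that matters — the selection is spatially more even than a uniform
random subset of the same size — is tested directly via nearest-neighbor
spacing.

**Clade pooling** does not deduplicate coordinates across genera (two genera
at the same coordinate are two ecological observations); per-genus profiles
deduplicate within genus only.

## Sampling effort and range metrics

**Fisher–Jenks.** Exact O(k·n²) dynamic program on sorted values with
prefix-sum segment costs; ties (within 1e-12) resolve to the earliest split,
i.e. the smallest last-class minimum. Heat-map classing uses only occupied
(nonzero) cells; k defaults to 7 and is configurable. Correctness is checked
against exhaustive enumeration of all contiguous partitions for n ≤ 12.

**Hotspots.** Threshold = 0.25 × (regional per-cell maximum), also reported
as the ceiling integer ("at least N records"); a class is a hotspot when its
class maximum reaches the threshold, which makes flags monotone up the class
order. Among the plausible readings of "categories including 25% of sampling
effort within their ranges" (class min, class max, band overlap), class-max
is implemented because it reproduces the published flagged-class sets; the
comparison uses the raw threshold, the integer form is for reporting.

**AOO.** Points are projected with a Lambert cylindrical equal-area
projection on the authalic sphere and binned into a fixed 2-km mesh anchored
at (0, 0); AOO = 4 km² × occupied cells. AOO is origin-dependent for point
pairs straddling a grid line (documented and tested); the fixed origin makes
results reproducible and is exposed as a parameter.

**EOO.** Geodesic area of the convex hull: latitudes are converted to
authalic latitude and the exact spherical excess is evaluated on the authalic
sphere (l'Huilier triangulation), which matches a WGS84 ellipsoidal-area
oracle (`geosphere::areaPolygon`) to ~2×10⁻⁴ % on a 1°×1° equatorial
quadrangle — far inside the 0.5% tolerance used in tests. Hulls crossing the
antimeridian are computed after unwrapping longitudes by 360° when that
shrinks the point spread below 180°; fewer than three non-collinear points
give 0. Hull edges are great circles rather than ellipsoidal geodesics; for
range-sized hulls the difference is negligible against the tolerance.

**Size classes.** restricted iff AOO < 2000 km² (the IUCN criterion-B2
vulnerable bound, used purely as an objective range-size cutoff, not a threat
assessment); widespread iff AOO > 10 000 km²; both bounds exclusive, the
bounds themselves are intermediate.

**Temporal series** exclude records before 1900 (and undated records),
counting the exclusions; quartile years are the first year whose cumulative
count reaches 25/50/75% of the series total.

## Synthetic data: what it emulates, and what it does not

The generator tiles a rectangular continent with nx×ny "botanical country"
polygons, surrounded by sea, with a co-registered 0.05° land mask. Clean
records are uniform within each genus's native polygon with 4-decimal
coordinate text; planted defects are **disjoint by construction** (each
record carries at most one defect) so that every cleaning stage's removal
count is identifiable against the withheld truth table: byte-identical
replicates differing only in source label; coordinate text truncated to one
decimal; coastal points displaced 3.5–8 km (well inside the 10-km rule, with
slack for the spherical-distance approximation) and offshore points 20–60 km
perpendicular off an outer coast; keyword-bearing localities; records placed
in a non-native polygon. Monthly temperatures follow
t = intercept − gradient·|lat| + seasonality·cos(2π(m−7)/12)·hemisphere-sign
(+ optional seeded noise), so every Holdridge belt boundary is analytically
invertible: belt bound B sits at |lat| = (intercept − B)/gradient.

Default scenario: 5 genera × 40 clean records, with 10 replicates, 5
low-precision, 3 coastal, 3 offshore, 2 cultivated and 4 out-of-range records
planted — small enough for fast seeded batteries (20-seed recovery runs in
seconds) while exercising every stage.

What passing these tests shows: the rules are implemented exactly as
specified, the bookkeeping conserves records, and each stage removes exactly
what it should under its own definition of "should". What they do not show:
performance on real compilations, where defects overlap (a cultivated record
may also be imprecise), replicates are near- rather than byte-identical,
coastlines are not rectangles, and the cultivated keyword list has real
false-positive/false-negative rates. The generator deliberately omits
species-distribution realism, collector behavior and misidentification.

## Known limitations

- No GeoTIFF/shapefile I/O; inputs must be ASCII-grid rasters and GeoJSON
  polygons (plain-text, versionable, adequate at desk scale).
- Point-in-polygon lookup is a linear scan over polygons — fine for dozens of
  units, not for the full 369-unit TDWG level-3 layer at millions of records.
- The coastal rule's fidelity is tied to the land-template resolution (see
  above).
- Simplified-ecoregion grouping yields 9 categories from the 14 biomes as the
  merge rules are stated; descriptions of the same grouping elsewhere cite a
  different category count (19), which is not reproducible from the stated
  rules and is not attempted.
- Published cleaned-database totals cannot be re-derived here: they require
  the original multi-gigabyte downloads. The acceptance surface instead
  checks the arithmetic that connects published counts (Loss%, database
  share, hotspot thresholds) and the pipeline's behavior on generated data
  with known truth.
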