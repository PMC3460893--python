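# Methods

## Problem and model

`prioralign` measures how strongly a portfolio of conservation land
acquisitions follows a map of science-defined priority areas. Three polygon
layers enter: land-interest records (fee-simple purchases and conservation
easements, each one acquisition event), priority areas from systematic
conservation planning, and jurisdiction (state) boundaries. Two statistics
come out.

**Science influence score.** Let `A_O` be the area of holdings overlapping
priority areas, `A_TNC` the total holdings area, `A_P` the priority area and
`A_S` the region area, all inside one region; write `P_TNC = A_O/A_TNC` and
`P_S = A_P/A_S`. The score is

    score = (P_TNC − P_S) / (1 − P_S)

`P_S` is the alignment expected when acquisitions ignore the priority map
entirely (a uniformly placed small parcel lands in priorities with
probability `P_S`), so the score is the observed excess over chance,
normalized so that full alignment scores 1. It is 0 at chance level,
negative below chance (lower bound `−P_S/(1−P_S)`), and undefined when
`P_S = 1` — a fully covered region cannot discriminate, and the package
raises a typed error rather than reporting a meaningless 100%.

The score also has a generative reading: if a fraction `s` of acquisitions
are placed deliberately inside priorities and the rest are placed blindly,
the expected alignment is `P_TNC = s + (1−s)·P_S`, whose score is exactly
`s`. This identity is what the simulation suite exercises.

**Centroid chi-square test.** Area overlap alone has no sampling
distribution, so the analysis is reframed event-wise: each record's
geometric centroid either falls inside the priority layer or not. Under the
area-proportional null the inside-probability is `P_S`, giving a two-cell
Pearson goodness-of-fit statistic with 1 df (no continuity correction — at
portfolio sample sizes the correction is immaterial, and the uncorrected
statistic is the published convention for this analysis). The p-value is
the upper tail of the χ²₁ distribution; an expected cell below 5 flags the
result rather than suppressing it. The test runs on *undissolved* records,
because each record is one acquisition decision; the area pipeline below
dissolves records, because area must not be double-counted.

## Overlay pipeline

The assessment follows standard gap-analysis practice, in this order:

1. **Repair** every geometry on load and after each overlay (shapely
   `make_valid`); only polygonal content is kept.
2. **Project** layers arriving in geographic coordinates to an Albers Equal
   Area Conic frame (km); already-planar layers (synthetic data) bypass this.
3. **Clip** holdings and priorities to the state boundaries, removing
   marine/out-of-jurisdiction slivers.
4. **Stratify** holdings into: all records; three acquisition periods
   (half-open `[start, end)` intervals, default pre-2000 / 2000–2005 /
   2006–extraction-date, extraction date 2011-07-20 by default); undated
   records; easements; fee simple. Undated records stay in the all-records
   stratum but join no period; unknown tenure joins neither tenure stratum.
5. **Dissolve** each stratum separately, so overlapping records never
   double-count area, but an easement overlapping a fee parcel still counts
   fully within each of its own strata.
6. **Intersect** each dissolved stratum with the dissolved priority layer
   and summarize `A_O, A_TNC, A_P, A_S` nationally, per stratum, and per
   state (for the all-records stratum).

Per-state summaries are computed by intersecting the dissolved national
layers with each state polygon; this is area-equivalent to a union overlay
with the state layer and easier to contract-test (state overlap areas must
sum to the national overlap to 1e-6 relative).

## Numerical choices

- All planar computation is double precision with coordinates in km, which
  keeps continental magnitudes near 1e3–1e7 and area round-off far below
  the 1e-9 km² sliver threshold; overlay products smaller than that
  threshold are dropped as coordinate noise.
- `dissolve` computes connected components of the "intersects" relation
  (STRtree self-join + sparse connected components) and unions each
  component. On layers that are mostly disjoint — parcels at realistic
  densities — this is near-linear, and it returns exactly the cascaded
  union (verified against `shapely.union_all` to 1e-12 relative in the
  suite). Output features are sorted by lower-left bound, making the
  result independent of input order.
- Boundary points count as inside for point-in-polygon; deterministic and
  of measure zero.
- A multipolygon's centroid is the centroid of the whole record, even when
  it falls outside every part; records are analyzed as wholes.
- The projection is the spherical Albers Equal Area Conic on the authalic
  radius (6371.0072 km), standard parallels 29.5°/45.5°, origin 23°N 96°W.
  The spherical form is exactly area-preserving on the sphere, which is
  the only property the area arithmetic uses; geometries are densified to
  0.05° before projection so planar polygon areas converge to their
  spherical values (a 1°×1° cell matches the closed-form spherical zone
  area to better than 1e-6 relative). Ellipsoidal areas differ from
  authalic-sphere areas by ≲0.1% locally, which cancels in the ratios
  `P_TNC` and `P_S` to first order and is irrelevant for synthetic data.
- Report tables round percentages half-away-from-zero at 0.1 granularity;
  all internal computation keeps full precision. Recomputing a score from
  a table's two rounded percentage columns can therefore drift by roughly
  ±0.1–0.2 points from the printed score, with the exact worst case given
  by first-order propagation of the ±0.05-point input rounding.
- Undefined quantities (a stratum or state with no holdings) render as
  `NA`, never 0.

## Synthetic landscape generator

Because real land-interest databases are partly confidential, the generator
emulates their structure so every pipeline stage is testable end to end:

- **States**: a row of non-overlapping squares. Default 3 × 2,000 km —
  continental scale, so the default 18,034 parcels of mean ≈2.05 km² sit at
  ≈0.3% land density and chance parcel-on-parcel overlap stays negligible
  (a U.S.-wide portfolio of ~41,300 km² is ~0.5% of land area).
- **Priorities**: per state, `priority_blocks` equal square patches sized
  analytically so coverage is exact (default 36.4%, the U.S.-wide figure),
  placed by seeded rejection without overlap; placement fails loudly with
  advice to use fewer/larger blocks rather than silently overlapping.
- **Parcels**: the mixture process. Per parcel: state ∝ area; tenure from
  (easement, fee, unknown) weights (default 0.48/0.14/0.38, following the
  published area shares); date absent with probability 0.57 (the published
  undated share), else a period drawn from the dated-area shares
  (0.48/0.28/0.24) and a uniform day within it; side length lognormal
  (median 1 km, log-sd 0.6); with probability `s` the parcel is placed
  wholly inside a priority patch (patch ∝ area, center uniform over the
  patch shrunk by half a side), else its center is uniform over the state
  and the parcel is clipped at the state line. Default influence is 0.6
  overall with easements at 0.44 and fee simple at 0.78, the published
  tenure contrast.
- **Validation**: the 99th-percentile parcel side must not exceed a quarter
  of the smallest patch side, so targeted parcels always fit; the residual
  ~1e-6 lognormal tail is clamped to the patch side.
- **Reproducibility**: each generator stage draws from its own stream
  spawned deterministically from the seed, so changing `n_parcels` never
  moves the state or priority geometry; the same seed yields byte-identical
  GeoJSON.

What the generator deliberately does *not* emulate: real parcel-shape
morphology, spatial autocorrelation in seller willingness, land price, or
priority maps drawn to include pre-existing holdings. Passing recovery
tests therefore show that the pipeline and statistics are correct and
unbiased under the mixture model — not that any particular real portfolio
was generated by that model.

### Edge effects and tolerances

Targeted parcels sit wholly inside patches while chance parcels may
straddle patch and state borders; dissolving also merges the rare chance
overlap between parcels. Together these perturb recovered scores at the
few-tenths-of-a-point level at default densities, which is why recovery is
asserted to ±0.01 on a 20-replicate mean (20,000 parcels per replicate)
rather than exactly. At `s = 1` every parcel is inside a patch by
construction and the pipeline returns exactly 100%.

## Problem sizes used by the validation suite

Score-arithmetic and chi-square checks are instantaneous. The generative
checks use 20,000 parcels × 20 replicates per condition (influence ∈ {0,
0.25, 0.5, 0.75, 1} × coverage ∈ {0.15, 0.364, 0.55}); centroid-test
calibration uses 2,000-parcel landscapes (the test's effect size saturates
power far below full scale, and 200 null replicates bound the type-I rate);
the tenure-contrast check uses 6 replicates at 20,000 parcels. These sizes
give Monte-Carlo standard errors comfortably inside the asserted
tolerances.

## Known limitations

- GeoJSON is the only file format (text end to end); Shapefile/GeoPackage
  input raises a typed unsupported-format error.
- Geodesic (ellipsoidal) areas are out of scope; areas are equal-area
  planar by construction.
- The score comes with no confidence interval; the centroid test is the
  package's only inferential statement, and its null ignores parcel shape
  and spatial autocorrelation.
- Period strata use calendar dates only; no finer temporal modeling.
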