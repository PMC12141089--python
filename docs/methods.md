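# Methods

## The estimation problem

Checklist databases record where birders went and what they reported,
not where a species lives. Two processes are confounded in any apparent
range movement: real change in occupancy, and change in where observers
concentrate. This package estimates annual range summaries from
presence/absence grid cells and then removes the observer-coverage
signal by regression adjustment, rather than by fitting an occupancy
model: detection within a retained cell-year is treated as raw presence.

## Pipeline assumptions

- **Zero-filling** assumes complete checklists really are complete: a
  complete checklist without the focal species is a valid non-detection.
- **Inclusion filters** (stationary/traveling only, distance ≤ 5 km,
  duration ≤ 5 h, complete, May 1 – Jul 31, 2010–2022) bound effort
  variability. Thresholds are kept *inclusive* because the exclusions
  are phrased strictly ("> 5 km", "longer than 5 h"). Records with
  missing duration are excluded (effort unquantifiable); missing
  distance excludes only traveling checklists. The per-rule exclusion
  report charges each dropped record to its first failing rule in a
  fixed order (protocol → completeness → distance → duration → season →
  year); rule order affects only the report, never membership.
- **Shared (group) checklists** are collapsed to one representative
  (lowest checklist id; detection is the OR over the group) to avoid
  pseudo-replication. `--no-collapse` disables the collapse for
  workflows that skip it. "X" counts are detections with unknown count;
  the analysis is presence-based, so counts never enter any estimate.

## Grid and projection

Cells are 10 km × 10 km squares of an Albers equal-area conic grid
(spherical form on the authalic sphere, R = 6 371 007.181 m; standard
parallels 29.5°/45.5° N, origin 23° N 96° W — the conventional North
America setup). Equal-area cells prevent the latitude-dependent
cell-size bias a geographic-coordinate grid would introduce. Cell
membership is half-open, `[x, x+10 km) × [y, y+10 km)`, so assignment
partitions the plane; region membership is by cell center with
boundary ties resolved by region file order. The projection parameters
are configurable and recorded in every output's metadata.

Cells with checklists in fewer than 5 distinct years are dropped. The
retention rule counts years with *any* checklist, not years with
detections — it is a statement about sampling coverage, not occupancy.

## Range metrics

Per region-year, detection metrics are computed over retained cells
with ≥ 1 detection and effort metrics over retained cells with ≥ 1
checklist. The centroid is the area-weighted centroid of the *union* of
the cell squares, evaluated in the projection and reported in degrees.
Because the grid partitions the plane into equal-area squares, this
equals the arithmetic mean of the cell centers; `annual_summaries` uses
the mean-of-centers form directly, and the polygon-union route
(`union_centroid`) is kept and pinned against it in the tests. Range
limits are the extremes of the cell *corner* coordinates after
transformation to degrees — cell edges, not centers, define the
bounding box. Empty detection sets yield explicitly missing metrics and
the region-year is dropped from trend fitting pairwise.

Computing the effort metrics from the same retained-cell universe
(rather than raw checklist coordinates) makes the covariate
like-for-like with the response; a config switch is not needed because
both share one code path over different cell subsets.

## Trend model

For each region × metric, ordinary least squares of position on year
plus the matching effort metric. The year coefficient (°/yr) is the
effort-corrected trend; its two-sided t-test p-value is reported raw
(22 region-metric tests, no multiple-testing correction — flagged here
so users can apply their own). Collinearity between year and the
covariate is screened with VIF = 1/(1 − r²); a perfectly collinear
covariate is an error, fits with fewer than 4 complete years return an
explicit "insufficient" status, and per-fit failures never abort the
batch.

Degree-to-kilometre conversion: slope × span × 111.32 km/°, with span
= 13 (the inclusive year count of 2010–2022; a 12-interval policy is
available via `KmConversion(span_years=12)`). Longitudinal slopes are
additionally scaled by cos(latitude) at the region's mean
detection-centroid latitude; `--no-cos` disables the convergence factor
to reproduce plain equatorial-degree arithmetic. Conversion is linear
and antisymmetric in the slope; rounding happens only at report time.

## Synthetic data: what it emulates and what it does not

The generator simulates the two confounded processes directly:

- **Effort** is a mixture of 256 Gaussian hotspots (sd 8 km) on a
  jittered 16 × 16 grid spanning 38–52° N, 117–103° W, with lognormal
  base weights — birding locations that are revisited year after year,
  which is precisely what makes a ≥ 5-year retention rule meaningful.
  Hotspot usage fluctuates between years (lognormal noise, sd 0.4 in
  log space), so the effort centroid wobbles realistically instead of
  being a deterministic function of year; without that wobble an
  imposed effort drift would be perfectly collinear with year and
  covariate adjustment would be degenerate.
- **Effort drift** is usage *reallocation*: hotspot positions stay
  fixed while their weights are exponentially tilted each year so the
  effort mixture's mean moves at the configured °/yr. A positional
  shift of the whole field would move every hotspot off its cells
  within a year or two (11 km/yr vs 10 km cells) and empty the
  retention rule; reallocation matches how coverage actually shifts —
  participation grows in some areas and wanes in others.
- **Occupancy** is an isotropic Gaussian kernel (sd 180 km) whose
  center drifts at a configurable °/yr; a checklist at projected
  distance d detects the species with probability
  0.9 · exp(−d²/(2 σ²)). Distances are computed on the equal-area
  projected plane (an approximation documented here; at these scales
  the error is negligible).
- **Contaminants** (incidental protocol, incomplete, > 5 km, > 5 h) are
  injected in mutually exclusive slots at configured fractions, with
  clean records guaranteed to pass every filter, so the exclusion
  report can be checked against the injected counts exactly.
- 2 000 checklists/year over 2010–2022 gives roughly 8 checklists per
  hotspot-year, enough to near-saturate detection in well-occupied
  cells. Saturation matters: at sparse sampling the detected-cell
  centroid is attenuated several percent relative to an imposed
  occupancy drift, because detection probability then depends on local
  effort intensity and the effort field modulates the occupancy kernel.
  Under the default conditions the detected-cell centroid tracks an
  imposed 0.1 °/yr drift at ≈ 0.094 °/yr — the small residual
  attenuation is a property of presence-grid centroids, not of the
  regression.
- Per-year random substreams are derived from (master seed, year), so
  resizing one year never perturbs another.

Not emulated: spatial autocorrelation of real observer behaviour beyond
hotspot clustering, observer heterogeneity in detection skill,
misidentification, range shape changes other than translation of a
symmetric kernel. Passing simulation tests therefore demonstrates that
the pipeline recovers translations of a smooth occupancy surface under
drifting, clustered effort — not that every feature of real checklist
data is handled.

## Numerical choices

- All geometry in double precision; geographic output rounded to 6
  decimals (~0.1 m) at write time only.
- Union centroids agree with mean-of-centers to < 1e-9 m in projected
  coordinates (exact partition, no overlapping cells).
- Bounding boxes agree with per-corner enumeration to double-precision
  ULP (vectorized vs scalar transcendental evaluation).
- Collinearity guard: r² ≥ 1 − 1e-12 between year and covariate raises.
- The weight-tilt solver (effort drift) uses bisection per axis with
  four relaxation sweeps; imposed drifts that would push the effort
  centroid outside the hotspot field are rejected at generation time.

## Simulation study sizes

The test suite and `scripts/acceptance.py` use 100 simulated studies
for drift recovery, 200 (×2 centroid axes) for null calibration, and
200 for the effort-confound comparison in the tests; the acceptance
script uses 40/60/40 studies for the same three experiments. These
sizes give binomial/Monte-Carlo precision comfortably tighter than the
thresholds being checked.

## Known limitations

- Raw presence per cell-year: no detection-probability model, so
  changes in per-checklist detectability over time would masquerade as
  range change (the effort covariate only absorbs *positional* coverage
  shifts).
- OLS on 13 annual points: no autocorrelation correction; standard
  errors assume independent annual errors.
- Bounding-box limits are extreme-value statistics and noisier than
  centroids; they are reported only for the full range.
- Region polygons are read from GeoJSON; other vector formats should be
  converted externally.
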