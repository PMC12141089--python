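# rangeshift

Estimating how a species' breeding range has moved — its boundary limits
and centroid position — from semi-structured community-science checklist
data (eBird Basic Dataset style), with explicit correction for shifting
observer effort.

## Who this is for

Ecologists and conservation analysts who want to turn raw checklist
extracts (an observation table plus a sampling-event table) into
defensible range-trend estimates: "the northern range limit moved north
by *x* km over the study window", per region (e.g., Bird Conservation
Regions) and for the range as a whole. Everything is driven by plain
tab-separated text and a YAML config, and a built-in simulator with
known ground truth lets you validate the whole chain before touching
real data.

## The method

1. **Zero-filling.** Every complete sampling event with no record of the
   focal species becomes an explicit non-detection, turning a
   presence-only table into presence/absence.
2. **Inclusion filters.** Keep complete stationary/traveling checklists
   with distance ≤ 5 km and duration ≤ 5 h, within the breeding season
   (May 1 – Jul 31) and study years (2010–2022). Exclusions are reported
   per rule.
3. **Equal-area gridding.** Checklists are binned into 10 km × 10 km
   cells of an Albers equal-area grid; cells sampled in fewer than 5
   distinct years are dropped; each retained cell-year is scored for
   detection.
4. **Annual range metrics.** Per region and year: the centroid of the
   union of detection cells, the bounding-box range limits (N/S/E/W),
   and the same metrics over *all* sampled cells (the effort surface).
5. **Effort-corrected trends.** For each positional metric *y* and its
   effort counterpart *e*, ordinary least squares

   *y*ₜ = β₀ + β₁·year + β₂·*e*ₜ + εₜ

   gives the effort-corrected trend β₁ (°/yr), screened for
   collinearity with VIF = 1/(1 − r²(year, *e*)). Cumulative
   displacement over the window is β₁ × 13 × 111.32 km/°, with
   longitude additionally scaled by cos(latitude) for meridian
   convergence.

## Worked example

Run the full pipeline on simulated data with a known northward
occupancy drift of 0.1 °/yr:

```python
import rangeshift as rs

cfg = rs.SyntheticConfig(seed=1, occupancy_drift=(0.1, 0.0))
events, obs, truth = rs.generate(cfg)
res = rs.analyze(events, obs)
t = res.trends
row = t[(t.region == "full_range") & (t.metric == "centroid_lat")].iloc[0]
print(f"slope {row.slope:.3f} ± {row.slope_se:.3f} °/yr, p = {row.p_value:.2g}, "
      f"VIF {row.vif:.2f}, cumulative {row.cumulative_km:.0f} km {row.direction}")
```

prints

```
slope 0.081 ± 0.013 °/yr, p = 9.4e-05, VIF 1.00, cumulative 117 km N
```

i.e., the effort-corrected centroid-latitude trend recovers the imposed
0.1 °/yr drift (within two standard errors), is highly significant,
shows no year/effort collinearity, and corresponds to ≈120 km of
cumulative northward movement over the 13-year window.

The same pipeline runs from the shell, stage by stage or end to end:

```bash
rangeshift all --config run.yaml          # generate → filter → grid → metrics → trends
rangeshift all --config run.yaml --no-collapse    # keep shared checklists uncollapsed
rangeshift all --config run.yaml --no-cos         # longitude km without cos(lat)
```

Each stage writes a tabular text artifact plus a metadata record
(config hash, package version, seed) into the configured output
directory.

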