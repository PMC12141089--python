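"""Per region-year range metrics: centroids and bounding-box limits.

For each region and year two sets of positional metrics are computed
from the retained grid cells:

* **detection metrics** over cells with at least one detection — the
  centroid of the union of those cells and the bounding box of their
  corners (the annual range limits);
* **effort metrics** over cells with at least one checklist, detected or
  not — the same quantities for observer coverage, used downstream as
  the covariate that absorbs shifts in where people go birding.

Because the grid partitions the plane into equal-area squares, the
area-weighted centroid of the unioned cells equals the plain mean of the
cell centers; ``annual_summaries`` exploits that identity for speed,
while :func:`union_centroid` keeps the explicit polygon-union route (the
two are pinned against each other in the test suite). All geometry is
computed in the projected plane and reported in geographic degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .gridding import GridSpec, RegionSet

#: column order of the annual summary table
SUMMARY_COLUMNS = [
    "region",
    "year",
    "n_det_cells",
    "n_effort_cells",
    "det_centroid_lat",
    "det_centroid_lon",
    "det_min_lat",
    "det_max_lat",
    "det_min_lon",
    "det_max_lon",
    "effort_centroid_lat",
    "effort_centroid_lon",
    "effort_min_lat",
    "effort_max_lat",
    "effort_min_lon",
    "effort_max_lon",
]


def union_centroid_projected(cells, grid: GridSpec) -> tuple[float, float] | None:
    """Projected (x, y) centroid of the union of grid cells, in metres.

    Unions the cell squares in projected space and takes the
    area-weighted centroid of the resulting polygon. Returns None for an
    empty cell set.
    """
    cells = list(cells)
    if not cells:
        return None
    polys = [grid.cell_polygon(c, r) for c, r in cells]
    # cells never overlap (grid partition), so the coverage union applies
    merged = shapely.coverage_union_all(polys)
    return float(merged.centroid.x), float(merged.centroid.y)


def union_centroid(cells, grid: GridSpec) -> tuple[float, float] | None:
    """Centroid (lat, lon) of the union of grid cells.

    Area-weighted centroid of the unioned cell squares, computed in the
    equal-area projection and transformed to geographic degrees. Returns
    None for an empty cell set (the region-year is skipped by the
    caller).
    """
    xy = union_centroid_projected(cells, grid)
    if xy is None:
        return None
    lon, lat = grid.crs.inverse(*xy)
    return float(lat), float(lon)


def bounds_of(cells, grid: GridSpec) -> tuple[float, float, float, float] | None:
    """(min_lat, max_lat, min_lon, max_lon) over cell polygon corners.

    Extremes are taken over the geographic coordinates of every cell
    corner — cell edges, not centers, define the range limits. Returns
    None for an empty set.
    """
    cells = list(cells)
    if not cells:
        return None
    cols = np.array([c for c, _ in cells], dtype=float)
    rows = np.array([r for _, r in cells], dtype=float)
    xs, ys = grid.cell_corners(cols, rows)
    lon, lat = grid.crs.inverse(xs, ys)
    return float(lat.min()), float(lat.max()), float(lon.min()), float(lon.max())


def _mean_center_latlon(cols: np.ndarray, rows: np.ndarray, grid: GridSpec):
    """Fast path: mean of projected cell centers, back-transformed."""
    x, y = grid.cell_center(cols, rows)
    lon, lat = grid.crs.inverse(np.mean(x), np.mean(y))
    return float(lat), float(lon)


def _metrics_for(cols, rows, grid: GridSpec) -> dict:
    lat_c, lon_c = _mean_center_latlon(np.asarray(cols), np.asarray(rows), grid)
    xs, ys = grid.cell_corners(np.asarray(cols, dtype=float), np.asarray(rows, dtype=float))
    lon, lat = grid.crs.inverse(xs, ys)
    return {
        "centroid_lat": lat_c,
        "centroid_lon": lon_c,
        "min_lat": float(lat.min()),
        "max_lat": float(lat.max()),
        "min_lon": float(lon.min()),
        "max_lon": float(lon.max()),
    }


def annual_summaries(
    cell_years: pd.DataFrame,
    grid: GridSpec | None = None,
    regions: RegionSet | None = None,
    include_full_range: bool = True,
) -> pd.DataFrame:
    """Annual detection and effort range metrics per region.

    Parameters
    ----------
    cell_years
        Scored, retained cell-year table (``cell_col``, ``cell_row``,
        ``year``, ``n_checklists``, ``detected``; plus ``region`` when
        ``regions`` were overlaid).
    grid
        Grid the cell ids refer to.
    regions
        Optional region set; when given, per-region rows are emitted in
        addition to the full-range rows.

    Returns
    -------
    One row per (region, year); detection metrics are NaN (EMPTY) for
    region-years with no detection cells, effort metrics are always
    present for sampled region-years.
    """
    grid = grid or GridSpec()
    region_names = []
    if include_full_range:
        region_names.append(RegionSet.FULL_RANGE)
    if regions is not None:
        region_names.extend(regions.names)

    rows = []
    for region in region_names:
        if region == RegionSet.FULL_RANGE:
            sub = cell_years
        else:
            sub = cell_years[cell_years["region"] == region]
        for year, yr in sub.groupby("year"):
            effort = yr  # every summarized cell-year has >= 1 checklist
            det = yr[yr["detected"]]
            rec = {
                "region": region,
                "year": int(year),
                "n_det_cells": len(det),
                "n_effort_cells": len(effort),
            }
            em = _metrics_for(effort["cell_col"].to_numpy(), effort["cell_row"].to_numpy(), grid)
            rec.update({f"effort_{k}": v for k, v in em.items()})
            if len(det):
                dm = _metrics_for(det["cell_col"].to_numpy(), det["cell_row"].to_numpy(), grid)
                rec.update({f"det_{k}": v for k, v in dm.items()})
            else:
                rec.update(
                    {
                        f"det_{k}": np.nan
                        for k in (
                            "centroid_lat",
                            "centroid_lon",
                            "min_lat",
                            "max_lat",
                            "min_lon",
                            "max_lon",
                        )
                    }
                )
            rows.append(rec)
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return out.sort_values(["region", "year"], ignore_index=True)


def write_summaries(summaries: pd.DataFrame, path) -> None:
    """Write the annual summary table as tab-separated text.

    Geographic values are rounded to 6 decimal places (~0.1 m) at write
    time only; EMPTY detection metrics become blank fields.
    """
    out = summaries.copy()
    for c in out.columns:
        if out[c].dtype == float:
            out[c] = out[c].round(6)
    out.to_csv(path, sep="\t", index=False)


def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
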