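"""Equal-area occupancy grid and region overlay.

Checklists are binned into 10 km x 10 km cells of an equal-area grid
(half-open membership ``[x, x+s) x [y, y+s)``, so assignment partitions
the plane). Cells sampled in fewer than five distinct years are dropped
to limit spatial bias from sporadically visited locations, and each
retained cell-year is scored by whether the focal species was detected.
Regions (Bird Conservation Region style polygons) are overlaid by cell
center, ties on shared boundaries going to the region listed first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape, Point, box
from shapely.validation import make_valid

from .projection import AlbersEqualArea


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    ``origin`` is the projected coordinate of the corner of cell (0, 0);
    cell ids are (col, row) integer offsets from it. ``crs`` must be an
    equal-area projection so every cell covers the same ground area.
    """

    cell_size_m: float = 10_000.0
    crs: AlbersEqualArea = field(default_factory=AlbersEqualArea)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    def cell_of(self, x, y):
        """(col, row) of the cell containing projected point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size_m).astype(np.int64)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size_m).astype(np.int64)
        return col, row

    def cell_center(self, col, row):
        """Projected center of cell(s) (col, row)."""
        x = self.origin[0] + (np.asarray(col, dtype=float) + 0.5) * self.cell_size_m
        y = self.origin[1] + (np.asarray(row, dtype=float) + 0.5) * self.cell_size_m
        return x, y

    def cell_corners(self, col, row):
        """Projected corner arrays (4, n) for x and y of cell(s)."""
        col = np.atleast_1d(np.asarray(col, dtype=float))
        row = np.atleast_1d(np.asarray(row, dtype=float))
        x0 = self.origin[0] + col * self.cell_size_m
        y0 = self.origin[1] + row * self.cell_size_m
        s = self.cell_size_m
        xs = np.stack([x0, x0 + s, x0 + s, x0])
        ys = np.stack([y0, y0, y0 + s, y0 + s])
        return xs, ys

    def cell_polygon(self, col, row):
        """Shapely square for one cell, in projected coordinates."""
        x0 = self.origin[0] + col * self.cell_size_m
        y0 = self.origin[1] + row * self.cell_size_m
        return box(x0, y0, x0 + self.cell_size_m, y0 + self.cell_size_m)

    def to_dict(self) -> dict:
        return {
            "cell_size_m": self.cell_size_m,
            "origin": list(self.origin),
            "crs": self.crs.to_dict(),
        }


def assign_cells(records: pd.DataFrame, grid: GridSpec | None = None) -> pd.DataFrame:
    """Annotate checklist records with their grid cell.

    Adds ``cell_col``/``cell_row`` (and projected ``x``/``y``) columns.
    Deterministic for a fixed :class:`GridSpec`; raises if any coordinate
    cannot be projected.
    """
    grid = grid or GridSpec()
    out = records.copy()
    x, y = grid.crs.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        bad = out.index[~(np.isfinite(x) & np.isfinite(y))][:10]
        raise ValueError(f"projection failed for record(s) at index {list(bad)}")
    col, row = grid.cell_of(x, y)
    out["x"], out["y"] = x, y
    out["cell_col"], out["cell_row"] = col, row
    return out


def retain_cells(summaries: pd.DataFrame, min_years: int = 5) -> set[tuple[int, int]]:
    """Cells sampled (>= 1 checklist) in at least ``min_years`` distinct years.

    ``summaries`` needs columns ``cell_col``, ``cell_row``, ``year`` and
    ``n_checklists``; retention counts years with any checklist at all,
    not years with detections.
    """
    sampled = summaries[summaries["n_checklists"] >= 1]
    per_cell = sampled.groupby(["cell_col", "cell_row"])["year"].nunique()
    keep = per_cell[per_cell >= min_years]
    return set(keep.index)


def summarize_cell_years(records: pd.DataFrame) -> pd.DataFrame:
    """Raw per-(cell, year) checklist and detection counts.

    One row per cell-year with at least one checklist; feeds both
    :func:`retain_cells` and :func:`score_cell_years`.
    """
    g = records.assign(year=pd.to_datetime(records["date"]).dt.year).groupby(
        ["cell_col", "cell_row", "year"], as_index=False
    )
    out = g.agg(n_checklists=("detected", "size"), n_detections=("detected", "sum"))
    out["n_detections"] = out["n_detections"].astype(int)
    out["detected"] = out["n_detections"] >= 1
    return out


def score_cell_years(
    records: pd.DataFrame, retained: set[tuple[int, int]]
) -> pd.DataFrame:
    """Cell-year detection summaries for the retained cells only."""
    summaries = summarize_cell_years(records)
    mask = [
        (c, r) in retained
        for c, r in zip(summaries["cell_col"], summaries["cell_row"])
    ]
    return summaries.loc[mask].reset_index(drop=True)


class RegionSet:
    """Named analysis regions (polygons in geographic coordinates).

    Regions are held in file order; :meth:`assign` resolves boundary ties
    in favour of the earlier region. An implicit full-range region (the
    union of all polygons) is always available under
    :attr:`FULL_RANGE`.
    """

    FULL_RANGE = "full_range"

    def __init__(self, names: list[str], polygons: list):
        if len(names) != len(polygons):
            raise ValueError("names and polygons length mismatch")
        self.names = list(names)
        self.polygons = [make_valid(p) if not p.is_valid else p for p in polygons]
        for p in self.polygons:
            shapely.prepare(p)

    @classmethod
    def from_geojson(cls, path: str | Path, name_property: str = "name") -> "RegionSet":
        """Load regions from a GeoJSON FeatureCollection."""
        try:
            with open(path) as fh:
                gj = json.load(fh)
            feats = gj["features"]
            names = [f["properties"][name_property] for f in feats]
            polys = [shape(f["geometry"]) for f in feats]
        except (OSError, KeyError, ValueError) as exc:
            raise ValueError(f"cannot load region polygons from {path}: {exc}") from exc
        return cls(names, polys)

    def union(self):
        return shapely.unary_union(self.polygons)

    def assign(self, lon, lat) -> np.ndarray:
        """Region name for each point, or None if outside every polygon."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, None, dtype=object)
        unassigned = np.ones(lon.shape, dtype=bool)
        for name, poly in zip(self.names, self.polygons):
            if not unassigned.any():
                break
            idx = np.flatnonzero(unassigned)
            # covers(): boundary points count as inside, so file order
            # breaks shared-edge ties deterministically
            hit = shapely.covers(poly, shapely.points(lon[idx], lat[idx]))
            out[idx[hit]] = name
            unassigned[idx[hit]] = False
        return out


def assign_region(
    summaries: pd.DataFrame, regions: RegionSet, grid: GridSpec | None = None
) -> pd.DataFrame:
    """Annotate cell-year summaries with the region of each cell center."""
    grid = grid or GridSpec()
    out = summaries.copy()
    x, y = grid.cell_center(out["cell_col"].to_numpy(), out["cell_row"].to_numpy())
    lon, lat = grid.crs.inverse(x, y)
    out["center_lon"], out["center_lat"] = lon, lat
    out["region"] = regions.assign(lon, lat)
    return out
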