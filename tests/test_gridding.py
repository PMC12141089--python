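import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rangeshift import ebd_io, gridding
from rangeshift.gridding import (
    GridSpec,
    RegionSet,
    assign_cells,
    assign_region,
    retain_cells,
    score_cell_years,
    summarize_cell_years,
)
from rangeshift.synthetic import make_region_fixture

from conftest import make_events, make_obs


class TestCellArithmetic:
    def test_point_inside_first_cell(self, grid):
        assert grid.cell_of(5_000.0, 5_000.0) == (0, 0)

    def test_cell_boundary_is_half_open(self, grid):
        assert grid.cell_of(10_000.0, 0.0) == (1, 0)

    def test_points_straddling_an_edge_fall_in_different_cells(self, grid):
        a = grid.cell_of(9_999.5, 500.0)
        b = grid.cell_of(10_000.5, 500.0)
        assert a != b

    def test_every_cell_has_equal_projected_area(self, grid):
        for col, row in [(0, 0), (120, -40), (-3, 517)]:
            assert grid.cell_polygon(col, row).area == pytest.approx(
                grid.cell_size_m**2, rel=1e-12
            )

    def test_assign_cells_is_deterministic_and_total(self, grid):
        records = ebd_io.zero_fill(
            make_events(
                [{"checklist_id": f"S{i}", "lat": 40 + i, "lon": -115 + i} for i in range(8)]
            ),
            make_obs([]),
        )
        a = assign_cells(records, grid)
        b = assign_cells(records, grid)
        assert (a[["cell_col", "cell_row"]] == b[["cell_col", "cell_row"]]).all().all()
        # cell id consistent with direct projection arithmetic
        x, y = grid.crs.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
        np.testing.assert_array_equal(a["cell_col"].to_numpy(), np.floor(x / grid.cell_size_m))


class TestRetention:
    def _summaries(self, cell_years: dict) -> pd.DataFrame:
        rows = []
        for (col, row), years in cell_years.items():
            for y in years:
                rows.append(
                    {"cell_col": col, "cell_row": row, "year": y, "n_checklists": 1}
                )
        return pd.DataFrame(rows)

    def test_four_years_is_not_enough(self):
        s = self._summaries({(0, 0): [2010, 2012, 2014, 2016]})
        assert retain_cells(s) == set()

    def test_five_distinct_years_retains(self):
        s = self._summaries({(0, 0): [2010, 2011, 2012, 2013, 2014]})
        assert retain_cells(s) == {(0, 0)}

    def test_min_years_one_keeps_every_sampled_cell(self):
        s = self._summaries({(0, 0): [2010], (3, 4): [2015]})
        assert retain_cells(s, min_years=1) == {(0, 0), (3, 4)}

    @given(min_years=st.integers(1, 13))
    def test_retention_is_monotone_in_threshold(self, min_years):
        rng = np.random.default_rng(3)
        cells = {
            (int(c), int(r)): list(
                rng.choice(range(2010, 2023), size=rng.integers(1, 13), replace=False)
            )
            for c, r in rng.integers(0, 5, size=(30, 2))
        }
        s = self._summaries(cells)
        assert retain_cells(s, min_years=min_years + 1) <= retain_cells(s, min_years=min_years)


class TestScoring:
    def _records(self, grid):
        # 4 checklists / 1 detection in cell A (2015); 3 / 0 in cell B (2016)
        lon_a, lat_a = grid.crs.inverse(*grid.cell_center(100, 100))
        lon_b, lat_b = grid.crs.inverse(*grid.cell_center(101, 100))
        rows = []
        for i in range(4):
            rows.append({"checklist_id": f"A{i}", "lat": lat_a, "lon": lon_a,
                         "date": pd.Timestamp("2015-06-01")})
        for i in range(3):
            rows.append({"checklist_id": f"B{i}", "lat": lat_b, "lon": lon_b,
                         "date": pd.Timestamp("2016-06-01")})
        records = ebd_io.zero_fill(make_events(rows), make_obs(["A0"]))
        return assign_cells(records, grid)

    def test_counts_and_detection_flags(self, grid):
        records = self._records(grid)
        out = score_cell_years(records, {(100, 100), (101, 100)})
        a = out[(out.cell_col == 100) & (out.year == 2015)].iloc[0]
        assert (a.n_checklists, a.n_detections, bool(a.detected)) == (4, 1, True)
        b = out[(out.cell_col == 101) & (out.year == 2016)].iloc[0]
        assert (b.n_checklists, b.n_detections, bool(b.detected)) == (3, 0, False)

    def test_dropped_cells_emit_no_summaries(self, grid):
        records = self._records(grid)
        out = score_cell_years(records, {(100, 100)})
        assert set(zip(out.cell_col, out.cell_row)) == {(100, 100)}

    def test_detection_counts_bounded_by_checklists(self, small_cfg, grid):
        from rangeshift import synthetic
        events, obs, _ = synthetic.generate(small_cfg)
        records = assign_cells(ebd_io.zero_fill(events, obs), grid)
        out = summarize_cell_years(records)
        assert (out.n_detections <= out.n_checklists).all()
        assert (out.detected == (out.n_detections >= 1)).all()


def _ray_cast(poly_coords, x, y):
    """Brute-force even-odd point-in-polygon test (independent oracle)."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


class TestRegions:
    def test_point_in_single_region(self, tmp_path):
        regions = RegionSet.from_geojson(
            make_region_fixture("two_rectangles", tmp_path / "r.geojson")
        )
        assert regions.assign(-114.0, 45.0)[0] == "west"
        assert regions.assign(-104.0, 45.0)[0] == "east"

    def test_point_outside_union_is_none(self, tmp_path):
        regions = RegionSet.from_geojson(
            make_region_fixture("two_rectangles", tmp_path / "r.geojson")
        )
        assert regions.assign(-90.0, 45.0)[0] is None

    def test_shared_boundary_goes_to_first_region(self, tmp_path):
        regions = RegionSet.from_geojson(
            make_region_fixture("two_rectangles", tmp_path / "r.geojson")
        )
        # -110 is the shared edge between west (listed first) and east
        assert regions.assign(-110.0, 45.0)[0] == "west"

    def test_random_points_match_ray_casting_oracle(self, tmp_path):
        path = make_region_fixture("two_rectangles", tmp_path / "r.geojson")
        regions = RegionSet.from_geojson(path)
        import json

        feats = json.load(open(path))["features"]
        rings = {f["properties"]["name"]: f["geometry"]["coordinates"][0] for f in feats}
        rng = np.random.default_rng(9)
        lons = rng.uniform(-120, -100, 100)
        lats = rng.uniform(36, 54, 100)
        got = regions.assign(lons, lats)
        for lon, lat, g in zip(lons, lats, got):
            expected = None
            for name in regions.names:  # file order = tie-break order
                if _ray_cast(rings[name], lon, lat):
                    expected = name
                    break
            assert g == expected

    def test_unreadable_region_file_is_a_load_error(self, tmp_path):
        bad = tmp_path / "bad.geojson"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="bad.geojson"):
            RegionSet.from_geojson(bad)

    def test_cells_get_at_most_one_region(self, grid, tmp_path):
        regions = RegionSet.from_geojson(
            make_region_fixture("eight_band", tmp_path / "r.geojson")
        )
        summaries = pd.DataFrame(
            {
                "cell_col": np.arange(380, 420),
                "cell_row": np.full(40, 300),
                "year": 2015,
                "n_checklists": 1,
                "n_detections": 0,
                "detected": False,
            }
        )
        out = assign_region(summaries, regions, grid)
        assert len(out) == len(summaries)  # exactly one region (or none) per cell
        assigned = out["region"].dropna()
        assert set(assigned) <= set(regions.names)
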