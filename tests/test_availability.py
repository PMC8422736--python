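"""Home-range MCPs, raster availability proportions, exclusion screening."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon, box

import habresp as hr
from habresp.availability import AvailabilityConfig, read_ascii_grid, write_ascii_grid


def circle_points(n=20, r=1.0):
    ang = np.linspace(0, 2 * np.pi, n + 1)[:-1]
    return np.c_[r * np.cos(ang), r * np.sin(ang)]


class TestMCP:
    def test_full_hull_of_unit_square(self):
        hr100 = hr.mcp_home_range([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)], 100)
        assert hr100.area == pytest.approx(1.0)
        assert hr100.n_points_used == 5

    def test_outlier_peeled_at_95(self):
        pts = np.vstack([circle_points(20), [10.0, 0.0]])  # n = 21 -> remove 2
        hr95 = hr.mcp_home_range(pts, 95)
        assert hr95.n_points_used == 19
        assert hr95.area < np.pi * 1.01
        # the far outlier must be outside the peeled hull
        assert not hr95.polygon.covers(Point(10.0, 0.0))

    def test_removal_count_follows_ceiling_rule(self):
        pts = circle_points(40)
        assert hr.mcp_home_range(pts, 95).n_points_used == 38  # ceil(0.05*40) = 2
        assert hr.mcp_home_range(pts, 90).n_points_used == 36

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="insufficient fixes"):
            hr.mcp_home_range([(0, 0), (1, 0), (0, 1)], 95)
        # 5 points but only 4 distinct
        with pytest.raises(ValueError, match="insufficient fixes"):
            hr.mcp_home_range([(0, 0), (0, 0), (1, 0), (0, 1), (1, 1)], 95)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate hull"):
            hr.mcp_home_range([(i, 0) for i in range(6)], 100)

    def test_distance_ties_keep_earlier_points(self):
        # symmetric cross: all 4 outer points equidistant from centroid
        pts = [(0, 1), (1, 0), (0, -1), (-1, 0), (0.01, 0.0), (-0.01, 0.0)]
        out = hr.mcp_home_range(pts, 84)  # n=6 -> remove 1: last tied point (-1, 0)
        assert not out.polygon.covers(Point(-1, 0))
        assert out.polygon.covers(Point(0, 1))

    @pytest.mark.parametrize("seed", range(4))
    def test_area_monotone_in_level(self, seed):
        pts = np.random.default_rng(seed).normal(0, 1, (30, 2))
        areas = [hr.mcp_home_range(pts, lvl).area for lvl in (60, 70, 80, 90, 95, 100)]
        assert all(a1 <= a2 + 1e-12 for a1, a2 in zip(areas, areas[1:]))


class TestProportions:
    def test_halved_checkerboard(self):
        codes = np.ones((10, 10), int)
        codes[:, 5:] = 2
        grid = hr.LandCoverGrid(1.0, (0.0, 0.0), codes, {1: "left", 2: "right"})
        hrx = hr.HomeRange("a", None, None, box(0, 0, 10, 10), 100.0, 10)
        p = hr.land_cover_proportions(hrx, grid)
        assert p["left"] == pytest.approx(0.5)
        assert p["right"] == pytest.approx(0.5)

    def test_single_category_region(self):
        codes = np.ones((20, 20), int)
        codes[:, 10:] = 2
        grid = hr.LandCoverGrid(1.0, (0.0, 0.0), codes, {1: "a", 2: "b"})
        hrx = hr.HomeRange("a", None, None, box(1, 1, 8, 8), 49.0, 10)
        p = hr.land_cover_proportions(hrx, grid)
        assert p["a"] == pytest.approx(1.0)
        assert p["b"] == pytest.approx(0.0)

    def test_boundary_centers_count_as_inside(self):
        codes = np.ones((4, 4), int)
        grid = hr.LandCoverGrid(1.0, (0.0, 0.0), codes, {1: "a"})
        # polygon edge passes exactly through the centers of column 0
        hrx = hr.HomeRange("a", None, None, box(0.5, 0.5, 3.5, 3.5), 9.0, 10)
        cx, cy = grid.cell_centers()
        import shapely

        inside = shapely.covers(hrx.polygon, shapely.points(cx.ravel(), cy.ravel()))
        assert inside.sum() == 16  # all 4x4 centers, boundary included

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_cell_enumeration(self, seed):
        r = np.random.default_rng(seed)
        codes = r.integers(1, 4, (60, 60))
        grid = hr.LandCoverGrid(2.0, (5.0, -3.0), codes, {1: "a", 2: "b", 3: "c"})
        hull = hr.mcp_home_range(r.uniform(10, 110, (12, 2)), 100).polygon
        hrx = hr.HomeRange("a", None, None, hull, hull.area, 12)
        p = hr.land_cover_proportions(hrx, grid)
        # brute-force oracle: test every single cell center
        counts = {"a": 0, "b": 0, "c": 0}
        cx, cy = grid.cell_centers()
        for i in range(60):
            for j in range(60):
                if hull.covers(Point(cx[i, j], cy[i, j])):
                    counts[grid.legend[int(codes[i, j])]] += 1
        total = sum(counts.values())
        assert total > 0
        for cat in counts:
            assert p[cat] == pytest.approx(counts[cat] / total, abs=1e-12)

    def test_no_overlap_raises(self):
        grid = hr.LandCoverGrid(1.0, (0.0, 0.0), np.ones((5, 5), int), {1: "a"})
        hrx = hr.HomeRange("a", None, None, box(100, 100, 110, 110), 100.0, 10)
        with pytest.raises(ValueError):
            hr.land_cover_proportions(hrx, grid)


def _telemetry_with_areas(scales, sex="female", min_fixes=12):
    """One animal-month per entry of scales, with hull area ~ scale^2."""
    rng = np.random.default_rng(0)
    rows = []
    base = circle_points(min_fixes)
    for i, s in enumerate(scales):
        pts = base * s + 50.0
        for x, y in pts:
            rows.append((f"a{i}", sex, 2005, 6, 12, x, y, "a"))
    return pd.DataFrame(rows, columns=["id", "sex", "year", "month", "hour", "x", "y", "category"])


class TestBuildAvailabilityTable:
    @pytest.fixture()
    def grid(self):
        return hr.LandCoverGrid(1.0, (0.0, 0.0), np.ones((100, 100), int), {1: "a"})

    def test_percentile_rule_excludes_largest(self, grid):
        tel = _telemetry_with_areas(np.sqrt(np.arange(1, 11)))
        table, exclusions, _ = hr.build_availability_table(
            tel, grid, AvailabilityConfig(cutoff_mode="percentile", cutoff_percentile=90)
        )
        assert len(exclusions) == 1
        assert exclusions[0].reason == "home range too large"
        assert exclusions[0].id == "a9"
        assert table["id"].nunique() == 9

    def test_absolute_thresholds_keep_everything_below(self, grid):
        tel = _telemetry_with_areas([1.0, 2.0, 3.0])
        cfg = AvailabilityConfig(
            cutoff_mode="absolute",
            absolute_thresholds={"female": 1_820_000.0, "male": 4_590_000.0},
        )
        table, exclusions, _ = hr.build_availability_table(tel, grid, cfg)
        assert exclusions == []
        assert table["id"].nunique() == 3

    def test_insufficient_fixes_logged(self, grid):
        tel = _telemetry_with_areas([1.0, 2.0])
        extra = pd.DataFrame(
            [("few", "female", 2005, 6, 1, 50 + i, 50.0 + 2 * i, "a") for i in range(3)],
            columns=tel.columns,
        )
        _, exclusions, _ = hr.build_availability_table(
            pd.concat([tel, extra]), grid, AvailabilityConfig(cutoff_mode="none")
        )
        assert any(e.id == "few" and e.reason == "insufficient fixes" for e in exclusions)

    def test_proportions_sum_to_one_per_animal_month(self):
        rng = np.random.default_rng(1)
        grid = hr.LandCoverGrid(
            1.0, (0.0, 0.0), rng.integers(1, 4, (80, 80)), {1: "a", 2: "b", 3: "c"}
        )
        tel = _telemetry_with_areas([4.0, 7.0, 10.0])
        table, _, _ = hr.build_availability_table(tel, grid, AvailabilityConfig(cutoff_mode="none"))
        sums = table.groupby(["id", "year", "month"])["proportion"].sum()
        assert np.max(np.abs(sums - 1.0)) <= 1e-9


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path):
        codes = np.arange(12).reshape(3, 4) % 3 + 1
        grid = hr.LandCoverGrid(10.0, (100.0, 200.0), codes, {1: "a", 2: "b", 3: "c"})
        path = tmp_path / "g.asc"
        write_ascii_grid(path, grid)
        back = read_ascii_grid(path, {1: "a", 2: "b", 3: "c"})
        assert np.array_equal(back.codes, codes)
        assert back.cell_size == 10.0
        assert back.origin == (100.0, 200.0)

    def test_legend_must_cover_codes(self):
        with pytest.raises(ValueError, match="legend"):
            hr.LandCoverGrid(1.0, (0, 0), np.array([[1, 2]]), {1: "a"})
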