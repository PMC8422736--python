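"""Monthly home ranges and land-cover availability within them.

Availability is third-order: the relative area of each land-cover
category inside an individual's monthly home range, estimated as a
minimum convex polygon (MCP) around the month's fixes.  At the
conventional 95% level the fixes farthest from the centroid are peeled
off before taking the convex hull, which robustifies the range against
excursions.  Proportions are obtained by counting raster cells whose
center falls inside the polygon.

Animal-months with implausibly large ranges (dispersal) are excluded
using a per-sex 90th-percentile area cut-off, or absolute per-sex
thresholds if configured; animal-months with too few fixes are
excluded as well.  Every exclusion is logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "LandCoverGrid",
    "HomeRange",
    "Exclusion",
    "mcp_home_range",
    "land_cover_proportions",
    "build_availability_table",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster with integer codes.

    ``codes[0, 0]`` is the top-left (north-west) cell; the grid origin
    ``(x0, y0)`` is the lower-left corner, matching the ESRI ASCII
    convention.
    """

    cell_size: float
    origin: tuple[float, float]
    codes: np.ndarray
    legend: Mapping[int, str]
    reference_category: str | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        present = set(np.unique(self.codes).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes without legend entry: {sorted(missing)}")
        if self.reference_category is not None and self.reference_category not in set(
            self.legend.values()
        ):
            raise ValueError("reference_category not present in legend")

    @property
    def categories(self) -> list[str]:
        return list(dict.fromkeys(self.legend.values()))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates aligned with ``codes`` (row 0 = top)."""
        nrows, ncols = self.codes.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class HomeRange:
    """Monthly MCP home range of one individual."""

    id: object
    year: int | None
    month: int | None
    polygon: Polygon
    area: float
    n_points_used: int
    level: float = 95.0

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("home-range area must be positive")


@dataclass(frozen=True)
class Exclusion:
    id: object
    year: int
    month: int
    reason: str
    detail: str = ""


def mcp_home_range(
    points: Sequence[tuple[float, float]],
    level: float = 95.0,
    *,
    id=None,
    year: int | None = None,
    month: int | None = None,
) -> HomeRange:
    """Minimum convex polygon at the given inclusion level.

    ``ceil((1 - level/100) * n)`` points farthest (Euclidean) from the
    centroid of *all* points are removed, ties broken by input order
    (earlier points kept), and the convex hull of the remainder is
    returned.  ``level=100`` is the plain convex hull.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if not 0 < level <= 100:
        raise ValueError("level must lie in (0, 100]")
    if len(np.unique(pts, axis=0)) < 5:
        raise ValueError("insufficient fixes: need at least 5 distinct points")
    n = len(pts)
    # epsilon guards the ceiling against float noise (1 - 95/100 != 0.05)
    n_remove = math.ceil((100.0 - level) / 100.0 * n - 1e-9)
    if n_remove >= n - 2:
        raise ValueError("level removes too many points for a polygon")
    if n_remove > 0:
        centroid = pts.mean(axis=0)
        dist = np.hypot(*(pts - centroid).T)
        # remove the farthest; among ties, later input points go first
        order = np.lexsort((-np.arange(n), -dist))
        keep = np.ones(n, dtype=bool)
        keep[order[:n_remove]] = False
        pts = pts[keep]
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise ValueError("degenerate hull: remaining points are collinear")
    return HomeRange(id, year, month, hull, hull.area, len(pts), level)


def land_cover_proportions(hr: HomeRange, grid: LandCoverGrid) -> pd.Series:
    """Relative availability of every category inside a home range.

    A raster cell counts as available when its *center* lies inside the
    polygon; centers exactly on the boundary count as inside.  Returns
    a Series over all legend categories summing to 1.
    """
    cx, cy = grid.cell_centers()
    minx, miny, maxx, maxy = hr.polygon.bounds
    half = 0.0
    sel = (cx >= minx - half) & (cx <= maxx + half) & (cy >= miny - half) & (cy <= maxy + half)
    if not np.any(sel):
        raise ValueError("home range does not overlap the raster")
    pts = shapely.points(cx[sel], cy[sel])
    inside = shapely.covers(hr.polygon, pts)  # covers: boundary counts as inside
    if not np.any(inside):
        raise ValueError("no raster cell centers inside the home range")
    codes_in = grid.codes[sel][inside]
    counts = pd.Series(0, index=grid.categories, dtype=float)
    for code, cnt in zip(*np.unique(codes_in, return_counts=True)):
        counts[grid.legend[int(code)]] += cnt
    return counts / counts.sum()


@dataclass
class AvailabilityConfig:
    """Exclusion and estimation settings for the availability table."""

    mcp_level: float = 95.0
    min_fixes: int = 5
    cutoff_mode: str = "percentile"  # "percentile", "absolute", or "none"
    cutoff_percentile: float = 90.0
    cutoff_scope: str = "monthly"  # "monthly" or "individual"
    absolute_thresholds: Mapping[str, float] | None = None  # per sex, area units


def build_availability_table(
    telemetry: pd.DataFrame,
    grid: LandCoverGrid,
    config: AvailabilityConfig | None = None,
) -> tuple[pd.DataFrame, list[Exclusion], list[HomeRange]]:
    """Per animal-month availability with home-range-size screening.

    Returns ``(table, exclusions, home_ranges)`` where ``table`` has
    columns (id, sex, year, month, category, proportion) and each kept
    animal-month's proportions sum to 1.  Animal-months are dropped
    (and logged) when they have fewer than ``min_fixes`` fixes, a
    degenerate hull, or an area above the configured cut-off
    (per-sex 90th percentile of monthly areas by default, or absolute
    per-sex thresholds, applied monthly or per individual).
    """
    if telemetry.empty:
        raise ValueError("telemetry is empty")
    config = config or AvailabilityConfig()
    exclusions: list[Exclusion] = []
    ranges: list[HomeRange] = []
    meta: list[tuple] = []  # (id, sex, year, month, hr)
    for (aid, sex, year, month), g in telemetry.groupby(["id", "sex", "year", "month"], sort=True):
        pts = g[["x", "y"]].to_numpy()
        if len(np.unique(pts, axis=0)) < max(config.min_fixes, 5):
            exclusions.append(Exclusion(aid, year, month, "insufficient fixes",
                                        f"{len(pts)} fixes"))
            continue
        try:
            hr = mcp_home_range(pts, config.mcp_level, id=aid, year=year, month=month)
        except ValueError as e:
            exclusions.append(Exclusion(aid, year, month, "degenerate hull", str(e)))
            continue
        meta.append((aid, sex, year, month, hr))

    if meta and config.cutoff_mode != "none":
        areas = pd.DataFrame(
            [(aid, sex, y, m, hr.area) for aid, sex, y, m, hr in meta],
            columns=["id", "sex", "year", "month", "area"],
        )
        if config.cutoff_mode == "absolute":
            if not config.absolute_thresholds:
                raise ValueError("absolute cutoff mode requires absolute_thresholds")
            thr = dict(config.absolute_thresholds)
        elif config.cutoff_mode == "percentile":
            if config.cutoff_scope == "individual":
                per_ind = areas.groupby(["sex", "id"])["area"].mean().reset_index()
                thr = {
                    s: np.percentile(g["area"], config.cutoff_percentile)
                    for s, g in per_ind.groupby("sex")
                }
                too_big_ids = {
                    row["id"]
                    for _, row in per_ind.iterrows()
                    if row["area"] > thr[row["sex"]]
                }
            else:
                thr = {
                    s: np.percentile(g["area"], config.cutoff_percentile)
                    for s, g in areas.groupby("sex")
                }
        else:
            raise ValueError(f"unknown cutoff_mode {config.cutoff_mode!r}")

        kept = []
        for aid, sex, y, m, hr in meta:
            if config.cutoff_mode == "percentile" and config.cutoff_scope == "individual":
                bad = aid in too_big_ids
            else:
                bad = hr.area > thr.get(sex, math.inf)
            if bad:
                exclusions.append(
                    Exclusion(aid, y, m, "home range too large",
                              f"area={hr.area:.6g} > cutoff={thr.get(sex, math.inf):.6g}")
                )
            else:
                kept.append((aid, sex, y, m, hr))
        meta = kept

    rows = []
    for aid, sex, y, m, hr in meta:
        try:
            props = land_cover_proportions(hr, grid)
        except ValueError as e:
            exclusions.append(Exclusion(aid, y, m, "no raster overlap", str(e)))
            continue
        ranges.append(hr)
        for cat, p in props.items():
            rows.append((aid, sex, y, m, cat, float(p)))
    table = pd.DataFrame(rows, columns=["id", "sex", "year", "month", "category", "proportion"])
    return table, exclusions, ranges


# -- ESRI ASCII grid IO -------------------------------------------------


def read_ascii_grid(
    path, legend: Mapping[int, str], reference_category: str | None = None
) -> LandCoverGrid:
    """Read a single-band integer ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_head = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_head += 1
        else:
            break
    codes = np.loadtxt(lines[n_head:], dtype=int)
    codes = np.atleast_2d(codes)
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid dimensions do not match header")
    return LandCoverGrid(
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        codes=codes,
        legend=legend,
        reference_category=reference_category,
    )


def write_ascii_grid(path, grid: LandCoverGrid) -> None:
    nrows, ncols = grid.codes.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\nyllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        for row in grid.codes:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
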