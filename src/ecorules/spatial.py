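"""Species-range climate metrics from monthly rasters and seasonal polygons.

Given 12-layer monthly stacks of minimum / average / maximum temperature and
per-species seasonal range polygons, this module derives the five per-species
temperature metrics used to test ecogeographical rules:

* ``max_temp_all_months``   — largest monthly zonal mean of Tmax over the
  warm-season ranges (breeding plus year-round),
* ``avg_temp_hottest_month`` — largest monthly zonal mean of Tavg over the
  warm-season ranges,
* ``avg_temp_all_months``   — mean of the monthly Tavg zonal means over all
  seasonal ranges,
* ``avg_temp_coldest_month`` — smallest monthly zonal mean of Tavg over the
  cold-season ranges (winter plus year-round),
* ``min_temp_all_months``   — smallest monthly zonal mean of Tmin over the
  cold-season ranges,

plus the absolute latitude of the all-season range centroid and the range
area on an equal-area (Eckert IV) projection.

Zonal means use pixel-centre containment (unweighted over included pixels)
with an all-touched fallback for sliver polygons.  Raster stacks are stored
as plain arrays with a north-up affine grid; file I/O is multiband TIFF plus
a JSON sidecar carrying the grid geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union
from scipy import stats

SEASONS = ("breeding", "winter", "year_round")

#: authalic Earth radius (m): the sphere with the WGS84 ellipsoid's area
EARTH_RADIUS = 6371007.1809


class SpatialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class RangePolygonSet:
    """Per-species seasonal range polygons with presence/origin flags.

    ``frame`` columns: species, season (breeding | winter | year_round, or
    flagged uncertain), presence, origin, geometry (shapely).
    """

    frame: pd.DataFrame
    crs: str = "EPSG:4326"

    REQUIRED = ("species", "season", "presence", "origin", "geometry")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise SpatialError(f"range table missing columns {sorted(missing)}")

    def __len__(self):
        return len(self.frame)

    # GeoJSON I/O -----------------------------------------------------------

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RangePolygonSet":
        with open(path) as fh:
            gj = json.load(fh)
        crs = gj.get("crs", {}).get("properties", {}).get("name", "EPSG:4326")
        rows = []
        for feat in gj["features"]:
            props = feat.get("properties", {})
            rows.append({
                "species": props.get("species"),
                "season": props.get("season"),
                "presence": props.get("presence", "extant"),
                "origin": props.get("origin", "native"),
                "geometry": shape(feat["geometry"]),
            })
        return cls(frame=pd.DataFrame(rows), crs=crs)

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for _, row in self.frame.iterrows():
            feats.append({
                "type": "Feature",
                "properties": {k: row[k] for k in
                               ("species", "season", "presence", "origin")},
                "geometry": mapping(row["geometry"]),
            })
        gj = {"type": "FeatureCollection", "features": feats,
              "crs": {"type": "name", "properties": {"name": self.crs}}}
        with open(path, "w") as fh:
            json.dump(gj, fh)


@dataclass
class MonthlyRasterStack:
    """Twelve monthly grids of one temperature variable on a north-up grid.

    Pixel (row, col) has centre ``(west + (col+0.5)*dx, north - (row+0.5)*dy)``.
    """

    variable: str                # Tmin | Tavg | Tmax
    data: np.ndarray             # (12, nrow, ncol)
    west: float
    north: float
    dx: float
    dy: float
    nodata: float = -9999.0
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 12:
            raise SpatialError(
                f"expected 12 monthly layers, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def x_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.dy

    # TIFF + JSON sidecar I/O ----------------------------------------------

    def to_file(self, path: str | Path) -> None:
        import tifffile
        path = Path(path)
        tifffile.imwrite(path, self.data.astype("float32"))
        meta = {"variable": self.variable, "west": self.west,
                "north": self.north, "dx": self.dx, "dy": self.dy,
                "nodata": self.nodata, "crs": self.crs}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_file(cls, path: str | Path) -> "MonthlyRasterStack":
        import tifffile
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data=data, **meta)


# ---------------------------------------------------------------------------
# Filtering and aggregation
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    ranges: RangePolygonSet
    report: pd.DataFrame      # per-species kept/dropped polygon counts
    excluded_species: list[str]


_GOOD_PRESENCE = {"extant"}
_GOOD_ORIGIN = {"native"}


def filter_ranges(raw: RangePolygonSet) -> FilterResult:
    """Keep only certain, native, extant polygons with a known season.

    Species whose polygons are all dropped are listed in
    ``excluded_species`` (and the report) rather than raising.
    """
    df = raw.frame
    ok = (df["presence"].isin(_GOOD_PRESENCE)
          & df["origin"].isin(_GOOD_ORIGIN)
          & df["season"].isin(SEASONS))
    report = (pd.DataFrame({"species": df["species"], "kept": ok})
              .groupby("species")["kept"].agg(["sum", "count"])
              .rename(columns={"sum": "kept", "count": "total"})
              .reset_index())
    report["dropped"] = report["total"] - report["kept"]
    excluded = report.loc[report["kept"] == 0, "species"].tolist()
    clean = RangePolygonSet(frame=df[ok].reset_index(drop=True), crs=raw.crs)
    return FilterResult(ranges=clean, report=report, excluded_species=excluded)


def aggregate_season(clean: RangePolygonSet) -> pd.DataFrame:
    """Unary union of polygons per (species, season).

    Returns a frame with columns species, season, geometry; invalid unions
    are repaired with ``make_valid`` and an error names the species if the
    repair fails.
    """
    rows = []
    for (sp, season), grp in clean.frame.groupby(["species", "season"],
                                                 sort=True):
        geom = unary_union(list(grp["geometry"]))
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if not geom.is_valid or geom.is_empty:
            raise SpatialError(
                f"could not build a valid union for {sp} / {season}")
        rows.append({"species": sp, "season": season, "geometry": geom})
    return pd.DataFrame(rows, columns=["species", "season", "geometry"])


# ---------------------------------------------------------------------------
# Zonal statistics
# ---------------------------------------------------------------------------


def zonal_monthly_means(stack: MonthlyRasterStack, geometry) -> np.ndarray:
    """Mean of non-nodata pixels inside ``geometry`` for each of 12 months.

    Pixels are included when their centre falls inside the geometry; if no
    centre is covered the rule falls back to any pixel whose cell intersects
    the geometry (all-touched), and an error is raised if the geometry still
    covers nothing or only nodata.
    """
    minx, miny, maxx, maxy = geometry.bounds
    nrow, ncol = stack.shape
    c0 = max(0, int(math.floor((minx - stack.west) / stack.dx)) - 1)
    c1 = min(ncol, int(math.ceil((maxx - stack.west) / stack.dx)) + 1)
    r0 = max(0, int(math.floor((stack.north - maxy) / stack.dy)) - 1)
    r1 = min(nrow, int(math.ceil((stack.north - miny) / stack.dy)) + 1)
    if c0 >= c1 or r0 >= r1:
        raise SpatialError("geometry does not intersect the raster grid")
    xs = stack.x_centers()[c0:c1]
    ys = stack.y_centers()[r0:r1]
    XX, YY = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geometry, XX.ravel(), YY.ravel())
    inside = inside.reshape(XX.shape)
    if not inside.any():
        half_x, half_y = stack.dx / 2.0, stack.dy / 2.0
        cells = shapely.box(XX.ravel() - half_x, YY.ravel() - half_y,
                            XX.ravel() + half_x, YY.ravel() + half_y)
        inside = shapely.intersects(cells, geometry).reshape(XX.shape)
        if not inside.any():
            raise SpatialError(
                "geometry covers no raster pixels, even all-touched")
    window = stack.data[:, r0:r1, c0:c1]
    means = np.empty(12)
    for m in range(12):
        vals = window[m][inside]
        vals = vals[vals != stack.nodata]
        if vals.size == 0:
            raise SpatialError("geometry covers only nodata pixels")
        means[m] = vals.mean()
    return means


# ---------------------------------------------------------------------------
# Temperature metrics
# ---------------------------------------------------------------------------

#: season sets over which each metric is computed
SEASON_SETS = {"warm": ("breeding", "year_round"),
               "cold": ("winter", "year_round"),
               "all": ("breeding", "winter", "year_round")}

METRICS = ("max_temp_all_months", "avg_temp_hottest_month",
           "avg_temp_all_months", "avg_temp_coldest_month",
           "min_temp_all_months")


def seasonal_union(aggregated: pd.DataFrame, species: str,
                   seasons: Iterable[str]):
    """Union of a species' aggregated geometries over a season set."""
    sel = aggregated[(aggregated["species"] == species)
                     & (aggregated["season"].isin(list(seasons)))]
    if sel.empty:
        return None
    return unary_union(list(sel["geometry"]))


def compute_zonal_tables(stacks: Mapping[str, MonthlyRasterStack],
                         aggregated: pd.DataFrame) -> pd.DataFrame:
    """Monthly zonal means per species x season-set x variable.

    Columns: species, season_set (warm|cold|all), variable, month (1-12),
    mean.  Missing season sets yield no rows (handled downstream).
    """
    needed = {"warm": ["Tmax", "Tavg"], "cold": ["Tmin", "Tavg"],
              "all": ["Tavg"]}
    rows = []
    for sp in aggregated["species"].unique():
        for set_name, seasons in SEASON_SETS.items():
            geom = seasonal_union(aggregated, sp, seasons)
            if geom is None:
                continue
            for var in needed[set_name]:
                means = zonal_monthly_means(stacks[var], geom)
                for m, val in enumerate(means, start=1):
                    rows.append({"species": sp, "season_set": set_name,
                                 "variable": var, "month": m,
                                 "mean": float(val)})
    return pd.DataFrame(rows)


def temperature_metrics(zonal: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The five per-species temperature metrics from a zonal-means table.

    Returns ``(metrics, report)``; metrics a species-missing season set
    cannot support are NaN, with the reason in ``report``.
    """
    defs = [
        ("max_temp_all_months", "warm", "Tmax", "max"),
        ("avg_temp_hottest_month", "warm", "Tavg", "max"),
        ("avg_temp_all_months", "all", "Tavg", "mean"),
        ("avg_temp_coldest_month", "cold", "Tavg", "min"),
        ("min_temp_all_months", "cold", "Tmin", "min"),
    ]
    out = []
    issues = []
    for sp, grp in zonal.groupby("species", sort=True):
        row = {"species": sp}
        for metric, set_name, var, how in defs:
            sel = grp[(grp["season_set"] == set_name)
                      & (grp["variable"] == var)]
            if sel.empty:
                row[metric] = np.nan
                issues.append({"species": sp, "metric": metric,
                               "reason": f"no {set_name}-season range"})
                continue
            vals = sel.sort_values("month")["mean"].to_numpy()
            row[metric] = float(getattr(np, how)(vals))
        out.append(row)
    metrics = pd.DataFrame(out, columns=["species", *METRICS])
    report = pd.DataFrame(issues, columns=["species", "metric", "reason"])
    return metrics, report


# ---------------------------------------------------------------------------
# Centroid latitude and equal-area range size
# ---------------------------------------------------------------------------


def centroid_abs_latitude(geometry) -> float:
    """Absolute latitude (degrees) of the geometry centroid."""
    if geometry is None or geometry.is_empty:
        raise SpatialError("empty geometry has no centroid")
    return float(abs(geometry.centroid.y))


def _eckert4(lon: np.ndarray, lat: np.ndarray,
             radius: float = EARTH_RADIUS) -> tuple[np.ndarray, np.ndarray]:
    """Forward Eckert IV equal-area projection (sphere), vectorised.

    Solves ``theta + sin(theta) cos(theta) + 2 sin(theta) =
    (2 + pi/2) sin(phi)`` by Newton iteration.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    target = (2.0 + math.pi / 2.0) * np.sin(phi)
    theta = phi / 2.0
    for _ in range(50):
        f = theta + np.sin(theta) * np.cos(theta) + 2.0 * np.sin(theta) - target
        fp = 1.0 + np.cos(2.0 * theta) + 2.0 * np.cos(theta)
        step = f / np.where(np.abs(fp) < 1e-12, 1e-12, fp)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-14:
            break
    x = 2.0 / math.sqrt(math.pi * (4.0 + math.pi)) * radius * lam \
        * (1.0 + np.cos(theta))
    y = 2.0 * math.sqrt(math.pi / (4.0 + math.pi)) * radius * np.sin(theta)
    return x, y


def range_area(geometry, crs: str = "EPSG:4326",
               densify_deg: float = 0.25) -> float:
    """Range area in m^2.

    Geographic inputs (EPSG:4326) are densified and projected to Eckert IV
    (equal-area) before the planar area is taken; already-planar inputs
    (synthetic worlds, metric CRSs) report their native-CRS area.
    """
    if geometry is None or geometry.is_empty:
        raise SpatialError("empty geometry has no area")
    if crs.upper() in {"EPSG:4326", "WGS84", "CRS84", "OGC:CRS84"}:
        geom = shapely.segmentize(geometry, densify_deg)

        def proj(coords: np.ndarray) -> np.ndarray:
            x, y = _eckert4(coords[:, 0], coords[:, 1])
            return np.column_stack([x, y])

        try:
            projected = shapely.transform(geom, proj)
        except Exception as exc:
            raise SpatialError(
                f"Eckert IV reprojection failed for CRS {crs}: {exc}") from exc
        return float(projected.area)
    return float(geometry.area)


# ---------------------------------------------------------------------------
# Response transforms
# ---------------------------------------------------------------------------


def transform_response(values, method: str = "identity",
                       eps: float = 0.5) -> tuple[np.ndarray, dict]:
    """Strictly monotone transforms for left-skewed temperature responses.

    ``reflect_log``: ``-ln(max + eps - x)`` (eps in the same units, default
    0.5 degC); ``rank_normal``: normal scores of the mid-ranks.  Returns the
    transformed array and a provenance record.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in response")
    meta = {"method": method}
    if method == "identity":
        out = x.copy()
    elif method == "reflect_log":
        pivot = float(x.max()) + eps
        if np.any(x >= pivot):
            raise ValueError("values at or above the reflection point")
        out = -np.log(pivot - x)
        meta.update(pivot=pivot, eps=eps)
    elif method == "rank_normal":
        ranks = stats.rankdata(x, method="average")
        out = stats.norm.ppf((ranks - 0.5) / len(x))
        meta.update(n=len(x))
    else:
        raise ValueError(f"unknown transform {method!r}")
    return out, meta


# ---------------------------------------------------------------------------
# High-level per-species climate table
# ---------------------------------------------------------------------------


def species_climate(stacks: Mapping[str, MonthlyRasterStack],
                    aggregated: pd.DataFrame,
                    crs: str = "EPSG:4326") -> pd.DataFrame:
    """One row per species: five temperature metrics, |latitude|, area."""
    zonal = compute_zonal_tables(stacks, aggregated)
    metrics, _report = temperature_metrics(zonal)
    rows = []
    for sp in aggregated["species"].unique():
        geom = seasonal_union(aggregated, sp, SEASON_SETS["all"])
        rows.append({"species": sp,
                     "abs_latitude": centroid_abs_latitude(geom),
                     "range_area_m2": range_area(geom, crs=crs)})
    extra = pd.DataFrame(rows)
    return metrics.merge(extra, on="species", how="left")
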