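"""Zonal statistics, temperature metrics, areas and response transforms."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from ecorules import spatial
from ecorules.spatial import (MonthlyRasterStack, RangePolygonSet,
                              SpatialError, aggregate_season,
                              centroid_abs_latitude, filter_ranges,
                              range_area, temperature_metrics,
                              transform_response, zonal_monthly_means)


def _stack(data, west=0.0, north=None, dx=1.0, dy=1.0, variable="Tavg"):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = np.repeat(data[None], 12, axis=0)
    north = north if north is not None else data.shape[1] * dy
    return MonthlyRasterStack(variable=variable, data=data, west=west,
                              north=north, dx=dx, dy=dy)


def _ranges(rows):
    return RangePolygonSet(frame=pd.DataFrame(rows))


def _poly_row(species, season="year_round", presence="extant",
              origin="native", geom=None):
    return {"species": species, "season": season, "presence": presence,
            "origin": origin, "geometry": geom or box(0, 0, 1, 1)}


class TestFilterRanges:
    def test_extinct_polygon_removed(self):
        raw = _ranges([_poly_row("a"), _poly_row("a", presence="extinct")])
        res = filter_ranges(raw)
        assert len(res.ranges) == 1
        assert res.report.loc[0, "dropped"] == 1

    def test_clean_set_unchanged_and_idempotent(self):
        raw = _ranges([_poly_row("a"), _poly_row("b", season="breeding")])
        res = filter_ranges(raw)
        assert len(res.ranges) == 2
        again = filter_ranges(res.ranges)
        assert len(again.ranges) == 2
        assert again.excluded_species == []

    def test_species_losing_all_polygons_reported(self):
        raw = _ranges([_poly_row("a", origin="introduced"),
                       _poly_row("b")])
        res = filter_ranges(raw)
        assert res.excluded_species == ["a"]


class TestAggregateSeason:
    def test_disjoint_parts_kept_as_multipolygon(self):
        raw = _ranges([_poly_row("a", geom=box(0, 0, 1, 1)),
                       _poly_row("a", geom=box(2, 0, 3, 1))])
        agg = aggregate_season(raw)
        assert len(agg) == 1
        assert isinstance(agg.iloc[0]["geometry"], MultiPolygon)
        assert agg.iloc[0]["geometry"].area == pytest.approx(2.0)

    def test_overlapping_parts_union_smaller_than_sum(self):
        raw = _ranges([_poly_row("a", geom=box(0, 0, 2, 1)),
                       _poly_row("a", geom=box(1, 0, 3, 1))])
        agg = aggregate_season(raw)
        assert agg.iloc[0]["geometry"].area == pytest.approx(3.0)

    def test_one_row_per_species_season(self):
        raw = _ranges([_poly_row("a"), _poly_row("a", season="breeding"),
                       _poly_row("b")])
        agg = aggregate_season(raw)
        assert set(map(tuple, agg[["species", "season"]].values)) == {
            ("a", "year_round"), ("a", "breeding"), ("b", "year_round")}

    def test_idempotent(self):
        raw = _ranges([_poly_row("a", geom=box(0, 0, 2, 1)),
                       _poly_row("a", geom=box(1, 0, 3, 1))])
        agg1 = aggregate_season(raw)
        agg2 = aggregate_season(RangePolygonSet(frame=agg1.assign(
            presence="extant", origin="native")))
        assert agg1.iloc[0]["geometry"].equals(agg2.iloc[0]["geometry"])


class TestZonalMeans:
    def test_uniform_raster(self):
        stack = _stack(np.full((4, 4), 10.0))
        out = zonal_monthly_means(stack, box(0.2, 0.2, 3.8, 3.8))
        np.testing.assert_allclose(out, 10.0)

    def test_left_column_of_2x2(self):
        stack = _stack(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = zonal_monthly_means(stack, box(0, 0, 1, 2))
        np.testing.assert_allclose(out, 2.0)

    def test_matches_bruteforce_pixel_centers(self):
        """Windowed zonal mean equals a full-grid brute-force scan."""
        rng = np.random.default_rng(5)
        data = rng.normal(10, 5, size=(12, 60, 80))
        stack = _stack(data, west=-40.0, north=30.0)
        geom = Point(-10.0, 5.0).buffer(13.7, quad_segs=8)
        out = zonal_monthly_means(stack, geom)
        xs = stack.x_centers()
        ys = stack.y_centers()
        import shapely
        for m in range(12):
            acc = []
            for r in range(60):
                for c in range(80):
                    if shapely.contains_xy(geom, xs[c], ys[r]):
                        acc.append(data[m, r, c])
            assert out[m] == np.mean(acc)  # exact: same pixels, same sum

    def test_nodata_pixels_excluded(self):
        data = np.full((2, 2), 5.0)
        data[0, 0] = -9999.0
        stack = _stack(data)
        out = zonal_monthly_means(stack, box(0, 0, 2, 2))
        np.testing.assert_allclose(out, 5.0)

    def test_sliver_falls_back_to_all_touched(self):
        stack = _stack(np.array([[1.0, 2.0], [3.0, 4.0]]))
        # tiny polygon in the corner of pixel (1, 0): no centre covered
        out = zonal_monthly_means(stack, box(0.01, 0.01, 0.1, 0.1))
        np.testing.assert_allclose(out, 3.0)

    def test_outside_grid_errors(self):
        stack = _stack(np.ones((2, 2)))
        with pytest.raises(SpatialError):
            zonal_monthly_means(stack, box(100, 100, 101, 101))


class TestTemperatureMetrics:
    def _zonal(self, rows):
        return pd.DataFrame(rows, columns=["species", "season_set",
                                           "variable", "month", "mean"])

    def test_constant_field_resident(self):
        rows = []
        for set_name, var in (("warm", "Tmax"), ("warm", "Tavg"),
                              ("all", "Tavg"), ("cold", "Tavg"),
                              ("cold", "Tmin")):
            rows += [{"species": "a", "season_set": set_name,
                      "variable": var, "month": m, "mean": 10.0}
                     for m in range(1, 13)]
        metrics, report = temperature_metrics(self._zonal(rows))
        for col in spatial.METRICS:
            assert metrics.loc[0, col] == pytest.approx(10.0)
        assert report.empty

    def test_sinusoidal_cycle_matches_closed_form(self):
        """Metrics equal the analytic extremes of a seasonal sinusoid."""
        base, amp, spread = 15.0, 8.0, 6.0
        rows = []
        for m in range(1, 13):
            s = base + amp * math.cos(2 * math.pi * (m - 7) / 12.0)
            for set_name in ("warm", "cold", "all"):
                rows.append({"species": "a", "season_set": set_name,
                             "variable": "Tavg", "month": m, "mean": s})
            rows.append({"species": "a", "season_set": "warm",
                         "variable": "Tmax", "month": m, "mean": s + spread})
            rows.append({"species": "a", "season_set": "cold",
                         "variable": "Tmin", "month": m, "mean": s - spread})
        metrics, _ = temperature_metrics(self._zonal(rows))
        row = metrics.iloc[0]
        assert row["max_temp_all_months"] == pytest.approx(base + amp + spread)
        assert row["avg_temp_hottest_month"] == pytest.approx(base + amp)
        assert row["avg_temp_all_months"] == pytest.approx(base)
        assert row["avg_temp_coldest_month"] == pytest.approx(base - amp)
        assert row["min_temp_all_months"] == pytest.approx(base - amp - spread)
        # ordering invariant
        vals = [row[c] for c in reversed(spatial.METRICS)]
        assert vals == sorted(vals)

    def test_missing_season_set_reported(self):
        rows = [{"species": "a", "season_set": "warm", "variable": "Tmax",
                 "month": m, "mean": 1.0} for m in range(1, 13)]
        metrics, report = temperature_metrics(self._zonal(rows))
        assert np.isnan(metrics.loc[0, "min_temp_all_months"])
        assert "no cold-season range" in set(report["reason"])


class TestLatitudeAndArea:
    def test_equator_symmetric_square(self):
        assert centroid_abs_latitude(box(-5, -10, 5, 10)) == pytest.approx(0.0)

    def test_mid_latitude_square(self):
        assert centroid_abs_latitude(box(0, 40, 10, 50)) == pytest.approx(45.0)

    def test_multipolygon_area_weighted_centroid(self):
        big = box(0, 0, 2, 2)       # area 4, centroid y=1
        small = box(0, 10, 1, 11)   # area 1, centroid y=10.5
        geom = MultiPolygon([big, small])
        expect = (4 * 1.0 + 1 * 10.5) / 5
        assert centroid_abs_latitude(geom) == pytest.approx(expect)

    def test_planar_area_native(self):
        assert range_area(box(0, 0, 1, 1), crs="local-metric") == 1.0

    def test_disjoint_parts_sum(self):
        geom = MultiPolygon([box(0, 0, 1, 1), box(5, 5, 7, 6)])
        assert range_area(geom, crs="local-metric") == pytest.approx(3.0)

    def test_eckert_iv_matches_geodesic_oracle(self):
        """Equal-area projected area vs spherical-excess area, within 0.5%."""
        geom = box(10.0, 40.0, 20.0, 50.0)
        a_proj = range_area(geom, crs="EPSG:4326")
        a_sphere = _spherical_area(geom)
        assert a_proj == pytest.approx(a_sphere, rel=0.005)

    def test_global_band_area(self):
        """A full-longitude band has a closed-form spherical area."""
        geom = box(-180.0, -10.0, 180.0, 10.0)
        R = spatial.EARTH_RADIUS
        expect = 2 * math.pi * R**2 * (math.sin(math.radians(10))
                                       - math.sin(math.radians(-10)))
        assert range_area(geom, crs="EPSG:4326") == pytest.approx(
            expect, rel=0.005)


def _spherical_area(geom, radius=spatial.EARTH_RADIUS):
    """Independent geodesic oracle: spherical shoelace on a densified ring."""
    import shapely
    geom = shapely.segmentize(geom, 0.05)
    total = 0.0
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        lon, lat = np.asarray(poly.exterior.coords).T
        lam = np.radians(lon)
        phi = np.radians(lat)
        # Chamberlain & Duquette spherical excess formula
        s = np.sum((lam[1:] - lam[:-1])
                   * (2 + np.sin(phi[1:]) + np.sin(phi[:-1])))
        total += abs(s) * radius**2 / 2.0
    return total


class TestTransformResponse:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        out, meta = transform_response(x, "identity")
        np.testing.assert_allclose(out, x)
        assert meta["method"] == "identity"

    @pytest.mark.parametrize("method", ["reflect_log", "rank_normal"])
    def test_strictly_monotone(self, method):
        rng = np.random.default_rng(3)
        x = np.sort(rng.normal(size=50))
        out, _ = transform_response(x, method)
        assert np.all(np.diff(out) > 0)

    def test_reflect_log_reduces_left_skew(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        x = 30.0 - rng.gamma(2.0, 4.0, size=2000)  # left-skewed
        out, _ = transform_response(x, "reflect_log")
        assert abs(stats.skew(out)) < abs(stats.skew(x))

    def test_reflect_log_domain_guard(self):
        with pytest.raises(ValueError):
            transform_response([1.0, 2.0], "reflect_log", eps=0.0)


class TestRasterIO:
    def test_tiff_sidecar_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = _stack(rng.normal(size=(12, 5, 7)), west=-3.0, north=4.0,
                       dx=0.5, dy=0.5, variable="Tmin")
        path = tmp_path / "tmin.tif"
        stack.to_file(path)
        back = MonthlyRasterStack.from_file(path)
        assert back.variable == "Tmin"
        assert back.west == -3.0 and back.dy == 0.5
        np.testing.assert_allclose(back.data, stack.data, atol=1e-6)


class TestGeoJSONIO:
    def test_roundtrip(self, tmp_path):
        raw = _ranges([_poly_row("a"), _poly_row("b", season="breeding")])
        path = tmp_path / "r.geojson"
        raw.to_geojson(path)
        back = RangePolygonSet.from_geojson(path)
        assert list(back.frame["species"]) == ["a", "b"]
        assert back.frame.iloc[0]["geometry"].equals(box(0, 0, 1, 1))


class TestSplitInvariance:
    def test_metrics_invariant_to_splitting_polygon(self):
        """Halving a polygon into adjacent parts changes no metric."""
        rng = np.random.default_rng(9)
        stacks = {}
        for var, off in (("Tmin", -5.0), ("Tavg", 0.0), ("Tmax", 5.0)):
            stacks[var] = _stack(rng.normal(10, 3, size=(12, 20, 20)) + off,
                                 variable=var, north=20.0)
        whole = _ranges([_poly_row("a", geom=box(2, 2, 18, 18))])
        halves = _ranges([_poly_row("a", geom=box(2, 2, 10, 18)),
                          _poly_row("a", geom=box(10, 2, 18, 18))])
        t1 = spatial.species_climate(stacks, aggregate_season(whole),
                                     crs="local")
        t2 = spatial.species_climate(stacks, aggregate_season(halves),
                                     crs="local")
        pd.testing.assert_frame_equal(t1, t2)
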