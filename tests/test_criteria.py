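import numpy as np
import pytest
from shapely.geometry import LineString

from aumex.criteria import (
    SourcePoint,
    Zones,
    aum_proximity,
    drainage_layer,
    idw_hazard,
    landform_classify,
    road_proximity,
    slope_aspect,
    topographic_exposure,
    tpi,
    trace_downstream,
    voronoi_zones,
    wind_index,
)
from aumex.met import WindField
from aumex.raster import Grid, Raster


def wind_field(grid, direction, speed=1.0):
    return WindField(
        direction=Raster(grid, np.full(grid.shape, float(direction))),
        speed=Raster(grid, np.full(grid.shape, float(speed))),
    )


def const_raster(grid, v):
    return Raster(grid, np.full(grid.shape, float(v)))


class TestAumProximity:
    def test_hand_value(self, grid):
        # area 10000 m^2 at distance 1000 m -> 10
        src = SourcePoint("a", 1050.0, 1550.0, 10_000.0)
        r = aum_proximity(grid, [src])
        assert r.values[0, 0] == pytest.approx(10.0)

    def test_radius_cutoff(self, grid):
        src = SourcePoint("a", 60_000.0, 1550.0, 10_000.0)
        r = aum_proximity(grid, [src], radius=50_000.0)
        assert r.values[0, 0] == 0.0

    def test_additivity_of_identical_sources(self, grid):
        a = SourcePoint("a", 1050.0, 1550.0, 10_000.0)
        b = SourcePoint("b", 1050.0, 1550.0, 10_000.0)
        single = aum_proximity(grid, [a])
        double = aum_proximity(grid, [a, b])
        np.testing.assert_allclose(double.values, 2 * single.values)

    def test_distance_floor_at_source_cell(self, grid):
        src = SourcePoint("a", 50.0, 1550.0, 100.0)
        r = aum_proximity(grid, [src])
        assert r.values[0, 0] == pytest.approx(100.0 / 50.0)  # floored at half cell


class TestTraceDownstream:
    def test_inclined_plane_runs_straight_east(self, inclined_dem, grid):
        start = SourcePoint("a", 50.0, 750.0, 1.0)
        path = trace_downstream(inclined_dem, start)
        rows = [rc[0] for rc in path]
        cols = [rc[1] for rc in path]
        assert cols == list(range(16))
        assert len(set(rows)) == 1

    def test_pit_gives_single_cell_path(self, grid):
        vals = np.full(grid.shape, 10.0)
        vals[8, 8] = 1.0
        dem = Raster(grid, vals)
        start = SourcePoint("a", 850.0, 750.0, 1.0)  # cell (8, 8)
        assert trace_downstream(dem, start) == [(8, 8)]

    def test_elevations_non_increasing_on_synthetic_dem(self):
        from aumex.synthetic_world import generate_terrain

        grid = Grid(32, 32, 100.0, 0.0, 3200.0)
        dem = generate_terrain(grid, 1.2, 50.0, seed=6)
        start = SourcePoint("a", 1550.0, 1650.0, 1.0)
        path = trace_downstream(dem, start)
        elevs = [dem.values[rc] for rc in path]
        assert all(b <= a for a, b in zip(elevs, elevs[1:]))

    def test_outside_grid_rejected(self, inclined_dem):
        with pytest.raises(ValueError):
            trace_downstream(inclined_dem, SourcePoint("a", -500.0, 0.0, 1.0))


class TestDrainageLayer:
    def _straight_world(self):
        # 64-cell wide inclined plane, 100 m cells: flow runs straight east
        grid = Grid(8, 64, 100.0, 0.0, 800.0)
        xx, _ = grid.cell_centers()
        dem = Raster(grid, 100.0 - xx * 0.01)
        return grid, dem

    def test_reciprocal_distance_hand_example(self):
        grid, dem = self._straight_world()
        src = SourcePoint("a", 50.0, 450.0, 1.0)  # cell (3, 0); path along row 3
        # zones: three one-row stripes acting as zones with centroids on/off path
        labels = np.zeros(grid.shape)
        labels[:, :] = 2  # background zone, centroid far from path midline
        centroids = np.array([
            [1050.0, 450.0],   # zone 0: on-path, 1 km along
            [2050.0, 450.0],   # zone 1: on-path, 2 km along
            [3000.0, 50.0],    # zone 2 centroid, off path (> threshold away)
        ])
        labels[3, 9:12] = 0
        labels[3, 19:22] = 1
        zones = Zones(Raster(grid, labels), centroids, mean_boundary_length=200.0)
        out = drainage_layer(dem, [src], zones, snap_threshold=200.0)
        assert out.values[3, 10] == pytest.approx(1.0, abs=1e-12)   # 1/1 km
        assert out.values[3, 20] == pytest.approx(0.5, abs=1e-12)   # 1/2 km
        assert out.values[0, 40] == 0.0                             # off-path zone

    def test_monotone_decay_along_path(self):
        grid, dem = self._straight_world()
        src = SourcePoint("a", 50.0, 450.0, 1.0)
        zones = voronoi_zones(grid, 24, seed=2)
        out = drainage_layer(dem, [src], zones, snap_threshold=300.0)
        on_path = out.values[3, :]
        nz = np.flatnonzero(on_path > 0)
        if len(nz) >= 2:
            assert on_path[nz[0]] > on_path[nz[-1]]

    def test_additive_over_source_subsets(self):
        grid, dem = self._straight_world()
        a = SourcePoint("a", 50.0, 450.0, 1.0)
        b = SourcePoint("b", 50.0, 250.0, 1.0)
        zones = voronoi_zones(grid, 24, seed=3)
        both = drainage_layer(dem, [a, b], zones, snap_threshold=300.0)
        va = drainage_layer(dem, [a], zones, snap_threshold=300.0)
        vb = drainage_layer(dem, [b], zones, snap_threshold=300.0)
        np.testing.assert_allclose(both.values, va.values + vb.values, atol=1e-12)


class TestWindIndex:
    def test_directly_downwind_unit_case(self):
        grid = Grid(8, 8, 100.0, 0.0, 800.0)
        # receptor at cell center (x=50, y=750); source 1 km due north of it:
        # bearing toward source = 0 = blowing-from direction (directly downwind)
        src = SourcePoint("s", 50.0, 1750.0, 1.0)
        wf = wind_field(grid, 0.0)
        out = wind_index(grid, [src], wf, const_raster(grid, 1.0))
        assert out.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_crosswind_excluded_by_strict_threshold(self):
        grid = Grid(8, 8, 100.0, 0.0, 800.0)
        src = SourcePoint("s", 1050.0, 750.0, 1.0)  # due east of cell (0,0)
        wf = wind_field(grid, 0.0)  # blowing from north: |theta-beta|=90 -> f=0.5
        out = wind_index(grid, [src], wf, const_raster(grid, 1.0))
        assert out.values[0, 0] == 0.0

    def test_two_identical_terms_sqrt_additivity(self):
        grid = Grid(8, 8, 100.0, 0.0, 800.0)
        a = SourcePoint("a", 50.0, 1750.0, 1.0)
        b = SourcePoint("b", 50.0, 1750.0, 1.0)
        wf = wind_field(grid, 0.0)
        sv = const_raster(grid, 1.0)
        single = wind_index(grid, [a], wf, sv).values[0, 0]
        double = wind_index(grid, [a, b], wf, sv).values[0, 0]
        assert double == pytest.approx(np.sqrt(2) * single)

    def test_matches_bruteforce_double_loop(self):
        grid = Grid(50, 50, 200.0, 0.0, 10_000.0)
        rng = np.random.default_rng(8)
        sources = [
            SourcePoint(str(i), rng.uniform(0, 10_000), rng.uniform(0, 10_000), rng.uniform(1e3, 1e5))
            for i in range(5)
        ]
        dirs = Raster(grid, rng.uniform(0, 360, grid.shape))
        spd = Raster(grid, rng.uniform(0.1, 1.0, grid.shape))
        wf = WindField(direction=dirs, speed=Raster(grid, np.ones(grid.shape)))
        out = wind_index(grid, sources, wf, spd)
        xx, yy = grid.cell_centers()
        floor_km = grid.cell_size / 2000.0
        expect = np.zeros(grid.shape)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                total = 0.0
                for s in sources:
                    theta = np.degrees(np.arctan2(s.x - xx[r, c], s.y - yy[r, c])) % 360
                    f = (1 - np.cos(np.radians(180 + theta - dirs.values[r, c]))) / 2
                    d = max(np.hypot(xx[r, c] - s.x, yy[r, c] - s.y) / 1000.0, floor_km)
                    if f > 0.5:
                        total += f / d * spd.values[r, c]
                expect[r, c] = np.sqrt(total)
        np.testing.assert_allclose(out.values, expect, atol=1e-9)

    def test_additive_over_source_subsets_after_squaring(self):
        grid = Grid(16, 16, 200.0, 0.0, 3200.0)
        rng = np.random.default_rng(9)
        srcs = [
            SourcePoint(str(i), rng.uniform(0, 3200), rng.uniform(0, 3200), 1e4)
            for i in range(4)
        ]
        wf = wind_field(grid, 225.0)
        sv = const_raster(grid, 0.7)
        all_sq = wind_index(grid, srcs, wf, sv).values ** 2
        parts = sum(wind_index(grid, [s], wf, sv).values ** 2 for s in srcs)
        np.testing.assert_allclose(all_sq, parts, atol=1e-12)


class TestTopographicExposure:
    def _terrain(self, grid, slope_deg, aspect_deg):
        from aumex.criteria import TerrainDerivatives

        return TerrainDerivatives(
            slope=const_raster(grid, slope_deg),
            aspect=const_raster(grid, aspect_deg),
        )

    def test_flat_terrain_is_zero(self, grid):
        t = self._terrain(grid, 0.0, 0.0)
        out = topographic_exposure(t, wind_field(grid, 225.0), const_raster(grid, 1.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_vertical_face_into_wind_is_one(self, grid):
        t = self._terrain(grid, 90.0, 225.0)
        out = topographic_exposure(t, wind_field(grid, 225.0), const_raster(grid, 1.0))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_hand_value(self, grid):
        # sin(30) * cos(60) = 0.25
        t = self._terrain(grid, 30.0, 100.0)
        out = topographic_exposure(t, wind_field(grid, 160.0), const_raster(grid, 1.0))
        np.testing.assert_allclose(out.values, 0.25, atol=1e-12)

    def test_flat_terrain_reduces_to_sin_beta_w(self, grid):
        t = self._terrain(grid, 0.0, 0.0)
        for bw in (0.0, 15.0, 45.0, 90.0):
            out = topographic_exposure(
                t, wind_field(grid, 10.0), const_raster(grid, 1.0), beta_w=bw
            )
            np.testing.assert_allclose(out.values, np.sin(np.radians(bw)), atol=1e-12)

    def test_range_bounded(self):
        grid = Grid(32, 32, 100.0, 0.0, 3200.0)
        rng = np.random.default_rng(10)
        from aumex.criteria import TerrainDerivatives

        t = TerrainDerivatives(
            slope=Raster(grid, rng.uniform(0, 90, grid.shape)),
            aspect=Raster(grid, rng.uniform(0, 360, grid.shape)),
        )
        wf = WindField(
            direction=Raster(grid, rng.uniform(0, 360, grid.shape)),
            speed=Raster(grid, np.ones(grid.shape)),
        )
        out = topographic_exposure(t, wf, const_raster(grid, 1.0))
        assert np.all(out.values >= -1 - 1e-12) and np.all(out.values <= 1 + 1e-12)


class TestTpiAndLandforms:
    def test_constant_dem_tpi_zero_and_all_flat(self, grid, flat_dem):
        t = tpi(flat_dem, radius=300.0)
        np.testing.assert_allclose(t.values, 0.0, atol=1e-12)
        terrain = slope_aspect(flat_dem)
        cls = landform_classify(t, terrain.slope)
        assert np.all(cls.values == 3)

    def test_inclined_plane_interior_tpi_zero(self, inclined_dem):
        t = tpi(inclined_dem, radius=300.0)
        interior = t.values[4:-4, 4:-4]
        np.testing.assert_allclose(interior, 0.0, atol=1e-9)

    def test_isolated_peak_positive(self, grid):
        vals = np.zeros(grid.shape)
        vals[8, 8] = 10.0
        t = tpi(Raster(grid, vals), radius=300.0)
        assert t.values[8, 8] > 0

    def test_extreme_tpi_is_ridge_class(self, grid):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, grid.shape)
        vals[5, 5] = 50.0  # guaranteed >= one sd above
        t = Raster(grid, vals)
        cls = landform_classify(t, const_raster(grid, 10.0))
        s = np.std(vals)
        assert vals[5, 5] >= s and cls.values[5, 5] == 6

    def test_classification_matches_bruteforce(self):
        grid = Grid(32, 32, 100.0, 0.0, 3200.0)
        rng = np.random.default_rng(12)
        t = Raster(grid, rng.normal(0, 2, grid.shape))
        slope = Raster(grid, rng.uniform(0, 20, grid.shape))
        got = landform_classify(t, slope).values
        s = np.std(t.values)
        for r in range(32):
            for c in range(32):
                v, sl = t.values[r, c], slope.values[r, c]
                if v <= -s:
                    expect = 1
                elif v <= -0.5 * s:
                    expect = 2
                elif abs(v) < 0.5 * s:
                    expect = 3 if sl <= 5 else 4
                elif v < s:
                    expect = 5
                else:
                    expect = 6
                assert got[r, c] == expect, (r, c)


class TestSlopeAspect:
    def test_inclined_plane_aspect_east(self, inclined_dem):
        terrain = slope_aspect(inclined_dem)
        interior = terrain.aspect.values[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 90.0, atol=1e-9)
        expected_slope = np.degrees(np.arctan(0.01))
        np.testing.assert_allclose(terrain.slope.values[1:-1, 1:-1], expected_slope, atol=1e-9)

    def test_flat_aspect_undefined(self, flat_dem):
        terrain = slope_aspect(flat_dem)
        assert np.all(np.isnan(terrain.aspect.values))
        assert np.all(terrain.slope.values == 0.0)


class TestRoadProximity:
    def test_cell_on_road_is_zero(self, grid):
        road = LineString([(0.0, 750.0), (1600.0, 750.0)])
        out = road_proximity(grid, [road])
        r, c = grid.index_of(850.0, 750.0)
        assert out.values[r, c] == 0.0

    def test_horizontal_road_vertical_offset(self, grid):
        road = LineString([(0.0, 750.0), (1600.0, 750.0)])
        out = road_proximity(grid, [road])
        r, c = grid.index_of(850.0, 1250.0)
        assert out.values[r, c] == pytest.approx(500.0)

    def test_matches_bruteforce_segment_distance(self):
        grid = Grid(64, 64, 50.0, 0.0, 3200.0)
        rng = np.random.default_rng(13)
        roads = [
            LineString(rng.uniform(0, 3200, size=(4, 2))) for _ in range(3)
        ]
        out = road_proximity(grid, roads)

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        centers = grid.cell_center_points()
        idx = np.random.default_rng(1).choice(len(centers), 200, replace=False)
        for k in idx:
            p = centers[k]
            expect = min(
                seg_dist(p, np.array(r.coords[i]), np.array(r.coords[i + 1]))
                for r in roads
                for i in range(len(r.coords) - 1)
            )
            assert out.values.ravel()[k] == pytest.approx(expect, abs=1e-9)


class TestIdwHazard:
    def test_exact_at_well(self, grid):
        out = idw_hazard(grid, np.array([[50.0, 1550.0]]), np.array([7.5]))
        assert out.values[0, 0] == 7.5

    def test_two_equidistant_wells_average(self, grid):
        # cell center (750, 750) sits exactly midway between the wells
        wells = np.array([[0.0, 750.0], [1500.0, 750.0]])
        out = idw_hazard(grid, wells, np.array([1.0, 3.0]))
        r, c = grid.index_of(750.0, 750.0)
        assert out.values[r, c] == pytest.approx(2.0)

    def test_hand_weighting(self):
        grid = Grid(8, 8, 1.0, 0.0, 8.0)
        # cell center (0.5, 7.5); wells at distances 1 and 2
        wells = np.array([[1.5, 7.5], [2.5, 7.5]])
        out = idw_hazard(grid, wells, np.array([0.0, 3.0]), power=2.0)
        assert out.values[0, 0] == pytest.approx(0.6)


def test_distance_layers_translation_invariant():
    g1 = Grid(16, 16, 100.0, 0.0, 1600.0)
    g2 = Grid(16, 16, 100.0, 5000.0, 9000.0)
    dx, dy = 5000.0, 7400.0
    src1 = SourcePoint("a", 400.0, 900.0, 1e4)
    src2 = SourcePoint("a", 400.0 + dx, 900.0 + dy, 1e4)
    np.testing.assert_allclose(
        aum_proximity(g1, [src1]).values, aum_proximity(g2, [src2]).values
    )
    wells1 = np.array([[300.0, 1000.0], [900.0, 400.0]])
    np.testing.assert_allclose(
        idw_hazard(g1, wells1, np.array([1.0, 2.0])).values,
        idw_hazard(g2, wells1 + [dx, dy], np.array([1.0, 2.0])).values,
    )
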