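import numpy as np
import pytest
from scipy import stats

from aumex.fuzzy import WeightVector
from aumex.raster import Grid, Raster
from aumex.synthetic_world import (
    emulate_met_sources,
    generate_ancillary,
    generate_mines,
    generate_terrain,
    generate_validation_samples,
    generate_wind_truth,
)

GRID = Grid(64, 64, 500.0, 0.0, 32_000.0)


class TestTerrain:
    def test_seeded_determinism(self):
        a = generate_terrain(GRID, 1.3, 100.0, seed=5)
        b = generate_terrain(GRID, 1.3, 100.0, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rescaled_to_relief(self):
        dem = generate_terrain(GRID, 1.0, 100.0, seed=1)
        assert dem.values.min() == pytest.approx(0.0, abs=1e-9)
        assert dem.values.max() == pytest.approx(100.0, abs=1e-9)

    def test_spectral_slope_steeper_for_rougher_parameter(self):
        def log_periodogram_slope(dem):
            f = np.fft.fft2(dem.values - dem.values.mean())
            power = np.abs(f) ** 2
            ky = np.fft.fftfreq(GRID.n_rows)[:, None]
            kx = np.fft.fftfreq(GRID.n_cols)[None, :]
            k = np.hypot(kx, ky).ravel()
            p = power.ravel()
            keep = (k > 0.02) & (k < 0.4)
            slope, *_ = stats.linregress(np.log(k[keep]), np.log(p[keep]))
            return slope

        smooth = generate_terrain(GRID, 1.8, 100.0, seed=2)
        rough = generate_terrain(GRID, 0.2, 100.0, seed=2)
        assert log_periodogram_slope(smooth) < log_periodogram_slope(rough)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_terrain(GRID, 1.0, -5.0, seed=0)
        with pytest.raises(ValueError):
            generate_terrain(GRID, 2.5, 100.0, seed=0)


class TestMines:
    def test_single_mine(self):
        mines = generate_mines(GRID, 1, 1, 1000.0, (1e3, 1e4), seed=0)
        assert len(mines) == 1

    def test_areas_within_range(self):
        mines = generate_mines(GRID, 4, 10, 2000.0, (2e3, 2e5), seed=1)
        areas = np.array([m.area for m in mines])
        assert np.all((areas >= 2e3) & (areas <= 2e5))

    def test_clustering_reduces_nearest_neighbor_distance(self):
        def mean_nn(pts):
            d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).mean()

        clustered_wins = 0
        for seed in range(20):
            clustered = generate_mines(GRID, 4, 10, 1500.0, (1e3, 1e4), seed=seed)
            cpts = np.array([[m.x, m.y] for m in clustered])
            rng = np.random.default_rng(seed)
            xmin, ymin, xmax, ymax = GRID.extent
            upts = np.column_stack(
                [rng.uniform(xmin, xmax, len(cpts)), rng.uniform(ymin, ymax, len(cpts))]
            )
            clustered_wins += mean_nn(cpts) < mean_nn(upts)
        assert clustered_wins >= 18

    def test_inverted_area_range_rejected(self):
        with pytest.raises(ValueError):
            generate_mines(GRID, 1, 1, 100.0, (1e4, 1e3), seed=0)


class TestWindTruth:
    def test_zero_sd_gives_constant_direction(self):
        d, s = generate_wind_truth(GRID, 225.0, 0.0, 4.0, 0.0, 10_000.0, seed=0)
        assert np.all(d.values == 225.0)
        assert np.all(s.values == 4.0)

    def test_circular_mean_near_prevailing(self):
        big = Grid(128, 128, 500.0, 0.0, 64_000.0)
        d, _ = generate_wind_truth(big, 225.0, 20.0, 4.0, 1.0, 10_000.0, seed=3)
        rad = np.radians(d.values)
        mean_dir = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360
        assert abs(mean_dir - 225.0) < 5.0

    def test_speeds_nonnegative(self):
        _, s = generate_wind_truth(GRID, 90.0, 30.0, 0.5, 2.0, 5_000.0, seed=1)
        assert np.all(s.values >= 0.0)

    def test_directions_wrapped(self):
        d, _ = generate_wind_truth(GRID, 350.0, 40.0, 4.0, 1.0, 5_000.0, seed=2)
        assert np.all((d.values >= 0) & (d.values < 360))


class TestEmulateMetSources:
    def setup_method(self):
        self.truth = generate_wind_truth(GRID, 225.0, 20.0, 4.0, 1.0, 10_000.0, seed=7)

    def test_direct_samples_truth_exactly(self):
        direct, _ = emulate_met_sources(self.truth, 10, 8_000.0, 5_000.0, 15.0, seed=1)
        d_raster, s_raster = self.truth
        for p in direct.points:
            assert p.direction_deg == d_raster.sample(np.array([p.x]), np.array([p.y]))[0]
            assert p.speed == s_raster.sample(np.array([p.x]), np.array([p.y]))[0]

    def test_degenerate_degradation_equals_truth_on_lattice(self):
        _, gridded = emulate_met_sources(self.truth, 5, 8_000.0, 0.0, 0.0, seed=2)
        d_raster, _ = self.truth
        for p in gridded.points:
            assert p.direction_deg == pytest.approx(
                d_raster.sample(np.array([p.x]), np.array([p.y]))[0]
            )

    def test_gridded_angular_error_exceeds_direct_under_bias(self):
        def mae(points, raster):
            errs = []
            for p in points:
                truth = raster.sample(np.array([p.x]), np.array([p.y]))[0]
                errs.append(abs((p.direction_deg - truth + 180) % 360 - 180))
            return np.mean(errs)

        worse = 0
        for seed in range(10):
            truth = generate_wind_truth(GRID, 225.0, 20.0, 4.0, 1.0, 10_000.0, seed=seed)
            direct, gridded = emulate_met_sources(truth, 10, 8_000.0, 5_000.0, 15.0, seed=seed)
            worse += mae(gridded.points, truth[0]) > mae(direct.points, truth[0])
        assert worse == 10  # direct error is exactly zero at its stations

    def test_spacing_validation(self):
        with pytest.raises(ValueError):
            emulate_met_sources(self.truth, 5, 100.0, 0.0, 0.0, seed=0)  # < cell
        with pytest.raises(ValueError):
            emulate_met_sources(self.truth, 5, 1e6, 0.0, 0.0, seed=0)  # > extent


class TestAncillary:
    def test_contracts(self):
        wells, roads, ndvi = generate_ancillary(GRID, n_wells=40, n_roads=3, seed=0)
        assert len(wells) == 40
        assert np.all(wells["hazard_index"] > 0)
        assert len(roads) == 3
        assert np.all((ndvi.values >= -1) & (ndvi.values <= 1))

    def test_hazard_right_skewed(self):
        wells, _, _ = generate_ancillary(GRID, n_wells=400, n_roads=1, seed=1)
        assert stats.skew(wells["hazard_index"]) > 0


class TestValidationSamples:
    def _stack(self):
        rng = np.random.default_rng(0)
        smooth = [
            Raster(GRID, np.clip(rng.random(GRID.shape), 0, 1)) for _ in range(2)
        ]
        return smooth

    def test_noise_free_rank_correlation_is_one(self):
        stack = self._stack()
        w = WeightVector([0.6, 0.4])
        samples = generate_validation_samples(stack, w, 200, 0.0, seed=4)
        xs = np.array([s.x for s in samples])
        ys = np.array([s.y for s in samples])
        e = 0.6 * stack[0].sample(xs, ys) + 0.4 * stack[1].sample(xs, ys)
        conc = np.array([s.concentration for s in samples])
        rho = stats.spearmanr(conc, e).statistic
        assert rho == pytest.approx(1.0)

    def test_concentrations_right_skewed(self):
        stack = self._stack()
        samples = generate_validation_samples(
            stack, WeightVector([0.5, 0.5]), 2000, 0.5, seed=5, slope=3.0
        )
        conc = np.array([s.concentration for s in samples])
        assert stats.skew(conc) > 0

    def test_sample_count_and_validation(self):
        stack = self._stack()
        assert len(generate_validation_samples(stack, WeightVector([0.5, 0.5]), 50, 0.1, 0)) == 50
        with pytest.raises(ValueError):
            generate_validation_samples(stack, WeightVector([0.5, 0.5]), 50, -0.1, 0)
        with pytest.raises(ValueError):
            generate_validation_samples(stack, WeightVector([0.5, 0.5]), 5, 0.1, 0)


def test_generators_are_pure_functions_of_seed():
    a = generate_mines(GRID, 3, 5, 1000.0, (1e3, 1e4), seed=9)
    b = generate_mines(GRID, 3, 5, 1000.0, (1e3, 1e4), seed=9)
    assert [(m.x, m.y, m.area) for m in a] == [(m.x, m.y, m.area) for m in b]
    w1, r1, n1 = generate_ancillary(GRID, 10, 2, seed=9)
    w2, r2, n2 = generate_ancillary(GRID, 10, 2, seed=9)
    assert w1.equals(w2)
    np.testing.assert_array_equal(n1.values, n2.values)
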