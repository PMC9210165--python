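"""Synthetic stand generator: point processes, marks, substrate, relief."""

import math

import numpy as np
import pytest
from scipy import integrate

import shapely
from karststand.config import ConfigError, StandConfig, yachang_like
from karststand.species import census_abundances
from karststand.structure import sssp_table
from karststand.synthetic import (
    SimulationError,
    assign_species_and_sizes,
    generate_elevation_field,
    generate_point_pattern,
    generate_scenario,
    generate_substrate,
    largest_remainder_counts,
)
from karststand.terrain import (
    build_quadrat_grid,
    compute_terrain,
    set_elevations,
)

from conftest import make_stems


def _cfg(**kw):
    base = dict(
        plot_width=200.0,
        plot_height=110.0,
        n_stems=500,
        pattern="poisson",
        species_abundances=[1.0],
        seed=7,
    )
    base.update(kw)
    return StandConfig(**base)


class TestPointPatterns:
    def test_too_few_stems_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(n_stems=1)

    def test_points_inside_window_exact_count(self):
        for pattern, params in [
            ("poisson", {}),
            ("thomas_cluster", {"parent_intensity": 0.003, "cluster_sd": 8.0}),
            ("hardcore", {"radius": 1.5}),
        ]:
            pts = generate_point_pattern(_cfg(pattern=pattern, pattern_params=params))
            assert pts.shape == (500, 2)
            assert pts[:, 0].min() >= 0 and pts[:, 0].max() <= 200
            assert pts[:, 1].min() >= 0 and pts[:, 1].max() <= 110

    def test_seeded_determinism(self):
        a = generate_point_pattern(_cfg(n_stems=2000, seed=42))
        b = generate_point_pattern(_cfg(n_stems=2000, seed=42))
        np.testing.assert_array_equal(a, b)

    def test_hardcore_minimum_distance_brute_force(self):
        """Every pairwise distance respects the inhibition radius (O(n^2) check)."""
        pts = generate_point_pattern(
            _cfg(pattern="hardcore", pattern_params={"radius": 5.0}, n_stems=500)
        )
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert math.sqrt(d2.min()) >= 5.0

    def test_infeasible_hardcore_errors_with_context(self):
        cfg = _cfg(
            plot_width=20.0,
            plot_height=20.0,
            n_stems=500,
            pattern="hardcore",
            pattern_params={"radius": 5.0},
        )
        with pytest.raises(SimulationError, match="radius 5.0"):
            generate_point_pattern(cfg)

    def test_pattern_discrimination_by_uniform_angle_index(self):
        """Replicate-mean W orders hardcore < Poisson < Thomas cluster."""
        means = {}
        for pattern, params in [
            ("hardcore", {"radius": 1.2}),
            ("poisson", {}),
            ("thomas_cluster", {"parent_intensity": 0.0025, "cluster_sd": 6.0}),
        ]:
            reps = []
            for s in range(20):
                pts = generate_point_pattern(
                    _cfg(pattern=pattern, pattern_params=params, n_stems=2000, seed=100 + s)
                )
                tab = sssp_table(make_stems(pts), plot_width=200, plot_height=110)
                reps.append(tab.loc[~tab["edge_flag"], "W"].mean())
            means[pattern] = np.mean(reps)
        assert means["hardcore"] < means["poisson"] < means["thomas_cluster"]


class TestMarks:
    def test_single_species_everywhere(self):
        pts = generate_point_pattern(_cfg())
        stems = assign_species_and_sizes(pts, _cfg(species_abundances=[1.0]))
        assert (stems["species"] == "S01").all()

    def test_census_preset_exact_counts(self):
        """Exact apportionment of the census abundances recovers the printed
        count of the most abundant species."""
        cfg = yachang_like(seed=5, pattern="poisson")
        pts = generate_point_pattern(cfg)
        stems = assign_species_and_sizes(pts, cfg)
        counts = stems["species"].value_counts()
        assert counts["PS"] == 1369
        assert counts.sum() == 4596
        assert stems["species"].nunique() == 62

    def test_largest_remainder_is_exact_and_sums(self):
        _, census_counts = census_abundances()
        p = census_counts / census_counts.sum()
        counts = largest_remainder_counts(4596, p)
        np.testing.assert_array_equal(counts, census_counts)

    def test_truncated_weibull_mean_matches_integration_oracle(self):
        """Sample mean of Weibull(2, 10) truncated at 1 cm agrees with the
        numerically integrated truncated mean, and with the untruncated
        analytic moment 10*Gamma(1.5) to within 2%."""
        cfg = _cfg(n_stems=100_000, dbh_weibull=(2.0, 10.0), seed=3)
        pts = generate_point_pattern(cfg)
        stems = assign_species_and_sizes(pts, cfg)
        pdf = lambda x: (2 / 10) * (x / 10) ** 1 * np.exp(-((x / 10) ** 2))
        num, _ = integrate.quad(lambda x: x * pdf(x), 1.0, np.inf)
        den, _ = integrate.quad(pdf, 1.0, np.inf)
        oracle = num / den
        sample_mean = stems["dbh_cm"].mean()
        assert abs(sample_mean - oracle) / oracle < 0.01
        analytic = 10 * math.gamma(1.5)
        assert abs(sample_mean - analytic) / analytic < 0.02
        assert stems["dbh_cm"].min() >= 1.0

    def test_height_allometry_noise_free(self):
        cfg = _cfg(height_allometry=(1.5, 0.6))
        pts = generate_point_pattern(cfg)
        stems = assign_species_and_sizes(pts, cfg)
        expected = 1.3 + 1.5 * stems["dbh_cm"] ** 0.6
        np.testing.assert_allclose(stems["th_m"], expected)
        assert (stems["th_m"] > 1.3).all()

    def test_species_recovery_at_large_n(self):
        p = np.array([0.4, 0.3, 0.2, 0.07, 0.03])
        cfg = _cfg(n_stems=100_000, species_abundances=list(p), seed=9)
        pts = generate_point_pattern(cfg)
        stems = assign_species_and_sizes(pts, cfg)
        phat = stems["species"].value_counts(normalize=True)
        phat = phat.reindex([f"S{i + 1:02d}" for i in range(5)]).fillna(0.0).to_numpy()
        assert np.max(np.abs(phat - p)) < 0.02


class TestSubstrate:
    def test_zero_target_is_empty(self):
        sub = generate_substrate(_cfg(rock_target_fraction=0.0))
        assert len(sub) == 0 and sub.total_rock_area == 0.0

    def test_target_fraction_reached_raster_oracle(self):
        """Achieved rock fraction within +-0.03 of the 0.283 target,
        measured independently by 0.1 m rasterization."""
        sub = generate_substrate(_cfg(rock_target_fraction=0.283))
        xs = np.arange(0.05, 200.0, 0.1)
        ys = np.arange(0.05, 110.0, 0.1)
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(sub.union, gx.ravel(), gy.ravel())
        raster_frac = inside.mean()
        assert 0.253 <= raster_frac <= 0.313
        assert abs(raster_frac - sub.rock_fraction) < 0.005

    def test_substrate_determinism(self):
        a = generate_substrate(_cfg(seed=4))
        b = generate_substrate(_cfg(seed=4))
        assert a.union.equals_exact(b.union, tolerance=0.0)

    def test_target_too_high_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(rock_target_fraction=0.96)


class TestElevation:
    def _terrain(self, cfg):
        grid = build_quadrat_grid(cfg.plot_width, cfg.plot_height, 10.0)
        elev = generate_elevation_field(cfg, grid)
        set_elevations(grid, elev)
        compute_terrain(grid)
        return grid

    def test_flat_field_is_constant(self):
        cfg = _cfg(elevation_trend=(1293.0, 0.0, 200.0), elevation_noise_sd=0.0)
        grid = self._terrain(cfg)
        for q in grid:
            assert q.elevation == pytest.approx(1293.0)
            assert q.convexity == pytest.approx(0.0)
            assert q.slope == pytest.approx(0.0)
            assert math.isnan(q.aspect)

    def test_planar_field_recovers_dip_and_azimuth(self):
        """Noiseless 25-degree plane dipping at 200 degrees: every quadrat
        reports that slope, that aspect, and zero convexity."""
        cfg = _cfg(elevation_trend=(1293.0, 25.0, 200.0), elevation_noise_sd=0.0)
        grid = self._terrain(cfg)
        for q in grid:
            assert q.slope == pytest.approx(25.0, abs=1e-6)
            assert q.aspect == pytest.approx(200.0, abs=1e-6)
            assert q.convexity == pytest.approx(0.0, abs=1e-9)


class TestScenario:
    def test_scenario_invariants(self, small_scenario, small_config):
        stems = small_scenario.stems
        assert len(stems) == small_config.n_stems
        assert stems[["x", "y"]].duplicated().sum() == 0
        assert stems["x"].between(0, small_config.plot_width).all()
        assert stems["y"].between(0, small_config.plot_height).all()

    def test_scenario_determinism(self, small_config, small_scenario):
        again = generate_scenario(small_config)
        assert again.stems.equals(small_scenario.stems)
        assert again.elevations.equals(small_scenario.elevations)
        assert again.substrate.union.equals_exact(
            small_scenario.substrate.union, tolerance=0.0
        )

    def test_rock_affinity_biases_occupancy(self):
        cfg = _cfg(n_stems=2000, rock_target_fraction=0.3, rock_affinity=4.0, seed=21)
        sc = generate_scenario(cfg)
        on_rock = shapely.contains_xy(
            sc.substrate.union, sc.stems["x"].to_numpy(), sc.stems["y"].to_numpy()
        )
        assert on_rock.mean() > sc.substrate.rock_fraction + 0.1
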