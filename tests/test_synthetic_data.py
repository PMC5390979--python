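import numpy as np
import pytest

from pfe import (
    build_grid,
    buffer_seaward,
    compute_pfe,
    detect_fishing_events,
    events_per_cell,
    fit_catch_model,
    fit_power_law,
)
from pfe.kde import KdeConfig, aggregate_mean, density_surface
from pfe.synthetic_data import (
    SyntheticScenario,
    generate_catch,
    generate_region,
    generate_tracks,
)

from .conftest import make_cells


class TestGenerateRegion:
    def test_reproducible_under_seed(self):
        a = generate_region(SyntheticScenario(seed=42))
        b = generate_region(SyntheticScenario(seed=42))
        np.testing.assert_array_equal(a[1].xy, b[1].xy)
        np.testing.assert_array_equal(a[2].values, b[2].values)
        assert a[0].geometry.equals(b[0].geometry)

    def test_noise_free_boats_follow_power_law(self):
        sc = SyntheticScenario(seed=1, sigma_b=0.0)
        _, communities, boats = generate_region(sc)
        expected = np.round(communities.values**sc.m_true)
        np.testing.assert_array_equal(boats.values, expected)

    def test_communities_within_coastal_strip(self):
        coast, communities, _ = generate_region(SyntheticScenario(seed=2))
        import shapely

        d = shapely.distance(coast.geometry, shapely.points(communities.xy))
        assert (d <= 5000.0).all()

    def test_too_few_communities_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(n_communities=1)

    def test_exponent_recovery_across_replicates(self):
        # fitted m within 3 se of the generating exponent in >= 95% of
        # replicates (n = 500 communities, sigma_b = 0.3); the fit uses
        # offset = 0 because the +1 zero-handling offset adds a small
        # systematic bias at communities with few boats
        hits, n_rep = 0, 200
        for rep in range(n_rep):
            sc = SyntheticScenario(
                seed=9000 + rep, n_communities=500, m_true=0.5, sigma_b=0.3
            )
            _, communities, boats = generate_region(sc)
            fit = fit_power_law(
                make_cells(dict(enumerate(boats.values))),
                make_cells(dict(enumerate(communities.values))),
                offset=0.0,
            )
            if abs(fit.m - sc.m_true) <= 3 * fit.se_m:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestGenerateCatch:
    def test_noise_free_value_at_half_b(self):
        pfe = make_cells({0: 23.5})
        catch = generate_catch(pfe, K_true=2204.0, b_true=47.0, sigma_c=0.0, seed=0)
        assert catch.values.loc[0] == pytest.approx(2204.0 * np.exp(-2.0))

    def test_zero_pfe_zero_catch(self):
        catch = generate_catch(
            make_cells({0: 0.0, 1: 10.0}), 1000.0, 20.0, 0.3, seed=1
        )
        assert catch.values.loc[0] == 0.0
        assert catch.values.loc[1] > 0.0

    def test_log_variance_matches_sigma(self):
        # equal pfe everywhere: var(log catch) ~ sigma_c^2
        n, sigma = 10_000, 0.3
        pfe = make_cells(dict(enumerate(np.full(n, 30.0))))
        catch = generate_catch(pfe, 1000.0, 20.0, sigma, seed=3)
        assert np.var(np.log(catch.values)) == pytest.approx(sigma**2, rel=0.05)


class TestGenerateTracks:
    @pytest.fixture(scope="class")
    def scenario_grid(self):
        sc = SyntheticScenario(seed=5)
        coast, _, _ = generate_region(sc)
        grid = build_grid(buffer_seaward(coast, 75.0), 500.0)
        return sc, grid

    def test_detector_recovers_ground_truth_exactly(self, scenario_grid):
        sc, grid = scenario_grid
        tracks, truth = generate_tracks(sc, grid)
        detected = []
        for tr in tracks:
            detected.extend(
                detect_fishing_events(tr, speed_max=1.0, min_points=sc.points_per_event)
            )
        assert len(detected) == len(truth) == sc.n_vessels * sc.events_per_vessel
        for ev, t in zip(detected, truth):
            assert ev.location == pytest.approx(t["location"])

    def test_per_cell_counts_match_truth(self, scenario_grid):
        sc, grid = scenario_grid
        tracks, truth = generate_tracks(sc, grid)
        detected = []
        for tr in tracks:
            detected.extend(detect_fishing_events(tr, 1.0, sc.points_per_event))
        counts, dropped = events_per_cell(detected, grid)
        true_counts: dict = {}
        true_dropped = 0
        for t in truth:
            if t["cell_id"] is None:
                true_dropped += 1
            else:
                true_counts[t["cell_id"]] = true_counts.get(t["cell_id"], 0) + 1
        assert dropped == true_dropped
        assert counts.values.to_dict() == pytest.approx(true_counts)

    def test_slow_cruise_merges_into_one_event(self, scenario_grid):
        sc, grid = scenario_grid
        tracks, _ = generate_tracks(sc, grid)
        # threshold above cruise speed: whole track is one merged run
        events = detect_fishing_events(tracks[0], speed_max=sc.cruise_speed + 1.0, min_points=3)
        assert len(events) == 1
        assert events[0].start == 0
        assert events[0].end == len(tracks[0].times) - 1


class TestFullPipelineRecovery:
    def test_catch_parameters_recovered_through_whole_pipeline(self):
        # region -> KDE -> allometry -> PFE -> catch -> fit: the catch
        # parameters survive the full chain with < 10% relative bias at
        # multiplicative noise sigma_c = 0.3 (~500 cells per replicate)
        biases_K, biases_b = [], []
        for rep in range(3):
            sc = SyntheticScenario(seed=7000 + rep)
            coast, communities, boats = generate_region(sc)
            aoi = buffer_seaward(coast, 75.0)
            grid = build_grid(aoi, 500.0)
            cfg = KdeConfig()
            extent = aoi.polygon.bounds
            pop_cells = aggregate_mean(
                density_surface(communities, cfg, extent), grid, cell_totals=True
            )
            boat_cells = aggregate_mean(
                density_surface(boats, cfg, extent), grid, cell_totals=True
            )
            fit_m = fit_power_law(boat_cells, pop_cells)
            surface = compute_pfe(boat_cells, pop_cells, fit_m.m)
            catch = generate_catch(
                surface.cells, sc.K_true, sc.b_true, sc.sigma_c, seed=8000 + rep
            )
            fit = fit_catch_model(
                surface.cells, catch, n_draws=50, draw_size=250, seed=rep
            )
            biases_K.append(abs(fit.K - sc.K_true) / sc.K_true)
            biases_b.append(abs(fit.b - sc.b_true) / sc.b_true)
        assert np.mean(biases_K) < 0.10
        assert np.mean(biases_b) < 0.10
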