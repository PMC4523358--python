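import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, poisson

import seedpassage as sp
from seedpassage.design import SpeciesProfile, StudyDesign, default_design
from seedpassage.model import excretion_probability
from seedpassage.simulate import (
    draw_initial_seed_load,
    reference_parameter_presets,
    replay,
    simulate_counts,
    simulate_dataset,
    simulate_feces_and_samples,
    simulate_gut_dynamics,
)


class TestInitialSeedLoad:
    def test_zero_mean_gives_zero(self, rng):
        assert draw_initial_seed_load(0, rng) == 0
        with pytest.raises(ValueError):
            draw_initial_seed_load(-1, rng)

    def test_large_mixture_mean(self, rng):
        draws = np.array([draw_initial_seed_load(11_000, rng) for _ in range(1000)])
        se = math.sqrt(11_000 / 1000)
        assert abs(draws.mean() - 11_000) < 3 * se

    def test_pmf_matches_poisson_by_chi_square(self, rng):
        draws = rng.poisson(4, 100_000)
        draws = np.array([draw_initial_seed_load(4, rng) for _ in range(100_000)])
        kmax = 12
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        exp = poisson.pmf(np.arange(kmax), 4) * draws.size
        exp = np.append(exp, draws.size - exp.sum())
        stat, p = chisquare(obs, exp)
        assert p > 0.01


class TestGutDynamics:
    def test_no_excretion_cases(self, collection_grid, rng):
        times = np.asarray(collection_grid.times)
        deltas = np.asarray(collection_grid.deltas)
        # pex ~ 0 everywhere
        traj = simulate_gut_dynamics(500, times, deltas, np.ones(13, int),
                                     (-60, 0, 0), 0.0, rng)
        assert traj.nf.sum() == 0
        # never defecates
        traj = simulate_gut_dynamics(500, times, deltas, np.zeros(13, int),
                                     (0.0, 0, 0), 0.0, rng)
        assert traj.nf.sum() == 0

    def test_thinning_expectation(self, rng):
        """Constant per-interval excretion probability 0.1 over 5 steps:
        E[final load] = N0 * 0.9^5."""
        from scipy.special import logit

        times = np.arange(1.0, 6.0)
        deltas = np.ones(5)
        abc = (float(logit(0.1)), 0.0, 0.0)
        finals = []
        for _ in range(500):
            traj = simulate_gut_dynamics(1000, times, deltas, np.ones(5, int),
                                         abc, 0.0, rng, nt0=1000)
            finals.append(traj.nt[-1])
        expected = 1000 * 0.9**5
        sd = math.sqrt(sum(1000 * (1 - 0.1) ** k * 0.1 * (1 - 0.1 * (1 - 0.1) ** k)
                           for k in range(5)))  # conservative bound on var
        se = np.std(finals) / math.sqrt(500)
        assert abs(np.mean(finals) - expected) < 3 * max(se, 1e-9)

    def test_exact_conservation_on_random_trajectories(self, collection_grid, rng):
        times = np.asarray(collection_grid.times)
        deltas = np.asarray(collection_grid.deltas)
        for _ in range(200):
            defec = rng.integers(0, 2, 13)
            traj = simulate_gut_dynamics(int(rng.integers(0, 2000)), times, deltas,
                                         defec, (-3, 0.2, -0.005), 0.0, rng)
            assert traj.nt0 == traj.nf.sum() + traj.nt[-1]
            assert np.all(traj.nt >= 0)
            assert np.all(traj.nf[defec == 0] == 0)


class TestFecesAndSamples:
    @pytest.mark.parametrize("name, mean, sd", [("roe_deer", 24.1, 17.7),
                                                ("red_deer", 61.9, 32.9)])
    def test_weight_moments(self, name, mean, sd, rng):
        species = default_design().species_profile(name)
        w = np.array([simulate_feces_and_samples(species, rng)[0] for _ in range(2000)])
        assert abs(w.mean() - mean) < 3 * sd / math.sqrt(2000)
        assert w.min() > 0

    def test_sample_weight_capped_at_half_feces(self, rng):
        tiny = SpeciesProfile("roe_deer", "ruminant", 21.2, 5, 4.0, 6.0, 0.5)
        for _ in range(50):
            w, wd, wg = simulate_feces_and_samples(tiny, rng)
            if w < 8.0:
                assert wd == wg == pytest.approx(w / 2)
                assert wd / w == pytest.approx(0.5)
            else:
                assert wd == 4.0


class TestCounts:
    def test_degenerate_inputs(self, rng):
        times = np.array([3.0, 6.0])
        nfd, y, g = simulate_counts(np.zeros(2, int), np.full(2, 0.4),
                                    np.full(2, 0.3), times, 0.5, (-1, -0.05),
                                    0.0, 0.0, rng)
        assert y.sum() == g.sum() == 0
        # everything dissected leaves nothing to germinate
        nfd, y, g = simulate_counts(np.array([50, 50]), np.ones(2), np.full(2, 0.3),
                                    times, 0.5, (5.0, 0.0), 0.0, 0.0, rng)
        assert np.all(nfd == 50)
        assert g.sum() == 0

    def test_counted_seed_expectation(self, rng):
        ys = []
        times = np.array([3.0])
        for _ in range(1000):
            _, y, _ = simulate_counts(np.array([200]), np.array([0.4]),
                                      np.array([0.3]), times, 0.5, (-30, 0.0),
                                      0.0, 0.0, rng)
            ys.append(y[0])
        se = np.std(ys) / math.sqrt(1000)
        assert abs(np.mean(ys) - 200 * 0.4 * 0.5) < 3 * se

    def test_counts_respect_sample_bounds(self, rng):
        times = np.array([3.0, 6.0, 9.0])
        for _ in range(100):
            nf = rng.integers(0, 30, 3)
            nfd, y, g = simulate_counts(nf, np.full(3, 0.4), np.full(3, 0.3),
                                        times, 0.7, (0.0, -0.05), 0.0, 0.0, rng)
            assert np.all(y <= nfd)
            assert np.all(nfd <= nf)
            assert np.all(g <= nf - nfd)


class TestSimulateDataset:
    def test_deterministic_given_seed(self):
        a = simulate_dataset(seed=9)
        b = simulate_dataset(seed=9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.feces, b.feces)

    def test_replay_reproduces_records_and_truth(self, fixture_sim):
        again = replay(fixture_sim)
        pd.testing.assert_frame_equal(again.feces, fixture_sim.feces)
        for key, traj in fixture_sim.latent.items():
            np.testing.assert_array_equal(traj.nf, again.latent[key].nf)
            np.testing.assert_array_equal(traj.nfd, again.latent[key].nfd)

    def test_default_design_shape(self, fixture_sim):
        assert fixture_sim.trials["species"].nunique() == 3
        per_species = fixture_sim.trials.groupby("species")["animal_id"].nunique()
        assert (per_species == 6).all()
        times_per_cell = fixture_sim.feces.groupby(["animal_id", "plant"])["time_h"].nunique()
        assert (times_per_cell == 13).all()

    def test_latent_truth_consistent_with_records(self, fixture_sim):
        ds = fixture_sim.dataset
        for (animal, plant), traj in fixture_sim.latent.items():
            cell = ds.cell_arrays(animal, plant)
            assert traj.is_valid()
            assert np.all(cell["y"] <= traj.nfd)
            assert np.all(cell["g"] <= traj.rest_nf)
            np.testing.assert_array_equal(cell["defec"], traj.defec)

    def test_partial_ingestion_reduces_totals(self):
        full = simulate_dataset(seed=4, ingestion="full")
        part = simulate_dataset(seed=4, ingestion="partial")
        assert part.trials["ntot"].sum() < full.trials["ntot"].sum()
        merged = part.trials.merge(full.trials, on=["animal_id", "plant"])
        assert (merged.ntot_x <= merged.ntot_y).all()

    def test_daily_defecation_rate_matches_target(self):
        """With the hazard set from the observed 6.3 feces/day, the simulated
        number of defecation-positive 3-h intervals per day recovers it."""
        from seedpassage.design import hazard_for_daily_defecations

        params = reference_parameter_presets()
        params.delta["roe_deer"] = hazard_for_daily_defecations(6.3, 3.0)
        base = default_design()
        design = StudyDesign(species=(base.species_profile("roe_deer"),),
                             traits=base.traits, grid=base.grid, n_replicates=50)
        sim = simulate_dataset(design, params, seed=31)
        first_day = sim.feces[(sim.feces.time_h <= 24) & (sim.feces.plant == "Calluna_vulgaris")]
        per_animal = first_day.groupby("animal_id")["defec"].sum()
        se = per_animal.std(ddof=1) / math.sqrt(len(per_animal))
        assert abs(per_animal.mean() - 6.3) < 3 * se


class TestPresets:
    def test_excretion_curves_peak_at_reported_values(self, presets):
        from seedpassage.simulate import _MAXPEX_MRT

        for (s, j), (max_pex, mrt) in _MAXPEX_MRT.items():
            a, b, c = presets.excretion[(s, j)]
            assert excretion_probability(a, b, c, mrt) == pytest.approx(max_pex)
            assert -b / (2 * c) == pytest.approx(mrt)

    def test_defecation_hazards_match_reported_medians(self, presets):
        for s, p in (("roe_deer", 0.70), ("red_deer", 0.74), ("wild_boar", 0.38)):
            assert 1 - math.exp(-3 * presets.delta[s]) == pytest.approx(p)

    def test_germination_curves_peak_at_first_collection(self, presets, collection_grid):
        from scipy.special import expit

        g0, g1 = presets.germination[("red_deer", "Juncus_effusus")]
        assert g1 < 0
        curve = expit(g0 + g1 * np.asarray(collection_grid.times))
        assert curve.max() == pytest.approx(0.388)
        assert curve.argmax() == 0
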