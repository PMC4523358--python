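import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta, kstest

import seedpassage as sp
from seedpassage.inference import (
    InsufficientChainsError,
    MCMCSettings,
    PosteriorDraws,
    adaptive_metropolis,
    classic_rhat,
    desk_settings,
    gelman_rubin,
    full_settings,
    posterior_predictive_check,
    run_mcmc,
)
from seedpassage.io import FeedingDataset
from seedpassage.model import ModelSpec


def _tiny_dataset():
    """One animal, one plant, two collection times."""
    trials = pd.DataFrame([("a1", "s", 1, "p", 6)],
                          columns=["animal_id", "species", "replicate", "plant", "ntot"])
    feces = pd.DataFrame(
        [
            ("a1", 3.0, 1, 20.0, 5.0, 5.0, "p", 1, 0),
            ("a1", 6.0, 1, 18.0, 5.0, 5.0, "p", 2, 1),
        ],
        columns=["animal_id", "time_h", "defec", "w_g", "wd_g", "wg_g", "plant",
                 "y_count", "g_count"],
    )
    return FeedingDataset(trials=trials, feces=feces)


class TestSettings:
    def test_full_scale_defaults(self):
        s = full_settings()
        assert (s.n_chains, s.n_burnin, s.n_iter, s.thin) == (3, 10**6, 10**6, 500)
        assert s.n_draws == 2000

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_chains=1)
        with pytest.raises(ValueError):
            MCMCSettings(thin=0)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=5, thin=10)
        with pytest.raises(ValueError):
            MCMCSettings(backend="jags")


class TestSamplerEngine:
    def test_matches_beta_posterior_by_ks(self):
        """Binomial likelihood (7 of 20) with a flat prior: the sampled
        probability must follow Beta(8, 14)."""
        k, n = 7, 20

        def log_post(x):
            p = x[0]
            if not (0 < p < 1):
                return -np.inf
            return k * math.log(p) + (n - k) * math.log(1 - p)

        rng = np.random.default_rng(77)
        draws = adaptive_metropolis(log_post, np.array([0.5]), 4000, 100_000, 50,
                                    rng, scale0=np.array([0.1]))
        stat, pval = kstest(draws[:, 0], beta(k + 1, n - k + 1).cdf)
        assert pval > 0.01

    def test_non_finite_start_raises(self):
        with pytest.raises(Exception, match="not finite"):
            adaptive_metropolis(lambda x: -np.inf, np.array([0.0]), 10, 10, 1,
                                np.random.default_rng(0))


class TestRunMCMC:
    def test_deterministic_given_seed(self):
        ds = _tiny_dataset()
        settings = MCMCSettings(2, 300, 600, 3, seed=5)
        d1 = run_mcmc(ds, ModelSpec(), settings)
        d2 = run_mcmc(ds, ModelSpec(), settings)
        assert d1.names == d2.names
        for nm in d1.names:
            np.testing.assert_array_equal(d1.draws[nm], d2.draws[nm])
        d3 = run_mcmc(ds, ModelSpec(), MCMCSettings(2, 300, 600, 3, seed=6))
        assert not np.array_equal(d1.draws[d1.names[0]], d3.draws[d1.names[0]])

    def test_defecation_only_fit_exposes_only_hazards(self):
        ds = _tiny_dataset()
        draws = run_mcmc(ds, ModelSpec(components=("defecation",)),
                         MCMCSettings(2, 200, 400, 2, seed=1))
        assert draws.names == ["delta[s]"]
        assert np.all(draws.draws["delta[s]"] > 0)

    def test_probability_draws_stay_in_unit_interval(self):
        ds = _tiny_dataset()
        draws = run_mcmc(ds, ModelSpec(), MCMCSettings(2, 500, 1000, 5, seed=2))
        pviz = draws.draws["pviz[s,p]"]
        assert np.all((pviz >= 0) & (pviz <= 1))
        assert draws.n_draws == 200

    def test_backend_equivalence_on_small_instance(self):
        """Marginal (collapsed-latent) and latent-count samplers target the
        same posterior: means agree within Monte Carlo error."""
        ds = _tiny_dataset()
        fixed = {"delta[s]": 0.3, "b[s,p]": 0.0, "c[s,p]": 0.0,
                 "gamma0[s,p]": -1.0, "gamma1[s,p]": 0.0}
        spec = ModelSpec(fixed=fixed, constrain_curvature=False)
        dm = run_mcmc(ds, spec, MCMCSettings(2, 4000, 8000, 4, seed=1))
        dl = run_mcmc(ds, spec, MCMCSettings(2, 1500, 4500, 3, seed=2,
                                             backend="latent"))
        for nm, tol in (("a[s,p]", None), ("pviz[s,p]", None)):
            xm, xl = dm.stacked(nm), dl.stacked(nm)
            import arviz as az

            se = xm.std() / math.sqrt(az.ess(dm.draws[nm])) + xl.std() / math.sqrt(
                max(az.ess(dl.draws[nm]), 10))
            assert abs(xm.mean() - xl.mean()) < 5 * se

    def test_collapsed_random_effects_backend_runs(self):
        ds = _tiny_dataset()
        spec = ModelSpec(random_effects="collapsed")
        draws = run_mcmc(ds, spec, MCMCSettings(2, 400, 800, 4, seed=3))
        assert "sigma_e[s,p]" in draws.names
        assert np.all(draws.draws["sigma_e[s,p]"] > 0)

    def test_nothing_to_fit_raises(self):
        ds = _tiny_dataset()
        with pytest.raises(ValueError, match="nothing to fit"):
            run_mcmc(ds, ModelSpec(components=("defecation",),
                                   fixed={"delta[s]": 0.3}),
                     MCMCSettings(2, 100, 200, 2, seed=1))


class TestGelmanRubin:
    def test_null_distribution(self):
        """Chains sampled i.i.d. from one normal should pass comfortably."""
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(20):
            draws = PosteriorDraws({"x": rng.normal(0, 1, (3, 5000))})
            rep = gelman_rubin(draws, method="classic")
            ok += rep.table.rhat.iloc[0] <= 1.05
        assert ok >= 20 * 0.99 - 1e-9  # >= 99% of repetitions

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(12)
        arr = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        draws = PosteriorDraws({"x": arr})
        for method in ("classic", "rank"):
            rep = gelman_rubin(draws, method=method)
            assert rep.table.rhat.iloc[0] > 1.2
            assert not rep.passed
            assert rep.failing == ["x"]

    def test_chain_label_exchangeability(self):
        rng = np.random.default_rng(13)
        arr = rng.normal(0, 1, (4, 500))
        r1 = classic_rhat(arr)
        r2 = classic_rhat(arr[[2, 0, 3, 1]])
        assert r1 == pytest.approx(r2)

    def test_single_chain_rejected(self):
        with pytest.raises(InsufficientChainsError):
            classic_rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(PosteriorDraws({"x": np.zeros((2, 5))}))

    def test_rank_method_is_conservative_here(self, fixture_fit):
        rank = gelman_rubin(fixture_fit, method="rank")
        classic = gelman_rubin(fixture_fit, method="classic")
        assert rank.max_rhat >= classic.table.rhat.median() - 0.05


class TestPosteriorPredictiveCheck:
    def test_calibrated_under_the_true_model(self, re_free_sim, re_free_fit, rng):
        """Data simulated from the model itself should sit inside its own
        predictive distribution in the vast majority of cells (zero observed
        counts give tail exactly 1 by the >= convention and cannot indicate
        misfit)."""
        table = posterior_predictive_check(re_free_sim.dataset, re_free_fit, rng,
                                           n_rep=150)
        inside = (
            ((table.tail_y > 0.025) & (table.tail_y < 0.975))
            | ((table.obs_y == 0) & (table.tail_y == 1.0))
        ).mean()
        assert inside >= 0.85

    def test_all_zero_observations_give_tail_one(self, fixture_sim, fixture_fit, rng):
        table = posterior_predictive_check(fixture_sim.dataset, fixture_fit, rng,
                                           n_rep=50)
        zero_cells = table[table.obs_g == 0]
        assert (zero_cells.tail_g == 1.0).all()

    def test_gross_misfit_detected(self, fixture_sim, fixture_fit, rng):
        ds = fixture_sim.dataset
        inflated = ds.feces.copy()
        inflated["y_count"] = inflated["y_count"] * 10
        bad = FeedingDataset(trials=ds.trials.copy(), feces=inflated, grid=ds.grid)
        table = posterior_predictive_check(bad, fixture_fit, rng, n_rep=100)
        informative = table[table.obs_y >= 10]
        assert (informative.tail_y < 0.05).mean() > 0.9


class TestParameterRecovery:
    def test_defecation_credibility_interval_coverage(self):
        """Scaled-down coverage check: over repeated synthetic experiments the
        95% CrI for the 3-h defecation probability covers the truth."""
        import seedpassage.summaries as S

        base = sp.default_design()
        params = sp.reference_parameter_presets()
        truth = 0.70
        covered = 0
        reps = 10
        for i in range(reps):
            design = sp.StudyDesign(species=(base.species_profile("roe_deer"),),
                                    traits=base.traits, grid=base.grid)
            sim = sp.simulate_dataset(design, params, seed=900 + i)
            draws = run_mcmc(sim.dataset, ModelSpec(components=("defecation",)),
                             MCMCSettings(3, 5000, 10000, 10, seed=i))
            row = S.defecation_summary(draws).iloc[0]
            covered += row.pdef_lo <= truth <= row.pdef_hi
        assert covered >= 8

    def test_excretion_vertex_recovered_within_interval(self, fixture_sim, fixture_fit):
        """The credible interval of the grid retention time covers the preset
        vertex for most strongly-informed (wild boar) pairs."""
        import seedpassage.summaries as S
        from seedpassage.simulate import _MAXPEX_MRT

        ret = S.retention_time_estimates(fixture_fit, fixture_sim.design.grid)
        boar = ret[ret.species == "wild_boar"]
        hits = sum(
            row.mrt_lo <= _MAXPEX_MRT[(row.species, row.plant)][1] <= row.mrt_hi
            for _, row in boar.iterrows()
        )
        assert hits >= 5  # of 6 pairs
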