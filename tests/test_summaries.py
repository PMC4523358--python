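import math

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import norm

import seedpassage as sp
from seedpassage.inference import PosteriorDraws
from seedpassage.model import excretion_quadratic_from_peak
from seedpassage import summaries as S


def _draws_from_quadratics(quads, species="wild_boar", plant="Rubus_fruticosus"):
    """PosteriorDraws with the given (a, b, c) triples as two chains."""
    arr = np.asarray(quads, dtype=float)
    half = max(1, len(arr) // 2)
    shape = {}
    for k, nm in enumerate("abc"):
        vals = arr[:, k]
        shape[f"{nm}[{species},{plant}]"] = np.stack(
            [vals[:half], vals[-half:]])
    return PosteriorDraws(shape)


class TestRetentionTime:
    def test_vertex_on_grid_returned_exactly(self, collection_grid):
        quad = excretion_quadratic_from_peak(0.05, 18.0)
        d = _draws_from_quadratics([quad, quad])
        tab = S.retention_time_estimates(d, collection_grid)
        assert tab.mrt_median.iloc[0] == 18.0
        assert not tab.boundary_flag.iloc[0]

    def test_off_grid_vertex_snaps_to_nearest_richer_neighbor(self, collection_grid):
        # vertex at 20 h: grid neighbors 18 and 21, and pex(21) > pex(18)
        quad = excretion_quadratic_from_peak(0.05, 20.0)
        d = _draws_from_quadratics([quad, quad])
        tab = S.retention_time_estimates(d, collection_grid)
        assert tab.mrt_median.iloc[0] == 21.0

    def test_boundary_censoring_flagged(self, collection_grid):
        # still increasing at 54 h, as for wild boar x Trifolium
        quad = excretion_quadratic_from_peak(0.05, 70.0)
        d = _draws_from_quadratics([quad, quad])
        tab = S.retention_time_estimates(d, collection_grid)
        assert tab.mrt_median.iloc[0] == 54.0
        assert tab.boundary_flag.iloc[0]

    def test_max_pex_summary_matches_construction(self, collection_grid):
        quad = excretion_quadratic_from_peak(0.0714, 42.0)
        d = _draws_from_quadratics([quad] * 4)
        tab = S.retention_time_estimates(d, collection_grid)
        assert tab.max_pex_median.iloc[0] == pytest.approx(0.0714, rel=1e-6)
        assert tab.mrt_vertex_median.iloc[0] == pytest.approx(42.0)

    def test_argmax_invariant_under_monotone_rescaling(self, collection_grid):
        rng = np.random.default_rng(5)
        a = rng.normal(-4, 1, 50)
        b = rng.normal(0.2, 0.05, 50)
        c = -np.abs(rng.normal(0.004, 0.001, 50))
        t1 = S.grid_argmax_time(a, b, c, np.asarray(collection_grid.times))
        t2 = S.grid_argmax_time(a + 3.7, b, c, np.asarray(collection_grid.times))
        np.testing.assert_array_equal(t1, t2)

    def test_empty_draws_rejected(self, collection_grid):
        d = PosteriorDraws({"a[s,p]": np.empty((2, 0)), "b[s,p]": np.empty((2, 0)),
                            "c[s,p]": np.empty((2, 0))})
        with pytest.raises(ValueError, match="no posterior draws"):
            S.retention_time_estimates(d, collection_grid)


class TestDefecationSummary:
    def test_degenerate_draws_collapse_interval(self):
        d = PosteriorDraws({"delta[roe_deer]": np.full((3, 40), 0.4013)})
        tab = S.defecation_summary(d)
        assert tab.pdef_median.iloc[0] == pytest.approx(0.70, abs=1e-3)
        assert tab.pdef_lo.iloc[0] == pytest.approx(tab.pdef_hi.iloc[0])

    def test_monotone_in_reference_interval(self):
        rng = np.random.default_rng(3)
        d = PosteriorDraws({"delta[s]": np.abs(rng.normal(0.3, 0.1, (2, 200)))})
        p3 = S.defecation_summary(d, reference_dt=3)
        p6 = S.defecation_summary(d, reference_dt=6)
        assert p6.pdef_median.iloc[0] >= p3.pdef_median.iloc[0]
        assert p6.pdef_hi.iloc[0] >= p3.pdef_hi.iloc[0]


class TestOverlapAndExceedance:
    def test_overlap_limits(self):
        x = np.random.default_rng(1).normal(size=2000)
        assert S.posterior_overlap_percentage(x, x) == pytest.approx(100.0)
        assert S.posterior_overlap_percentage(x, x + 100) == pytest.approx(0.0)

    def test_overlap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 3000), rng.normal(0.7, 1.3, 3000)
        assert S.posterior_overlap_percentage(a, b) == pytest.approx(
            S.posterior_overlap_percentage(b, a))

    def test_overlap_normal_closed_form(self):
        """Two unit normals one SD apart overlap by 2 * Phi(-1/2)."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10**5), rng.normal(1, 1, 10**5)
        expected = 100 * 2 * norm.cdf(-0.5)
        assert S.posterior_overlap_percentage(a, b) == pytest.approx(expected, abs=1.0)
        assert S.posterior_overlap_percentage(a, b, method="kde") == pytest.approx(
            expected, abs=1.0)

    def test_exceedance_ties_count_half(self):
        x = np.arange(100.0)
        assert S.exceedance_probability(x, x) == 0.5

    def test_exceedance_normal_closed_form(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10**5), rng.normal(1, 1, 10**5)
        assert S.exceedance_probability(a, b) == pytest.approx(
            norm.cdf(1 / math.sqrt(2)), abs=0.01)

    def test_exceedance_complement_identity(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 5000), rng.normal(0.2, 1, 5000)
        p_ab = S.exceedance_probability(a, b)
        p_ba = S.exceedance_probability(b, a)
        assert p_ab + p_ba == pytest.approx(1.0)  # ties have measure ~0, weight split

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            S.exceedance_probability(np.zeros(10), np.zeros(11))

    def test_group_exceedance_reports_mean_and_sd(self):
        rng = np.random.default_rng(8)
        ga = {"u1": rng.normal(0, 1, 4000), "u2": rng.normal(0.1, 1, 4000)}
        gb = {"v1": rng.normal(1, 1, 4000)}
        mean, sd = S.exceedance_probability_groups(ga, gb)
        assert 0.6 < mean < 0.85
        assert sd >= 0


class TestMaxGermination:
    def test_declining_curve_peaks_at_first_collection(self, collection_grid):
        d = PosteriorDraws({
            "gamma0[red_deer,Juncus_effusus]": np.zeros((2, 10)),
            "gamma1[red_deer,Juncus_effusus]": np.full((2, 10), -0.1),
        })
        tab = S.max_germination_probability(d, collection_grid)
        from scipy.special import expit

        assert tab.max_pgerm_median.iloc[0] == pytest.approx(expit(-0.3))

    def test_degenerate_posterior_flagged_without_data(self, collection_grid):
        d = PosteriorDraws({
            "gamma0[s,p]": np.full((2, 10), -30.0),
            "gamma1[s,p]": np.zeros((2, 10)),
        })
        tab = S.max_germination_probability(d, collection_grid)
        assert tab.degenerate_flag.iloc[0]

    def test_zero_seedling_pairs_flagged_from_data(self, fixture_sim, fixture_fit):
        tab = S.max_germination_probability(fixture_fit, fixture_sim.design.grid,
                                            dataset=fixture_sim.dataset)
        merged = fixture_sim.feces.merge(
            fixture_sim.trials[["animal_id", "plant", "species"]],
            on=["animal_id", "plant"])
        totals = merged.groupby(["species", "plant"])["g_count"].sum()
        for _, row in tab.iterrows():
            assert row.degenerate_flag == (totals[(row.species, row.plant)] == 0)


class TestPercentExcreted:
    def test_zero_counts_give_zero_percent(self, fixture_sim):
        ds = fixture_sim.dataset
        feces = ds.feces.copy()
        feces[["y_count", "g_count"]] = 0
        from seedpassage.io import FeedingDataset

        empty = FeedingDataset(trials=ds.trials.copy(), feces=feces, grid=ds.grid)
        d = PosteriorDraws({
            f"pviz[{s},{p}]": np.full((2, 10), 0.5)
            for (s, p) in fixture_sim.params.pviz
        })
        tab = S.percent_seeds_excreted(empty, d)
        assert (tab.pct_excreted_mean == 0).all()

    def test_recovers_latent_truth_on_simulated_data(self, fixture_sim):
        """Inverting the subsampling with the true detection probability
        reproduces the simulator's latent excreted fractions."""
        d = PosteriorDraws({
            f"pviz[{s},{p}]": np.full((2, 10), fixture_sim.params.pviz[(s, p)])
            for (s, p) in fixture_sim.params.pviz
        })
        est = S.percent_seeds_excreted(fixture_sim.dataset, d).set_index("species")
        truth = {}
        for (animal, plant), traj in fixture_sim.latent.items():
            s = animal.rsplit("_", 2)[0] + "_" + animal.rsplit("_", 2)[1]
            ntot = fixture_sim.trials.query(
                "animal_id == @animal and plant == @plant").ntot.iloc[0]
            truth.setdefault(s, []).append(100 * traj.nf.sum() / ntot)
        for s, vals in truth.items():
            t = np.mean(vals)
            assert est.loc[s, "pct_excreted_mean"] == pytest.approx(
                t, abs=max(0.15 * t, 1.5))
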