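import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import omnidiet as od
from omnidiet.datatypes import Dtdf, McmcConfig
from omnidiet.isotopes import SourceGroupSet
from omnidiet.mixing import ilr, ilr_inv

ZERO_DTDF = Dtdf(d13C_mean=0, d13C_sd=0, d15N_mean=0, d15N_sd=0)


def _sources(mu, sd, pctC, pctN):
    names = [f"s{i}" for i in range(len(mu))]
    stats = pd.DataFrame(
        {
            "n": 5,
            "mean_d13C": [m[0] for m in mu],
            "sd_d13C": [s[0] for s in sd],
            "mean_d15N": [m[1] for m in mu],
            "sd_d15N": [s[1] for s in sd],
            "mean_pctC": pctC,
            "mean_pctN": pctN,
        },
        index=pd.Index(names, name="group"),
    )
    return SourceGroupSet(groups={n: [n] for n in names}, stats=stats)


class TestIlr:
    @given(
        st.lists(st.floats(min_value=0.01, max_value=10), min_size=2, max_size=6)
    )
    def test_round_trip(self, raw):
        p = np.array(raw) / np.sum(raw)
        np.testing.assert_allclose(ilr_inv(ilr(p)), p, atol=1e-12)

    def test_skbio_oracle(self):
        composition = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(5), size=10)
        ours = ilr_inv(ilr(p))
        theirs = composition.ilr_inv(composition.ilr(p))
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_batched_shapes(self):
        x = np.zeros((7, 3))
        p = ilr_inv(x)
        assert p.shape == (7, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)


class TestMixingMoments:
    def test_single_source_ignores_concentrations(self):
        src = _sources([(-20, 5), (-10, 9)], [(1, 1)] * 2, [40, 60], [5, 15])
        dt = Dtdf(d13C_mean=1.7, d13C_sd=0, d15N_mean=3.2, d15N_sd=0)
        assert od.mixture_mean(np.array([1.0, 0.0]), src, dt, "d13C") == pytest.approx(
            -18.3
        )
        assert od.mixture_mean(np.array([0.0, 1.0]), src, dt, "d15N") == pytest.approx(
            12.2
        )

    def test_equal_concentration_reduces_to_weighted_mean(self):
        src = _sources([(-20, 5), (-10, 9)], [(1, 1)] * 2, 45.0, 5.0)
        dt = Dtdf(d13C_mean=1.7, d13C_sd=0, d15N_mean=0, d15N_sd=0)
        out = od.mixture_mean(np.array([0.5, 0.5]), src, dt, "d13C")
        assert out == pytest.approx(-13.3)

    def test_concentration_weighting_tilts_mean(self):
        src = _sources([(-20, 5), (-10, 9)], [(1, 1)] * 2, [90, 10], [5, 5])
        out = od.mixture_mean(np.array([0.5, 0.5]), src, ZERO_DTDF, "d13C")
        # carbon-rich source dominates the carbon mixture
        assert out == pytest.approx(0.9 * -20 + 0.1 * -10)

    def test_variance_hand_computed(self):
        src = _sources([(-20, 5), (-10, 9)], [(1, 1)] * 2, 45.0, 5.0)
        out = od.mixture_variance(np.array([0.5, 0.5]), src, ZERO_DTDF, "d13C",
                                  xi=1.0)
        assert out == pytest.approx(0.5)  # 2 x 0.25 x 1

    def test_variance_scales_with_xi_and_dtdf_sd(self):
        src = _sources([(-20, 5)], [(1, 1)], 45.0, 5.0)
        dt = Dtdf(d13C_mean=0, d13C_sd=1.3, d15N_mean=0, d15N_sd=0)
        v1 = od.mixture_variance(np.array([1.0]), src, dt, "d13C", xi=1.0)
        v2 = od.mixture_variance(np.array([1.0]), src, dt, "d13C", xi=2.0)
        assert v1 == pytest.approx(1 + 1.3**2)
        assert v2 == pytest.approx(2 * v1)


class TestGelmanRubin:
    def test_split_copies_near_one(self):
        rng = np.random.default_rng(2)
        stream = rng.normal(size=2000)
        chains = stream.reshape(2, 1000)
        assert od.gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(3)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert od.gelman_rubin(chains) > 1.1

    def test_hand_case_matches_bruteforce(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 2.5, 3.5, 2.2, 2.8],
                      [2.0, 3.0, 2.0, 5.0, 3.0, 2.0, 4.0, 3.0, 2.5, 3.5]])
        # independent formula evaluation
        m, n = x.shape
        W = np.mean([np.var(c, ddof=1) for c in x])
        B = n * np.var([c.mean() for c in x], ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert od.gelman_rubin(x) == pytest.approx(expected, abs=1e-12)

    def test_guards(self):
        with pytest.raises(od.ValidationError):
            od.gelman_rubin(np.zeros((1, 100)))
        with pytest.raises(od.ValidationError):
            od.gelman_rubin(np.zeros((2, 5)))


class TestSummaries:
    def test_uniform_draw_quantiles(self):
        rng = np.random.default_rng(4)
        draws = rng.uniform(size=(10_000, 1))
        s = od.summarize_posterior(draws, ["u"])
        assert s.loc["u", "2.5%"] == pytest.approx(0.025, abs=0.01)
        assert s.loc["u", "97.5%"] == pytest.approx(0.975, abs=0.01)
        assert s.loc["u", "mean"] == pytest.approx(0.5, abs=0.02)

    def test_degenerate_posterior_collapses(self):
        draws = np.full((50, 2), 0.5)
        s = od.summarize_posterior(draws, ["a", "b"])
        assert (s["sd"] == 0).all()
        assert (s["2.5%"] == s["97.5%"]).all()


class TestAggregation:
    def _results(self, draws):
        src = _sources([(-20, 5), (-10, 9), (-15, 7), (-25, 3)],
                       [(1, 1)] * 4, 45.0, 5.0)
        consumers = pd.DataFrame({"d13C": [-15.0], "d15N": [6.0]},
                                 index=["c1"])
        model = od.IsotopeMixingModel(consumers, src, ZERO_DTDF)
        mc = McmcConfig(chains=1, iterations=20, burn_in=10, thin=10)
        return od.MixingResults(
            model=model, draws={"p_global": draws,
                                "xi": np.ones((1, len(draws[0]), 2))},
            mcmc=mc,
        )

    def test_combined_draws_sum_members(self):
        draws = np.array([[[0.1, 0.2, 0.3, 0.4]]])
        res = self._results(draws)
        agg = res.aggregate({"s0": "g1", "s1": "g1", "s2": "g1", "s3": "g2"})
        np.testing.assert_allclose(agg.draws["p_global"][0, 0], [0.6, 0.4])

    def test_identity_map_unchanged(self):
        draws = np.array([[[0.1, 0.2, 0.3, 0.4]]])
        res = self._results(draws)
        agg = res.aggregate({f"s{i}": f"s{i}" for i in range(4)})
        np.testing.assert_allclose(agg.draws["p_global"], draws)

    def test_study_map_eight_to_four(self):
        """Five arthropod sources collapse into one of four groups."""
        rng = np.random.default_rng(5)
        p8 = rng.dirichlet(np.ones(8), size=3)[None]
        names = ["arth1", "arth2", "arth3", "arth4", "arth5",
                 "C3", "C4", "moli"]
        agg_draws, agg_names = od.mixing._aggregate(
            p8[0], names,
            {**{f"arth{i}": "arthropods" for i in range(1, 6)},
             "C3": "C3", "C4": "C4", "moli": "moli"},
        )
        assert agg_names == ["arthropods", "C3", "C4", "moli"]
        np.testing.assert_allclose(agg_draws[:, 0], p8[0][:, :5].sum(axis=1))
        np.testing.assert_allclose(agg_draws.sum(axis=1), 1.0, atol=1e-10)

    def test_non_partition_rejected(self):
        draws = np.array([[[0.1, 0.2, 0.3, 0.4]]])
        res = self._results(draws)
        with pytest.raises(od.ValidationError, match="partition"):
            res.aggregate({"s0": "g1"})


class TestFit:
    def test_prior_predictive_matches_dirichlet(self):
        """With the likelihood disabled the global simplex is Dirichlet(1)."""
        src = _sources([(-25, 3), (-12, 6), (-18, 12)], [(1, 1)] * 3, 45.0, 5.0)
        consumers = pd.DataFrame({"d13C": [-18.0], "d15N": [7.0]}, index=["c1"])
        model = od.IsotopeMixingModel(consumers, src, ZERO_DTDF)
        res = model.fit(
            McmcConfig(chains=3, iterations=12_000, burn_in=2_000, thin=5),
            seed=6, prior_only=True,
        )
        p = res.p_global
        # Dirichlet(1,1,1): mean 1/3, var = 2/(9*4) = 1/18
        np.testing.assert_allclose(p.mean(axis=0), 1 / 3, atol=0.02)
        np.testing.assert_allclose(p.var(axis=0), 1 / 18, atol=0.01)

    def test_two_source_recovery(self):
        """K=2 is fully identified: posterior mean near the true (0.7, 0.3)."""
        from omnidiet.simulate import IsotopeSimConfig, simulate_isotope_study

        truth_sources = pd.DataFrame(
            {
                "mean_d13C": [-26.0, -12.0],
                "sd_d13C": [1.0, 1.0],
                "mean_d15N": [3.0, 9.0],
                "sd_d15N": [1.0, 1.0],
                "pctC": [45.0, 45.0],
                "pctN": [8.0, 8.0],
            },
            index=pd.Index(["plant", "prey"], name="group"),
        )
        cfg = IsotopeSimConfig(
            source_truth=truth_sources, p_true=np.array([0.7, 0.3]),
            n_consumers=100, n_specimens_per_source=20, seed=7,
        )
        records, meta, truth = simulate_isotope_study(cfg)
        model = od.IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf
        )
        res = model.fit(
            McmcConfig(chains=3, iterations=6_000, burn_in=3_000, thin=5), seed=8
        )
        assert abs(res.p_global.mean(axis=0)[0] - 0.7) < 0.05
        assert res.rhat.max() < 1.1

    def test_consumer_at_single_source_identified(self):
        src = _sources([(-25, 3), (-12, 9), (-18, 14)], [(0.5, 0.5)] * 3,
                       45.0, 5.0)
        rng = np.random.default_rng(9)
        consumers = pd.DataFrame(
            {
                "d13C": -25 + rng.normal(0, 0.2, 40),
                "d15N": 3 + rng.normal(0, 0.2, 40),
            },
            index=[f"c{i}" for i in range(40)],
        )
        model = od.IsotopeMixingModel(consumers, src, ZERO_DTDF)
        res = model.fit(
            McmcConfig(chains=2, iterations=4_000, burn_in=2_000, thin=4), seed=10
        )
        assert res.p_global.mean(axis=0)[0] > 0.9

    def test_same_seed_identical_draws(self, iso_small):
        (records, meta, truth), cfg = iso_small
        model = od.IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf
        )
        mc = McmcConfig(chains=2, iterations=1_000, burn_in=500, thin=5)
        a = model.fit(mc, seed=11)
        b = model.fit(mc, seed=11)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])

    def test_simplex_conservation(self, iso_small):
        (records, meta, truth), cfg = iso_small
        model = od.IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf
        )
        res = model.fit(
            McmcConfig(chains=2, iterations=1_000, burn_in=500, thin=5), seed=12
        )
        np.testing.assert_allclose(
            res.p_global.sum(axis=1), 1.0, atol=1e-10
        )
        assert (res.draws["xi"] > 0).all()

    def test_summary_by_factor_levels(self):
        from omnidiet.simulate import IsotopeSimConfig, default_source_truth, \
            simulate_isotope_study

        cfg = IsotopeSimConfig(
            source_truth=default_source_truth(3), n_consumers=30,
            sigma_habitat=0.3, seed=13,
        )
        records, meta, truth = simulate_isotope_study(cfg)
        model = od.IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf,
            metadata=meta, factors=("habitat",),
        )
        res = model.fit(
            McmcConfig(chains=2, iterations=800, burn_in=400, thin=4), seed=14
        )
        s = res.summary(by="habitat")
        assert set(s["scope"]) == {"overall", "habitat=forest",
                                   "habitat=herbland", "habitat=shrub",
                                   "habitat=wetland"}
        for _, block in s.groupby("scope"):
            assert block["mean"].sum() == pytest.approx(1.0, abs=1e-8)

    def test_variance_partition_single_factor(self):
        from omnidiet.simulate import IsotopeSimConfig, default_source_truth, \
            simulate_isotope_study

        cfg = IsotopeSimConfig(
            source_truth=default_source_truth(3), n_consumers=30,
            sigma_habitat=0.3, seed=15,
        )
        records, meta, truth = simulate_isotope_study(cfg)
        model = od.IsotopeMixingModel.from_frames(
            records, truth["sample_sources"], cfg.dtdf,
            metadata=meta, factors=("habitat",),
        )
        res = model.fit(
            McmcConfig(chains=2, iterations=800, burn_in=400, thin=4), seed=16
        )
        vp = res.variance_partition()
        assert list(vp.index) == ["habitat"]
        assert "variance_ratio_vs_habitat" not in vp.columns
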