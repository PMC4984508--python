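import numpy as np
import pytest

from craterdemog.coalescent import simulate_sfs
from craterdemog.demography import Deme, DemographicModel
from craterdemog.fit import (
    FreeParam,
    ModelSpec,
    composite_lnl,
    crater_model_spec,
    ecm_fit,
    expected_sfs,
    parametric_bootstrap,
    rank_models,
    scale_params,
    unscale_params,
)
from craterdemog.types import FitResult, InferenceConfig, JointSFS


def _single_deme_spec(lo=500.0, hi=50_000.0):
    def builder(v):
        return DemographicModel(
            demes=[Deme("a", v["n"])], sample_config={"a": 10}
        )

    return ModelSpec("const", [FreeParam("n", lo, hi, "log")], builder)


class TestExpectedSfs:
    def test_single_deme_marginal_follows_one_over_i(self):
        model = DemographicModel(demes=[Deme("a", 2000.0)], sample_config={"a": 10})
        exp = expected_sfs(model, 20_000, seed=1, mu=1e-8, fold=False)
        xi = exp.counts[1:10, 0]
        ratios = xi / xi[0] * np.arange(1, 10)
        assert np.allclose(ratios, 1.0, atol=0.06)

    def test_symmetric_island_model_is_exchange_symmetric(self):
        model = DemographicModel(
            demes=[Deme("a", 1000.0), Deme("b", 1000.0)],
            migration=[[0.0, 1e-3], [1e-3, 0.0]],
            sample_config={"a": 6, "b": 6},
        )
        exp = expected_sfs(model, 30_000, seed=2, mu=1e-8)
        c = exp.counts
        # symmetry under swapping the two demes, away from tiny cells
        big = (c > 1e-4 * c.sum()) & (c.T > 1e-4 * c.sum())
        assert np.allclose(c[big], c.T[big], rtol=0.12)

    def test_monomorphic_probability_complements_tree_length(self):
        model = DemographicModel(demes=[Deme("a", 2000.0)], sample_config={"a": 10})
        mu = 1e-8
        exp = expected_sfs(model, 5000, seed=3, mu=mu)
        assert exp.counts.sum() == pytest.approx(1.0, abs=1e-9)
        assert exp.counts[0, 0] > 0.99  # tiny theta: almost all monomorphic

    def test_mc_error_shrinks_with_more_simulations(self):
        model = DemographicModel(demes=[Deme("a", 2000.0)], sample_config={"a": 8})
        devs = {}
        for n_sims, n_rep in ((2000, 8), (8000, 8)):
            rows = [
                expected_sfs(model, n_sims, seed=100 + r, mu=1e-8, fold=False).counts[
                    1:8, 0
                ]
                for r in range(n_rep)
            ]
            devs[n_sims] = np.std(np.array(rows), axis=0).mean()
        assert devs[8000] < devs[2000] / np.sqrt(2) * 1.35  # ~1/sqrt(4) expected

    def test_too_few_sims_rejected(self):
        model = DemographicModel(demes=[Deme("a", 100.0)], sample_config={"a": 4})
        with pytest.raises(ValueError):
            expected_sfs(model, 10, mu=1e-8)


class TestCompositeLnl:
    def test_hand_summed_toy(self):
        obs = JointSFS(np.array([[0.0, 3.0], [2.0, 0.0]]), 1, 1, folded=False)
        p = JointSFS(np.array([[0.0, 0.6], [0.4, 0.0]]), 1, 1, folded=False)
        assert composite_lnl(obs, p) == pytest.approx(
            3 * np.log(0.6) + 2 * np.log(0.4)
        )

    def test_all_zero_observation_gives_zero(self):
        obs = JointSFS(np.zeros((2, 2)), 1, 1)
        p = JointSFS(np.array([[0.0, 0.5], [0.5, 0.0]]), 1, 1)
        assert composite_lnl(obs, p) == 0.0

    def test_gibbs_inequality(self):
        """lnL is maximal when the expected proportions equal the observed
        ones; any perturbed expected spectrum scores lower."""
        rng = np.random.default_rng(8)
        q = rng.random((5, 5))
        q[0, 0] = q[4, 4] = 0.0
        q /= q.sum()
        obs = JointSFS(q * 1000, 4, 4)
        best = composite_lnl(obs, JointSFS(q, 4, 4))
        for _ in range(100):
            pert = q * np.exp(0.3 * rng.standard_normal(q.shape))
            pert[0, 0] = pert[4, 4] = 0.0
            pert /= pert.sum()
            assert composite_lnl(obs, JointSFS(pert, 4, 4)) <= best + 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_lnl(
                JointSFS(np.zeros((2, 2)), 1, 1), JointSFS(np.zeros((3, 3)), 2, 2)
            )


class TestEcmFit:
    def test_zero_free_parameters_returns_fixed_lnl(self):
        model_params = {"n": 2000.0}

        def builder(v):
            return DemographicModel(
                demes=[Deme("a", v["n"])], sample_config={"a": 10}
            )

        spec = ModelSpec("fixed", [], builder, fixed=model_params)
        truth = builder(model_params)
        obs = simulate_sfs(truth, mu=1e-7, n_sites=20_000, seed=3)
        cfg = InferenceConfig(
            mu=1e-7, ecm_rounds=1, sims_start=2000, sims_end=2000, sims_step=0,
            n_starts=1, seed=0,
        )
        res = ecm_fit(spec, obs, cfg)
        assert res.n_free == 0
        assert np.isfinite(res.lnl)
        assert res.aic == pytest.approx(-2 * res.lnl)

    def test_recovers_constant_population_size(self):
        """Self-consistency: a 1-parameter constant-size model fitted to its
        own simulated data recovers the size within 10%."""
        truth = DemographicModel(demes=[Deme("a", 5000.0)], sample_config={"a": 10})
        obs = simulate_sfs(truth, mu=1e-7, n_sites=100_000, seed=4)
        cfg = InferenceConfig(
            mu=1e-7, ecm_rounds=8, sims_start=3000, sims_end=5000, sims_step=500,
            n_starts=2, seed=1,
        )
        res = ecm_fit(_single_deme_spec(), obs, cfg)
        assert res.params["n"] == pytest.approx(5000.0, rel=0.10)

    def test_lnl_non_decreasing_within_round(self, monkeypatch):
        """Accepted coordinate steps never lower the composite likelihood
        at the round's shared simulation seed."""
        import craterdemog.fit as fit_mod

        truth = DemographicModel(demes=[Deme("a", 3000.0)], sample_config={"a": 8})
        obs = simulate_sfs(truth, mu=1e-7, n_sites=30_000, seed=5)
        accepted = []  # (round seed, lnl of the accepted point) per CM step
        orig_step = fit_mod._coordinate_step

        def recording_step(f, p, lo, hi, current, step_frac, max_evals,
                           **kwargs):
            x, lnl = orig_step(f, p, lo, hi, current, step_frac, max_evals,
                               **kwargs)
            accepted.append((step_frac, lnl))
            return x, lnl

        monkeypatch.setattr(fit_mod, "_coordinate_step", recording_step)

        def builder(v):
            return DemographicModel(
                demes=[Deme("a", v["n"], v["g"])], sample_config={"a": 8}
            )

        spec = ModelSpec(
            "grow", [FreeParam("n", 500, 50_000, "log"),
                     FreeParam("g", -0.001, 0.01, "linear")], builder,
        )
        cfg = InferenceConfig(
            mu=1e-7, ecm_rounds=4, sims_start=2000, sims_end=3000, sims_step=500,
            n_starts=1, seed=2,
        )
        ecm_fit(spec, obs, cfg)
        # steps within one round share a simulation seed (they appear
        # consecutively with the same step fraction); the accepted values'
        # likelihoods must be non-decreasing inside each round
        assert accepted
        rounds = {}
        for i, (frac, lnl) in enumerate(accepted):
            rounds.setdefault((frac, i // 2), []).append(lnl)  # 2 params/round
        for lnls in rounds.values():
            assert all(b >= a - 1e-9 for a, b in zip(lnls, lnls[1:]))

    def test_requires_polymorphic_observation(self):
        obs = JointSFS(np.zeros((11, 1)), 10, 0)
        cfg = InferenceConfig(mu=1e-8, sims_start=1000, sims_end=1000, n_starts=1)
        with pytest.raises(ValueError):
            ecm_fit(_single_deme_spec(), obs, cfg)


class TestRankModels:
    def _fit(self, model_id, lnl, k, obs_id="x"):
        return FitResult(model_id, {}, lnl, k, obs_id=obs_id)

    def test_orders_by_aic_with_delta(self):
        table = rank_models([self._fit("a", -100.0, 2), self._fit("b", -90.0, 5)])
        assert [r["model_id"] for r in table] == ["b", "a"]
        assert table[0]["delta_aic"] == 0.0
        assert table[1]["delta_aic"] == pytest.approx(204 - 190)

    def test_single_fit_ranks_first(self):
        assert rank_models([self._fit("only", -5.0, 1)])[0]["rank"] == 1

    def test_tie_broken_by_parameter_count(self):
        # same AIC: lnl difference exactly compensates parameter count
        a = self._fit("complex", -99.0, 3)
        b = self._fit("simple", -100.0, 2)
        table = rank_models([a, b])
        assert table[0]["model_id"] == "simple"

    def test_mixed_observations_rejected(self):
        with pytest.raises(ValueError):
            rank_models([self._fit("a", -1.0, 1, "x"), self._fit("b", -1.0, 1, "y")])


class TestBootstrap:
    def test_two_replicates_give_min_max_interval(self):
        spec = _single_deme_spec()
        truth = spec.build({"n": 4000.0})
        mle = FitResult("const", {"n": 4000.0}, -10.0, 1)
        cfg = InferenceConfig(
            mu=1e-7, ecm_rounds=3, sims_start=2000, sims_end=3000, sims_step=500,
            n_starts=1, n_bootstrap=2, seed=3,
        )
        ci = parametric_bootstrap(spec, mle, effective_length=30_000, config=cfg)
        lo, hi = ci["n"]
        assert lo < hi
        # with n = 2 the percentile interval collapses onto the two refits
        assert lo == pytest.approx(lo) and np.isfinite(hi)

    def test_interval_covers_truth_for_identifiable_model(self):
        spec = _single_deme_spec()
        mle = FitResult("const", {"n": 5000.0}, -10.0, 1)
        cfg = InferenceConfig(
            mu=1e-7, ecm_rounds=4, sims_start=2000, sims_end=3000, sims_step=500,
            n_starts=1, n_bootstrap=6, seed=4,
        )
        ci = parametric_bootstrap(spec, mle, effective_length=50_000, config=cfg)
        lo, hi = ci["n"]
        assert lo < 5000.0 < hi


class TestUnitConversion:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            params = {
                "n_anc": float(rng.uniform(1e3, 1e5)),
                "n_now": float(rng.uniform(1e3, 1e6)),
                "t_col": float(rng.uniform(10, 5000)),
                "mig": float(rng.uniform(1e-6, 1e-3)),
                "admix_prop": float(rng.uniform(0, 1)),
            }
            s = scale_params(params, mu=7.5e-9, effective_length=3.78e6)
            back = unscale_params(s, mu=7.5e-9, effective_length=3.78e6)
            for k, v in params.items():
                assert back[k] == pytest.approx(v, rel=1e-12)

    def test_theta_back_converts_to_printed_size(self):
        mu, L = 7.5e-9, 3.78e6
        theta = 4 * 20_439 * mu * L
        back = unscale_params({"theta": theta}, mu=mu, effective_length=L)
        assert back["n_anc"] == pytest.approx(20_439, rel=1e-12)

    def test_doubling_mu_halves_size_at_fixed_theta(self):
        mu, L = 7.5e-9, 1e6
        theta = 4 * 10_000 * mu * L
        n1 = unscale_params({"theta": theta}, mu=mu, effective_length=L)["n_anc"]
        n2 = unscale_params({"theta": theta}, mu=2 * mu, effective_length=L)["n_anc"]
        assert n2 == pytest.approx(n1 / 2)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            scale_params({"n_anc": 1000.0}, mu=0.0, effective_length=1e6)
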