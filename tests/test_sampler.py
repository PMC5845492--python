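"""Sampler correctness: exact conditionals, conjugacy, determinism, and a
Geweke joint-distribution check of the whole transition kernel."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import bernoulli, poisson

from miscount import (
    ChainConfig,
    Dataset,
    MiscountError,
    Mode,
    ParameterState,
    PriorSpec,
    gibbs_step,
    latent_x_full_conditional,
    run_chain,
    simulate_dataset,
    SimDesign,
    summarize,
)
from miscount.sampler import MCMC


def _mini_dataset(rng, n=12, N=3, q=2, two_tests=True):
    cluster = rng.integers(1, N + 1, n)
    cluster[:N] = np.arange(1, N + 1)  # every cluster occupied
    z = rng.standard_normal((n, q))
    return Dataset(
        y=rng.poisson(2.0, n),
        cluster=cluster,
        z_outcome=z,
        z_exposure=z,
        r=rng.uniform(0.5, 2.0, n),
        x1=rng.integers(0, 2, n),
        x2=rng.integers(0, 2, n) if two_tests else None,
    )


def _mini_state(rng, data, **kw):
    N = data.n_clusters
    q = data.z_exposure.shape[1]
    defaults = dict(
        beta0=rng.normal(0, 0.3),
        beta1=rng.normal(0, 0.3),
        beta=rng.normal(0, 0.3, data.z_outcome.shape[1]),
        u=rng.normal(0, 0.1, N),
        sigma=0.15,
        gamma0=rng.normal(0, 0.5),
        gamma=rng.normal(0, 0.3, q),
        v=rng.normal(0, 0.1, N),
        nu=0.12,
        S1=0.6,
        C1=0.9,
        S2=0.7,
        C2=0.8,
        x_latent=rng.integers(0, 2, data.n_subjects),
    )
    defaults.update(kw)
    return ParameterState(**defaults)


class TestLatentFullConditional:
    @pytest.mark.parametrize("mode", ["one_test", "two_test"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, mode, seed):
        """P(x=1 | rest) equals direct two-point Bayes to 1e-12."""
        rng = np.random.default_rng(seed)
        data = _mini_dataset(rng)
        state = _mini_state(rng, data)
        p = latent_x_full_conditional(data, state, mode)
        for i in range(data.n_subjects):
            j = data.cluster_index[i]
            weights = []
            for x in (0, 1):
                eta = (
                    state.beta0
                    + state.u[j]
                    + state.beta1 * x
                    + float(data.z_outcome[i] @ state.beta)
                )
                pi = expit(
                    state.gamma0 + state.v[j] + float(data.z_exposure[i] @ state.gamma)
                )
                w = bernoulli.pmf(x, pi) * poisson.pmf(
                    data.y[i], data.r[i] * np.exp(eta)
                )
                p1 = state.S1 if x == 1 else 1 - state.C1
                w *= bernoulli.pmf(data.x1[i], p1)
                if mode == "two_test":
                    p2 = state.S2 if x == 1 else 1 - state.C2
                    w *= bernoulli.pmf(data.x2[i], p2)
                weights.append(w)
            assert p[i] == pytest.approx(
                weights[1] / (weights[0] + weights[1]), abs=1e-12
            )

    def test_uninformative_test_and_null_effect_returns_pi(self):
        """S=C=0.5 and beta1=0: the data say nothing, so P(x=1|.) = pi."""
        rng = np.random.default_rng(7)
        data = _mini_dataset(rng, two_tests=False)
        state = _mini_state(rng, data, S1=0.5, C1=0.5, beta1=0.0)
        p = latent_x_full_conditional(data, state, "one_test")
        pi = expit(
            state.gamma0
            + state.v[data.cluster_index]
            + data.z_exposure @ state.gamma
        )
        np.testing.assert_allclose(p, pi, atol=1e-12)

    def test_degenerate_prior_pi_one_forces_one(self):
        rng = np.random.default_rng(8)
        data = _mini_dataset(rng, two_tests=False)
        state = _mini_state(rng, data)
        p = latent_x_full_conditional(data, state, "one_test", pi=1.0)
        np.testing.assert_allclose(p, 1.0)


class TestGibbsStep:
    def test_tiny_proposal_scales_freeze_metropolis_blocks(self):
        """With scales ~ 0, Metropolis blocks accept identical proposals and
        the continuous parameters stay put; latent x and S/C still move."""
        rng = np.random.default_rng(3)
        data = _mini_dataset(rng)
        state = _mini_state(rng, data)
        cfg = ChainConfig(
            adapt=False,
            proposal_scales={"beta": 1e-12, "gamma": 1e-12, "u": 1e-12,
                             "v": 1e-12, "log_sd": 1e-12},
        )
        new = gibbs_step(data, state, PriorSpec(), "two_test", cfg,
                         rng=np.random.default_rng(0))
        assert new.beta0 == pytest.approx(state.beta0, abs=1e-9)
        assert new.gamma0 == pytest.approx(state.gamma0, abs=1e-9)
        np.testing.assert_allclose(new.beta, state.beta, atol=1e-9)
        np.testing.assert_allclose(new.u, state.u, atol=1e-9)
        assert new.sigma == pytest.approx(state.sigma, abs=1e-9)
        assert new.nu == pytest.approx(state.nu, abs=1e-9)

    def test_sensitivity_update_matches_conjugate_beta(self):
        """With 10 exposed subjects (7 positive) and 20 concordant-negative
        unexposed subjects under flat priors, S1 | rest ~ beta(8, 4) up to a
        numerically negligible better-than-chance truncation (C1 | rest is
        beta(21, 1), so the bound 1 - C1 carries ~1e-9 of beta(8,4) mass)."""
        n = 30
        x_latent = np.array([1] * 10 + [0] * 20)
        x1 = np.array([1] * 7 + [0] * 3 + [0] * 20)
        data = Dataset(
            y=np.zeros(n, dtype=int),
            cluster=np.ones(n, dtype=int),
            z_outcome=np.zeros((n, 1)),
            z_exposure=np.zeros((n, 1)),
            x1=x1,
            x2=x_latent.copy(),
        )
        cfg = ChainConfig(adapt=False)
        mcmc = MCMC(data, PriorSpec(), Mode.TWO_TEST, cfg,
                    rng=np.random.default_rng(42))
        mcmc.x = x_latent.astype(float)  # condition on the latent state
        draws = np.empty(100_000)
        for t in range(draws.shape[0]):
            mcmc._update_sc()
            draws[t] = mcmc.S1
        # beta(8,4): mean 2/3, sd ~0.1307; MC error ~0.0004
        assert draws.mean() == pytest.approx(8 / 12, abs=0.002)
        assert draws.std() == pytest.approx(np.sqrt(8 * 4 / (12**2 * 13)), abs=0.002)

    def test_nonpositive_sc_counts_still_valid(self):
        # no exposed subjects at all: S draw falls back to the prior
        rng = np.random.default_rng(9)
        data = _mini_dataset(rng)
        cfg = ChainConfig(adapt=False)
        mcmc = MCMC(data, PriorSpec(s1_shape=(3, 2), c1_shape=(4, 2)),
                    Mode.TWO_TEST, cfg, rng=rng)
        mcmc.x = np.zeros(data.n_subjects)
        mcmc._update_sc()
        assert 0 < mcmc.S1 < 1 and 0 < mcmc.C1 < 1


class TestRunChain:
    def test_same_seed_is_bitwise_identical(self):
        rng = np.random.default_rng(1)
        data = _mini_dataset(rng, n=30, N=3)
        cfg = ChainConfig(n_iter=50, n_burn=20, seed=123)
        a = run_chain(data, PriorSpec(), "two_test", cfg)
        b = run_chain(data, PriorSpec(), "two_test", cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.names == b.names

    def test_different_seeds_differ(self):
        rng = np.random.default_rng(1)
        data = _mini_dataset(rng, n=30, N=3)
        a = run_chain(data, PriorSpec(), "naive", ChainConfig(50, 20, seed=1))
        b = run_chain(data, PriorSpec(), "naive", ChainConfig(50, 20, seed=2))
        assert not np.array_equal(a.draws, b.draws)

    def test_naive_intercept_only_recovers_sample_mean(self):
        """Single cluster, no covariates: posterior exp(beta0+u) matches the
        count sample mean within Monte Carlo error."""
        rng = np.random.default_rng(10)
        n = 400
        y = rng.poisson(3.0, n)
        data = Dataset(
            y=y,
            cluster=np.ones(n, dtype=int),
            z_outcome=np.zeros((n, 0)),
            z_exposure=np.zeros((n, 0)),
            x1=np.zeros(n, dtype=np.int8),
        )
        cfg = ChainConfig(n_iter=1500, n_burn=800, seed=4,
                          monitor_random_effects=True)
        sample = run_chain(data, PriorSpec(), "naive", cfg)
        # beta1 multiplies x1 = 0 everywhere; rate is exp(beta0 + u1)
        rate = np.exp(sample["beta0"] + sample["u1"])
        assert rate.mean() == pytest.approx(y.mean(), rel=0.05)

    def test_one_test_recovers_exposure_effect_on_simulated_data(self):
        """A one-test fit of simulated data recovers the generating exposure
        effect within two posterior SDs (small design for speed)."""
        design = SimDesign(N=10, n_per_cluster=150, seed=77)
        data = simulate_dataset(design)
        priors = PriorSpec(s1_shape=(10, 8), c1_shape=(165.7, 9.7))
        cfg = ChainConfig(n_iter=1200, n_burn=800, seed=5)
        sample = run_chain(data, priors, "one_test", cfg)
        summ = summarize(sample)
        mean, sd = summ.loc["beta1", "mean"], summ.loc["beta1", "sd"]
        assert abs(mean - 0.4) < 2 * sd

    def test_thinning_keeps_every_kth_draw(self):
        rng = np.random.default_rng(2)
        data = _mini_dataset(rng, n=20)
        cfg = ChainConfig(n_iter=40, n_burn=10, seed=9, thin=4)
        sample = run_chain(data, PriorSpec(), "naive", cfg)
        assert sample.draws.shape[0] == 10

    def test_two_test_requires_x2(self):
        rng = np.random.default_rng(2)
        data = _mini_dataset(rng, two_tests=False)
        with pytest.raises(MiscountError, match="x2"):
            run_chain(data, PriorSpec(), "two_test", ChainConfig(10, 5))

    def test_one_test_refuses_flat_sc_priors(self):
        rng = np.random.default_rng(2)
        data = _mini_dataset(rng, two_tests=False)
        with pytest.raises(MiscountError, match="identifiab"):
            run_chain(data, PriorSpec(), "one_test", ChainConfig(10, 5))


class TestNaiveCorrectedAgreement:
    def test_perfect_assessment_makes_models_agree(self):
        """On data with NO misclassification (x1 = x_true), the naive fit and
        a corrected fit with S/C priors concentrated near 1 give the same
        exposure effect within Monte Carlo error."""
        design = SimDesign(N=6, n_per_cluster=120, S1=1.0, C1=1.0, seed=21)
        data = simulate_dataset(design)
        cfg = ChainConfig(n_iter=1000, n_burn=600, seed=6)
        naive = summarize(run_chain(data, PriorSpec(), "naive", cfg))
        sharp = PriorSpec(s1_shape=(2000.0, 1.0), c1_shape=(2000.0, 1.0))
        corrected = summarize(run_chain(data, sharp, "one_test", cfg))
        diff = abs(naive.loc["beta1", "mean"] - corrected.loc["beta1", "mean"])
        mc = np.hypot(naive.loc["beta1", "sd"], corrected.loc["beta1", "sd"])
        assert diff < mc


class TestSummarize:
    def test_constant_chain(self):
        s = summarize(np.full(100, 2.5), names=["c"])
        assert s.loc["c", "mean"] == 2.5
        assert s.loc["c", "sd"] == 0.0
        assert s.loc["c", "q2.5"] == s.loc["c", "q97.5"] == 2.5

    def test_quantiles_match_order_statistics_oracle(self):
        draws = np.arange(1.0, 101.0)
        s = summarize(draws, names=["q"])
        # independent sort-and-interpolate oracle
        srt = np.sort(draws)
        for col, prob in (("q2.5", 0.025), ("q97.5", 0.975)):
            h = prob * (len(srt) - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            want = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
            assert s.loc["q", col] == pytest.approx(want, abs=1e-12)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        s = summarize(rng.standard_normal(100_000), names=["z"])
        assert s.loc["z", "q2.5"] == pytest.approx(-1.96, abs=0.03)
        assert s.loc["z", "q97.5"] == pytest.approx(1.96, abs=0.03)

    def test_empty_chain_errors(self):
        with pytest.raises(MiscountError, match="at least 2"):
            summarize(np.array([1.0]), names=["a"])


def _batch_means_se(x, n_batches=40):
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestGewekeJointDistribution:
    """'Getting it right': marginal moments of the parameters under
    (a) direct prior sampling and (b) the successive-conditional chain
    (sample data given state, then one posterior sweep) must agree."""

    def test_one_test_mini_model(self):
        rng = np.random.default_rng(314)
        N, n, q = 2, 10, 1
        cluster = np.repeat([1, 2], n // 2)
        z = rng.standard_normal((n, q))
        priors = PriorSpec(
            beta_var=0.25, gamma_var=0.25, sd_upper=0.5,
            s1_shape=(6.0, 3.0), c1_shape=(8.0, 2.0),
        )
        cl = cluster - 1

        def prior_draw(r):
            sigma = r.uniform(0, 0.5)
            nu = r.uniform(0, 0.5)
            return ParameterState(
                beta0=r.normal(0, 0.5),
                beta1=r.normal(0, 0.5),
                beta=r.normal(0, 0.5, q),
                u=r.normal(0, sigma, N),
                sigma=sigma,
                gamma0=r.normal(0, 0.5),
                gamma=r.normal(0, 0.5, q),
                v=r.normal(0, nu, N),
                nu=nu,
                S1=r.beta(6, 3),
                C1=r.beta(8, 2),
                x_latent=np.zeros(n, dtype=np.int8),
            )

        def gen_data(r, s):
            pi = expit(s.gamma0 + s.v[cl] + z @ s.gamma)
            x = (r.random(n) < pi).astype(np.int8)
            lam = np.exp(s.beta0 + s.u[cl] + s.beta1 * x + z @ s.beta)
            y = r.poisson(lam)
            p1 = np.where(x == 1, s.S1, 1 - s.C1)
            x1 = (r.random(n) < p1).astype(np.int8)
            return y, x1, x

        monitored = ["beta0", "beta1", "gamma0", "sigma", "nu", "S1", "C1"]

        # (a) direct prior draws
        M_prior = 40_000
        prior_vals = np.empty((M_prior, len(monitored)))
        for t in range(M_prior):
            s = prior_draw(rng)
            prior_vals[t] = [getattr(s, nm) for nm in monitored]

        # (b) successive-conditional chain
        s0 = prior_draw(rng)
        y0, x10, x0 = gen_data(rng, s0)
        data = Dataset(y=y0, cluster=cluster, z_outcome=z, z_exposure=z, x1=x10)
        cfg = ChainConfig(
            adapt=False,
            proposal_scales={"beta": 0.4, "gamma": 0.4, "u": 0.3,
                             "v": 0.3, "log_sd": 0.4},
        )
        mcmc = MCMC(data, priors, Mode.ONE_TEST, cfg, rng=rng, init=s0)
        mcmc.x = x0.astype(float)
        mcmc._refresh_caches()
        M_chain, burn = 24_000, 1_000
        chain_vals = np.empty((M_chain, len(monitored)))
        for t in range(M_chain + burn):
            s = mcmc.get_state()
            y, x1, x = gen_data(rng, s)
            mcmc.replace_observations(y, x1, x_latent=x)
            mcmc.sweep()
            if t >= burn:
                st = mcmc.get_state()
                chain_vals[t - burn] = [getattr(st, nm) for nm in monitored]

        for k, nm in enumerate(monitored):
            for power in (1, 2):
                a = prior_vals[:, k] ** power
                b = chain_vals[:, k] ** power
                se = np.sqrt(
                    (a.std(ddof=1) / np.sqrt(len(a))) ** 2
                    + _batch_means_se(b) ** 2
                )
                zscore = (a.mean() - b.mean()) / se
                assert abs(zscore) < 4.0, (
                    f"{nm}^{power}: prior {a.mean():.4f} vs chain {b.mean():.4f}"
                    f" (z = {zscore:.2f})"
                )

    def test_two_test_truncated_sc_updates(self):
        """Same joint-distribution check for the two-test kernel, whose S/C
        prior is restricted to the better-than-chance region S + C > 1."""
        rng = np.random.default_rng(2718)
        N, n, q = 2, 8, 1
        cluster = np.repeat([1, 2], n // 2)
        z = rng.standard_normal((n, q))
        priors = PriorSpec(
            beta_var=0.25, gamma_var=0.25, sd_upper=0.5,
            s1_shape=(4.0, 2.0), c1_shape=(5.0, 2.0),
            s2_shape=(3.0, 2.0), c2_shape=(4.0, 2.0),
        )
        cl = cluster - 1

        def draw_sc(r, s_shape, c_shape):
            while True:  # rejection sampling from the truncated prior
                s, c = r.beta(*s_shape), r.beta(*c_shape)
                if s + c > 1.0:
                    return s, c

        def prior_draw(r):
            sigma, nu = r.uniform(0, 0.5, 2)
            S1, C1 = draw_sc(r, (4, 2), (5, 2))
            S2, C2 = draw_sc(r, (3, 2), (4, 2))
            return ParameterState(
                beta0=r.normal(0, 0.5), beta1=r.normal(0, 0.5),
                beta=r.normal(0, 0.5, q),
                u=r.normal(0, sigma, N), sigma=sigma,
                gamma0=r.normal(0, 0.5), gamma=r.normal(0, 0.5, q),
                v=r.normal(0, nu, N), nu=nu,
                S1=S1, C1=C1, S2=S2, C2=C2,
                x_latent=np.zeros(n, dtype=np.int8),
            )

        def gen_data(r, s):
            pi = expit(s.gamma0 + s.v[cl] + z @ s.gamma)
            x = (r.random(n) < pi).astype(np.int8)
            lam = np.exp(s.beta0 + s.u[cl] + s.beta1 * x + z @ s.beta)
            y = r.poisson(lam)
            x1 = (r.random(n) < np.where(x == 1, s.S1, 1 - s.C1)).astype(np.int8)
            x2 = (r.random(n) < np.where(x == 1, s.S2, 1 - s.C2)).astype(np.int8)
            return y, x1, x2, x

        monitored = ["beta1", "gamma0", "S1", "C1", "S2", "C2"]
        M_prior = 40_000
        prior_vals = np.empty((M_prior, len(monitored)))
        for t in range(M_prior):
            s = prior_draw(rng)
            prior_vals[t] = [getattr(s, nm) for nm in monitored]

        s0 = prior_draw(rng)
        y0, x10, x20, x0 = gen_data(rng, s0)
        data = Dataset(y=y0, cluster=cluster, z_outcome=z, z_exposure=z,
                       x1=x10, x2=x20)
        cfg = ChainConfig(
            adapt=False,
            proposal_scales={"beta": 0.4, "gamma": 0.4, "u": 0.3,
                             "v": 0.3, "log_sd": 0.4},
        )
        mcmc = MCMC(data, priors, Mode.TWO_TEST, cfg, rng=rng, init=s0)
        mcmc.x = x0.astype(float)
        mcmc._refresh_caches()
        M_chain, burn = 20_000, 1_000
        chain_vals = np.empty((M_chain, len(monitored)))
        for t in range(M_chain + burn):
            s = mcmc.get_state()
            y, x1, x2, x = gen_data(rng, s)
            mcmc.replace_observations(y, x1, x2=x2, x_latent=x)
            mcmc.sweep()
            if t >= burn:
                st = mcmc.get_state()
                chain_vals[t - burn] = [getattr(st, nm) for nm in monitored]

        for k, nm in enumerate(monitored):
            for power in (1, 2):
                a = prior_vals[:, k] ** power
                b = chain_vals[:, k] ** power
                se = np.sqrt(
                    (a.std(ddof=1) / np.sqrt(len(a))) ** 2
                    + _batch_means_se(b) ** 2
                )
                zscore = (a.mean() - b.mean()) / se
                assert abs(zscore) < 4.0, (
                    f"{nm}^{power}: prior {a.mean():.4f} vs chain {b.mean():.4f}"
                    f" (z = {zscore:.2f})"
                )
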