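"""Sampler correctness: enumeration oracles, conjugacy, prior recovery."""

import numpy as np
import pytest
from scipy import stats

from sdpgwr import AreaGraph, ChainConfig, Dataset, ModelConfig, StickConfig, run_chain
from sdpgwr.mcmc import (_StickTarget, update_assignments,
                         update_regression_blocks, update_stick_blocks)
from sdpgwr.model import ModelState, cluster_prior_weights
from sdpgwr.stick import StickState, UnitScaler


def _line_dataset(n, p, seed=0):
    rng = np.random.default_rng(seed)
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    graph = AreaGraph([f"a{i}" for i in range(n)], coords,
                      {(i, i + 1) for i in range(n - 1)})
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return Dataset(y=y, X=X, graph=graph)


def _state(n, p, K, rng, kernel="squared_exponential"):
    cfg = StickConfig(truncation_K=K, knots=K, kernel_kind=kernel)
    stick = StickState(V=rng.uniform(0.3, 0.7, K),
                       knots=rng.uniform(0, 1, (K, 2)),
                       eps=np.full((K, 2), 0.4), config=cfg)
    return ModelState(z=rng.integers(0, K, n),
                      beta=rng.standard_normal((K, p)),
                      mu=np.zeros((K, p)), Sigma=np.tile(np.eye(p), (K, 1, 1)),
                      sigma2=rng.uniform(0.5, 2.0, n), b=5.0, stick=stick)


class TestAssignments:
    def test_single_cluster_always_assigned(self):
        rng = np.random.default_rng(0)
        data = _line_dataset(4, 2)
        state = _state(4, 2, 1, rng)
        z = update_assignments(state, data, np.ones((4, 4)), rng,
                               mode="plain", prior_p=np.ones((4, 1)))
        assert np.all(z == 0)

    def test_equal_likelihood_reduces_to_prior(self):
        """With identical coefficients in every cluster the conditional is
        the stick prior; empirical frequencies match p_k(s) within 3 s.e."""
        rng = np.random.default_rng(1)
        data = _line_dataset(3, 2)
        state = _state(3, 2, 2, rng)
        state.beta[1] = state.beta[0]
        prior_p = np.array([[0.3, 0.7], [0.5, 0.5], [0.9, 0.1]])
        M = 40_000
        counts = np.zeros((3, 2))
        for _ in range(M):
            z = update_assignments(state, data, np.ones((3, 3)), rng,
                                   mode="plain", prior_p=prior_p)
            counts[np.arange(3), z] += 1
        freq = counts / M
        se = np.sqrt(prior_p * (1 - prior_p) / M)
        assert np.all(np.abs(freq - prior_p) < 3 * se + 1e-9)

    def test_matches_exhaustive_enumeration(self):
        """n=3, K=2: empirical conditional frequencies over 10^5 sweeps match
        the exactly enumerated categorical conditionals (independent oracle
        via direct normal-density arithmetic)."""
        rng = np.random.default_rng(2)
        data = _line_dataset(3, 1, seed=5)
        state = _state(3, 1, 2, rng)
        prior_p = np.array([[0.4, 0.6], [0.5, 0.5], [0.2, 0.8]])

        exact = np.zeros((3, 2))
        for i in range(3):
            for k in range(2):
                exact[i, k] = prior_p[i, k] * stats.norm.pdf(
                    data.y[i], data.X[i] @ state.beta[k], np.sqrt(state.sigma2[i]))
            exact[i] /= exact[i].sum()

        M = 100_000
        counts = np.zeros((3, 2))
        for _ in range(M):
            z = update_assignments(state, data, np.ones((3, 3)), rng,
                                   mode="plain", prior_p=prior_p)
            counts[np.arange(3), z] += 1
        freq = counts / M
        se = np.sqrt(exact * (1 - exact) / M)
        assert np.all(np.abs(freq - exact) < 3 * se + 1e-9)

    def test_zero_prior_mass_never_sampled(self):
        rng = np.random.default_rng(3)
        data = _line_dataset(3, 1)
        state = _state(3, 1, 2, rng)
        prior_p = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        for _ in range(50):
            z = update_assignments(state, data, np.ones((3, 3)), rng,
                                   mode="plain", prior_p=prior_p)
            assert np.all(z == 1)


class TestRegressionBlocks:
    def _beta_conditional_mean(self, data, state, config, weights, n_draws=4000):
        """Monte-Carlo mean of the beta_0 full conditional (fresh rngs,
        identical entering state)."""
        draws = np.empty((n_draws, data.p))
        for s in range(n_draws):
            st = state.copy()
            update_regression_blocks(st, data, weights,
                                     np.random.default_rng(1000 + s), config)
            draws[s] = st.beta[0]
        return draws.mean(axis=0), draws.std(axis=0, ddof=1) / np.sqrt(n_draws)

    def test_vague_prior_limit_recovers_wls(self):
        """With a nearly flat prior the conditional mean of beta_k is the
        weighted least-squares solution on its cluster (independent oracle)."""
        rng = np.random.default_rng(4)
        data = _line_dataset(12, 2, seed=7)
        state = _state(12, 2, 1, rng)
        state.z[:] = 0
        state.Sigma[0] = 1e6 * np.eye(2)
        state.mu[0] = 0.0
        cfg = ModelConfig(p=2, likelihood_mode="plain",
                          stick=state.stick.config)
        A = np.diag(1.0 / state.sigma2)
        wls = np.linalg.solve(data.X.T @ A @ data.X, data.X.T @ A @ data.y)
        mean, se = self._beta_conditional_mean(data, state, cfg, np.ones((12, 12)))
        assert np.all(np.abs(mean - wls) < 4 * se + 1e-3)

    def test_posterior_mean_between_prior_and_wls_diagonal(self):
        rng = np.random.default_rng(5)
        n = 10
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        graph = AreaGraph(list(range(n)), coords, set())
        X = np.ones((n, 1))
        y = np.full(n, 3.0)
        data = Dataset(y=y, X=X, graph=graph)
        state = _state(n, 1, 1, rng)
        state.z[:] = 0
        state.sigma2[:] = 1.0
        state.mu[0] = np.array([0.0])
        state.Sigma[0] = np.array([[1.0]])
        cfg = ModelConfig(p=1, likelihood_mode="plain", stick=state.stick.config)
        mean, se = self._beta_conditional_mean(data, state, cfg, np.ones((n, n)))
        # exact conjugate mean: (1 + n)^-1 (0 + n*3)
        exact = n * 3.0 / (1 + n)
        assert abs(mean[0] - exact) < 4 * se[0]
        assert 0.0 < mean[0] < 3.0

    def test_zero_weight_area_has_no_influence(self):
        rng = np.random.default_rng(6)
        data = _line_dataset(5, 2, seed=9)
        state = _state(5, 2, 1, rng)
        state.z[:] = 0
        cfg = ModelConfig(p=2, likelihood_mode="composite", stick=state.stick.config)
        W = np.ones((5, 5))
        W[:, 4] = 0.0       # area 4 never contributes to any local likelihood
        st1 = state.copy()
        update_regression_blocks(st1, data, W, np.random.default_rng(77), cfg)
        y2 = data.y.copy()
        y2[4] = 99.0
        data2 = Dataset(y=y2, X=data.X, graph=data.graph)
        st2 = state.copy()
        update_regression_blocks(st2, data2, W, np.random.default_rng(77), cfg)
        np.testing.assert_allclose(st1.beta[0], st2.beta[0])


class _PriorOnlyTarget(_StickTarget):
    """Stick target with the data term removed: the conditionals reduce to
    the priors, so MH must recover them (detailed-balance check)."""

    def assigned_logmass(self, stick, z):
        return 0.0

    def logmass_with(self, L, V, z):
        return 0.0


class TestStickBlocks:
    def _run(self, kernel, bandwidth_prior, sweeps=4000, seed=11):
        rng = np.random.default_rng(seed)
        data = _line_dataset(4, 1)
        scfg = StickConfig(truncation_K=3, knots=2, kernel_kind=kernel,
                           bandwidth_prior=bandwidth_prior, lam=0.5)
        cfg = ModelConfig(p=1, likelihood_mode="plain", a_v=2.0, b_v=3.0,
                          D=20.0, stick=scfg)
        state = _state(4, 1, 3, rng)
        state.stick.config = scfg
        state.stick.V = rng.beta(2.0, 3.0, 3)
        state.stick.knots = rng.uniform(0, 1, (2, 2))
        state.stick.eps = np.full((2, 2), 0.4)
        target = _PriorOnlyTarget(data, cfg, UnitScaler(data.coords))
        scales = {"V": 1.0, "knots": 0.3, "eps": 0.5, "b": 4.0}
        W = np.ones((4, 4))
        dist = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        Vs, bs, knots = [], [], []
        for _ in range(sweeps):
            acc = {k: [] for k in scales}
            W = update_stick_blocks(state, data, rng, config=cfg, chain=None,
                                    target=target, distances=dist, weights=W,
                                    scales=scales, accepts=acc)
            Vs.append(state.stick.V.copy())
            bs.append(state.b)
            knots.append(state.stick.knots.copy())
            assert np.all((state.stick.V > 0) & (state.stick.V < 1))
            assert np.all((state.stick.knots >= 0) & (state.stick.knots <= 1))
            assert 0 < state.b < cfg.D
            assert np.all(state.stick.eps > 0)
        return np.array(Vs), np.array(bs), np.array(knots)

    def test_prior_recovery_without_likelihood(self):
        """With the data term switched off, the MH blocks must leave the
        priors invariant: V ~ Beta(2,3), knots ~ U(0,1), b ~ U(0,20)."""
        Vs, bs, knots = self._run("squared_exponential", "fixed_lambda_sq_half")
        assert Vs.mean() == pytest.approx(2.0 / 5.0, abs=0.04)
        assert knots.mean() == pytest.approx(0.5, abs=0.06)
        assert bs.mean() == pytest.approx(10.0, abs=1.5)

    def test_random_bandwidths_stay_positive_and_move(self):
        rng = np.random.default_rng(12)
        data = _line_dataset(4, 1)
        scfg = StickConfig(truncation_K=3, knots=2, kernel_kind="uniform",
                           bandwidth_prior="exp_lambda", lam=0.5)
        cfg = ModelConfig(p=1, likelihood_mode="plain", stick=scfg)
        state = _state(4, 1, 3, rng)
        state.stick.config = scfg
        state.stick.knots = rng.uniform(0, 1, (2, 2))
        state.stick.eps = np.full((2, 2), 0.5)
        target = _PriorOnlyTarget(data, cfg, UnitScaler(data.coords))
        scales = {"V": 1.0, "knots": 0.3, "eps": 0.5, "b": 4.0}
        dist = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        start = state.stick.eps.copy()
        W = np.ones((4, 4))
        for _ in range(200):
            acc = {k: [] for k in scales}
            W = update_stick_blocks(state, data, rng, config=cfg, chain=None,
                                    target=target, distances=dist, weights=W,
                                    scales=scales, accepts=acc)
        assert np.all(state.stick.eps > 0)
        assert not np.allclose(state.stick.eps, start)


class TestRunChain:
    def test_default_retention_count(self):
        assert ChainConfig().n_retained == 8000

    def test_same_seed_bit_identical(self):
        data = _line_dataset(8, 2, seed=3)
        cfg = ModelConfig(p=2, stick=StickConfig(truncation_K=4, knots=2))
        chain = ChainConfig(n_iter=120, burn_in=40, seed=99, progress_every=0)
        s1 = run_chain(data, cfg, chain)
        s2 = run_chain(data, cfg, chain)
        np.testing.assert_array_equal(s1.z, s2.z)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.b, s2.b)
        np.testing.assert_array_equal(s1.loglik, s2.loglik)

    def test_retained_shapes_and_thinning(self):
        data = _line_dataset(6, 1, seed=4)
        cfg = ModelConfig(p=1, stick=StickConfig(truncation_K=3, knots=3))
        chain = ChainConfig(n_iter=100, burn_in=20, thin=4, seed=5,
                            progress_every=0)
        s = run_chain(data, cfg, chain)
        assert s.n_draws == 20
        assert s.loglik.shape == (20, 6)
        assert s.beta.shape == (20, 3, 1)

    def test_k1_posterior_matches_conjugate_closed_form(self):
        """K=1 plain chain: the posterior mean of beta approaches the
        Bayesian weighted-regression closed form with sigma^2 integrated
        over its draws; checked with fixed, well-identified variance."""
        rng = np.random.default_rng(13)
        n = 40
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        graph = AreaGraph(list(range(n)), coords,
                          {(i, i + 1) for i in range(n - 1)})
        X = rng.standard_normal((n, 1))
        beta_true = np.array([2.0])
        y = X @ beta_true + 0.3 * rng.standard_normal(n)
        data = Dataset(y=y, X=X, graph=graph)
        cfg = ModelConfig(p=1, likelihood_mode="plain",
                          stick=StickConfig(truncation_K=1, knots=1))
        chain = ChainConfig(n_iter=3000, burn_in=500, seed=21, progress_every=0)
        s = run_chain(data, cfg, chain)
        # vague-ish check: with n large the posterior concentrates on OLS
        ols = float(np.linalg.lstsq(X, y, rcond=None)[0][0])
        assert s.beta[:, 0, 0].mean() == pytest.approx(ols, abs=0.05)

    def test_invalid_chain_config(self):
        with pytest.raises(ValueError, match="burn_in"):
            ChainConfig(n_iter=100, burn_in=100)

    def test_acceptance_rates_reported_in_range(self):
        data = _line_dataset(10, 2, seed=6)
        cfg = ModelConfig(p=2, stick=StickConfig(truncation_K=4, knots=2))
        chain = ChainConfig(n_iter=400, burn_in=200, seed=7, progress_every=0)
        s = run_chain(data, cfg, chain)
        for key in ("V", "knots", "b"):
            assert s.acceptance[key] is None or 0.0 <= s.acceptance[key] <= 1.0


class TestInvWishartSampler:
    def test_moments_match_closed_forms(self):
        """Bartlett-decomposition draws reproduce the closed-form mean
        S/(df-p-1) and diagonal variance 2 S_ii^2/((df-p-1)^2 (df-p-3))."""
        from sdpgwr.mcmc import _sample_invwishart
        rng = np.random.default_rng(0)
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        df, p = 15.0, 2
        draws = np.stack([_sample_invwishart(df, S, rng) for _ in range(20000)])
        np.testing.assert_allclose(draws.mean(axis=0), S / (df - p - 1),
                                   atol=0.005)
        var00 = 2 * S[0, 0] ** 2 / ((df - p - 1) ** 2 * (df - p - 3))
        assert draws[:, 0, 0].var() == pytest.approx(var00, rel=0.1)


class TestJointDistribution:
    def test_successive_conditional_simulator_matches_prior(self):
        """Geweke-style check on a 5-area, K=2 toy: alternating a Gibbs
        sweep with re-simulation of the data from the likelihood leaves the
        prior marginals of V and the knots invariant."""
        rng = np.random.default_rng(30)
        n, p, K = 5, 1, 2
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        graph = AreaGraph(list(range(n)), coords,
                          {(i, i + 1) for i in range(n - 1)})
        scfg = StickConfig(truncation_K=K, knots=K)
        cfg = ModelConfig(p=p, likelihood_mode="plain", a_v=2.0, b_v=2.0,
                          alpha1=3.0, alpha2=2.0, stick=scfg)
        X = rng.standard_normal((n, p))

        state = _state(n, p, K, rng)
        state.stick.config = scfg
        state.sigma2 = stats.invgamma.rvs(3.0, scale=2.0, size=n, random_state=rng)
        target = _StickTarget(
            Dataset(y=np.zeros(n), X=X, graph=graph), cfg,
            UnitScaler(coords))
        scales = {"V": 1.2, "knots": 0.4, "eps": 0.5, "b": 30.0}
        dist = np.abs(np.subtract.outer(np.arange(float(n)), np.arange(float(n))))
        W = np.ones((n, n))
        Vs, ks = [], []
        from sdpgwr.mcmc import update_assignments as upd_z
        from sdpgwr.model import cluster_prior_weights
        for t in range(6000):
            y = np.einsum("ij,ij->i", X, state.beta[state.z]) \
                + np.sqrt(state.sigma2) * rng.standard_normal(n)
            data = Dataset(y=y, X=X, graph=graph)
            prior_p = cluster_prior_weights(state, data)
            state.z = upd_z(state, data, W, rng, mode="plain", prior_p=prior_p)
            update_regression_blocks(state, data, W, rng, cfg)
            acc = {k: [] for k in scales}
            W = update_stick_blocks(state, data, rng, config=cfg, chain=None,
                                    target=_StickTarget(data, cfg, UnitScaler(coords)),
                                    distances=dist, weights=W, scales=scales,
                                    accepts=acc)
            if t >= 1000:
                Vs.append(state.stick.V.copy())
                ks.append(state.stick.knots.copy())
        Vs, ks = np.array(Vs), np.array(ks)
        # prior: V ~ Beta(2,2) mean .5; knots ~ U(0,1)^2 mean .5
        assert Vs.mean() == pytest.approx(0.5, abs=0.05)
        assert ks.mean() == pytest.approx(0.5, abs=0.05)
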