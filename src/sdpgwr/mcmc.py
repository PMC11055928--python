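"""Blocked Gibbs / Metropolis-Hastings sampler for the clustered GWR model.

One sweep updates, in order:

1. cluster assignments z_i from their categorical full conditionals
   (spatial stick-breaking prior times the local likelihood);
2. the regression blocks: beta_k from its multivariate-normal full
   conditional, (mu_k, Sigma_k) from the conjugate Normal-Inverse-Wishart
   update, sigma^2(s_i) from its Inverse-Gamma full conditional;
3. the stick blocks: stick fractions V_k, knots psi, kernel bandwidths
   eps (when their prior is not degenerate) via random-walk
   Metropolis-Hastings, and the GWR bandwidth b via random walk on (0, D).

Proposal scales adapt toward a 0.3 acceptance rate during burn-in only
(Robbins-Monro), keeping the retained chain Markovian.  All randomness
flows from a single seed through ``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .graph import (euclidean_distance_matrix, graph_distance_matrix,
                    great_circle_distance_matrix, gwr_weights)
from .model import (Dataset, ModelConfig, ModelState, composite_loglik_parts,
                    pointwise_loglik, total_loglik)
from .stick import (StickState, UnitScaler, bandwidth_is_fixed, kernel_matrix,
                    sample_bandwidths, sample_stick_prior, stick_weights)

logger = logging.getLogger(__name__)

TARGET_ACCEPT = 0.3


@dataclass
class ChainConfig:
    """MCMC run-length and proposal settings.

    The defaults follow the study design this model was developed under:
    chains of 10,000 sweeps with the first 2,000 discarded as burn-in,
    leaving 8,000 draws for posterior inference.
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    adapt: bool = True
    scale_V: float = 0.8          # logit-scale random walk
    scale_knots: float = 0.1      # unit-square random walk
    scale_eps: float = 0.4        # log-scale random walk
    scale_b: float = 5.0          # bandwidth random walk (data scale)
    progress_every: int = 500

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws plus per-draw pointwise log-likelihoods."""

    z: np.ndarray                 # (M, n) int labels in 0..K-1
    beta: np.ndarray              # (M, K, p)
    mu: np.ndarray                # (M, K, p)
    Sigma: np.ndarray             # (M, K, p, p)
    sigma2: np.ndarray            # (M, n)
    b: np.ndarray                 # (M,)
    V: np.ndarray                 # (M, K)
    knots: np.ndarray             # (M, n_knots, 2)
    eps: np.ndarray               # (M, n_knots, 2)
    loglik: np.ndarray            # (M, n) plain-mode pointwise log-likelihood
    acceptance: dict = field(default_factory=dict)
    seed: int | None = None
    likelihood_mode: str = "composite"

    @property
    def n_draws(self) -> int:
        return self.z.shape[0]

    @property
    def n_areas(self) -> int:
        return self.z.shape[1]


def _distance_matrix(data: Dataset, config: ModelConfig) -> np.ndarray:
    if config.distance_metric == "graph":
        return graph_distance_matrix(data.graph)
    if config.distance_metric == "great_circle":
        return great_circle_distance_matrix(data.coords)
    return euclidean_distance_matrix(data.coords)


def _gumbel_argmax(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical index per row of a (possibly -inf) log matrix."""
    g = rng.gumbel(size=logp.shape)
    return np.argmax(np.where(np.isfinite(logp), logp + g, -np.inf), axis=1)


def update_assignments(state: ModelState, data: Dataset, weights: np.ndarray,
                       rng: np.random.Generator, *, mode: str,
                       prior_p: np.ndarray) -> np.ndarray:
    """One sweep of the categorical full conditional for every z_i.

    The conditional mass of cluster k at area i is proportional to
    p_k(s_i) times the (local) likelihood of the data under beta_k;
    normalization happens in log space so underflow never yields NaN.
    """
    if mode != "plain":
        _, S = composite_loglik_parts(data, state.beta, weights)
        ll = -S / (2.0 * state.sigma2[:, None])
    else:
        resid = data.y[:, None] - data.X @ state.beta.T
        ll = -resid ** 2 / (2.0 * state.sigma2[:, None])
    with np.errstate(divide="ignore"):
        logp = np.log(prior_p) + ll
    return _gumbel_argmax(logp, rng)


def _sample_invwishart(df: float, scale: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition Inverse-Wishart draw (scale parameterization).

    X ~ IW(df, S) via X = W^{-1}, W ~ Wishart(df, S^{-1}).
    """
    p = scale.shape[0]
    T = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    idx = np.tril_indices(p, k=-1)
    A[idx] = rng.standard_normal(idx[0].size)
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    M = T @ A                                  # chol factor of W
    Minv = np.linalg.inv(np.tril(M))
    return Minv.T @ Minv


def update_regression_blocks(state: ModelState, data: Dataset,
                             weights: np.ndarray, rng: np.random.Generator,
                             config: ModelConfig) -> ModelState:
    """Conjugate updates for beta_k, (mu_k, Sigma_k) and sigma^2(s)."""
    n, p, K = data.n, data.p, config.K
    X, y = data.X, data.y
    inv_s2 = 1.0 / state.sigma2

    for k in range(K):
        members = state.z == k
        if config.likelihood_mode != "plain":
            # a_j = sum_{i: z_i = k} w_ij / sigma^2_i
            a = weights[members].T @ inv_s2[members] if members.any() else np.zeros(n)
        else:
            a = np.where(members, inv_s2, 0.0)
        Sigma_inv = np.linalg.inv(state.Sigma[k])
        prec = Sigma_inv + (X * a[:, None]).T @ X
        h = Sigma_inv @ state.mu[k] + X.T @ (a * y)
        try:
            L = np.linalg.cholesky(prec)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular full-conditional precision for cluster {k}; "
                "check for collinear covariates or degenerate weights"
            ) from err
        mean = np.linalg.solve(prec, h)
        state.beta[k] = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        # Normal-Inverse-Wishart update from the single observation beta_k
        d = state.beta[k] - config.m
        D_n = config.D_scale + 0.5 * np.outer(d, d)
        c_n = config.c + 1
        state.Sigma[k] = _sample_invwishart(c_n, D_n, rng)
        mu_n = 0.5 * (config.m + state.beta[k])
        Lk = np.linalg.cholesky(state.Sigma[k] / 2.0)
        state.mu[k] = mu_n + Lk @ rng.standard_normal(p)

    # sigma^2(s_i) | rest ~ InverseGamma(alpha1 + n_i/2, alpha2 + ssr_i/2)
    # where n_i is the local effective sample size: sum_j w_ij under the
    # weighted log-likelihood, the count of positive weights under the
    # density form, and 1 in plain mode
    if config.likelihood_mode != "plain":
        E2, S = composite_loglik_parts(data, state.beta, weights)
        if config.likelihood_mode == "composite":
            n_i = weights.sum(axis=1)
        else:
            n_i = (weights > 0).sum(axis=1)
        ssr = S[np.arange(n), state.z]
    else:
        resid = y - np.einsum("ij,ij->i", X, state.beta[state.z])
        n_i = np.ones(n)
        ssr = resid ** 2
    if config.variance_mode == "shared":
        # one pooled variance: a single IG conditional over all areas
        shape = config.alpha1 + 0.5 * float(np.sum(n_i))
        rate = config.alpha2 + 0.5 * float(np.sum(ssr))
        state.sigma2 = np.full(n, rate / rng.gamma(shape))
    else:
        shape = config.alpha1 + 0.5 * n_i
        rate = config.alpha2 + 0.5 * ssr
        state.sigma2 = rate / rng.gamma(shape)
    return state


class _StickTarget:
    """Log target pieces for the stick-block MH moves at fixed z.

    The kernel matrix is the expensive ingredient, so moves maintain it
    incrementally: a knot (or bandwidth) proposal touches only the columns
    of the sticks mapped to that knot, and V or swap proposals reuse it
    unchanged.
    """

    def __init__(self, data: Dataset, config: ModelConfig, scaler: UnitScaler):
        self.config = config
        self.coords01 = scaler.transform(data.coords)

    def kernels(self, stick: StickState) -> np.ndarray:
        return kernel_matrix(self.coords01, stick)

    def kernel_column(self, knot: np.ndarray, eps: np.ndarray) -> np.ndarray:
        """Kernel values of one knot at every area (shared by its sticks)."""
        diff = self.coords01 - knot[None, :]
        if self.config.stick.kernel_kind == "uniform":
            return (np.abs(diff) < eps[None, :] / 2.0).all(axis=1).astype(float)
        return np.exp(-(diff ** 2) / (2.0 * eps[None, :] ** 2)).prod(axis=1)

    def logmass_with(self, L: np.ndarray, V: np.ndarray, z: np.ndarray) -> float:
        p = stick_weights(V, L)
        mass = p[np.arange(z.shape[0]), z]
        if np.any(mass <= 0):
            return -np.inf
        return float(np.log(mass).sum())

    def assigned_logmass(self, stick: StickState, z: np.ndarray) -> float:
        return self.logmass_with(self.kernels(stick), stick.V, z)


def _beta_logpdf(v: float, a: float, b: float) -> float:
    from scipy.special import betaln
    return (a - 1.0) * np.log(v) + (b - 1.0) * np.log1p(-v) - betaln(a, b)


def _eps_logprior(eps: np.ndarray, config) -> float:
    """Fast log prior of one knot's bandwidth pair (random kinds only)."""
    from scipy.special import gammaln
    lam = config.lam
    if config.bandwidth_prior == "exp_lambda":
        return float(-np.sum(eps) / lam - 2.0 * np.log(lam))
    a, scale = 1.5, lam ** 2 / 2.0
    return float(np.sum(a * np.log(scale) - gammaln(a)
                        - (a + 1.0) * np.log(eps) - scale / eps))


def update_stick_blocks(state: ModelState, data: Dataset, rng: np.random.Generator,
                        *, config: ModelConfig, chain: ChainConfig,
                        target: _StickTarget, distances: np.ndarray,
                        weights: np.ndarray, scales: dict, accepts: dict):
    """MH updates for V, knots, kernel bandwidths, and the GWR bandwidth b.

    Rejected proposals keep the current state; every move is either a
    symmetric random walk on a transformed scale (with the matching
    Jacobian correction) or an independence refresh from the prior, so
    detailed balance holds per block.  Returns the (possibly refreshed)
    GWR weight matrix.
    """
    st = state.stick
    for key in ("V", "knots", "eps", "b", "swap"):
        accepts.setdefault(key, [])

    L = target.kernels(st)
    cur_mass = target.logmass_with(L, st.V, state.z)
    kmap = st.config.knot_of_stick()
    a_v, b_v = config.a_v, config.b_v

    # stick fractions: logit-scale random walk mixed with an occasional
    # independence refresh from the Beta prior (the prior cancels against
    # the proposal density, helping escape local stick geometries)
    for k in range(st.V.shape[0]):
        old = float(st.V[k])
        if rng.random() < 0.2:
            v_new = float(rng.beta(a_v, b_v))
            if not 0.0 < v_new < 1.0:
                accepts["V"].append(0)
                continue
            log_corr = 0.0          # prior proposal: Beta factors cancel
        else:
            v_new = float(expit(logit(old) + scales["V"] * rng.standard_normal()))
            if not 0.0 < v_new < 1.0:
                accepts["V"].append(0)
                continue
            log_corr = (_beta_logpdf(v_new, a_v, b_v) - _beta_logpdf(old, a_v, b_v)
                        + np.log(v_new * (1 - v_new)) - np.log(old * (1 - old)))
        st.V[k] = v_new
        new_mass = target.logmass_with(L, st.V, state.z)
        if np.log(rng.random()) < new_mass - cur_mass + log_corr:
            cur_mass = new_mass
            accepts["V"].append(1)
        else:
            st.V[k] = old
            accepts["V"].append(0)

    # knots: random walk in the unit square (uniform prior -> reject
    # outside), mixed with an occasional uniform independence refresh so a
    # knot can jump across the domain to a better-supported region
    for k in range(st.knots.shape[0]):
        old = st.knots[k].copy()
        if rng.random() < 0.2:
            prop = rng.uniform(0.0, 1.0, 2)
        else:
            prop = old + scales["knots"] * rng.standard_normal(2)
        if np.any((prop < 0.0) | (prop > 1.0)):
            accepts["knots"].append(0)
            continue
        cols = kmap == k
        col = target.kernel_column(prop, st.eps[k])
        L_new = L.copy()
        L_new[:, cols] = col[:, None]
        new_mass = target.logmass_with(L_new, st.V, state.z)
        if np.log(rng.random()) < new_mass - cur_mass:
            st.knots[k] = prop
            L, cur_mass = L_new, new_mass
            accepts["knots"].append(1)
        else:
            accepts["knots"].append(0)

    # kernel bandwidths: log-scale random walk (skipped for fixed priors)
    if not bandwidth_is_fixed(st.config.bandwidth_prior):
        for k in range(st.eps.shape[0]):
            old = st.eps[k].copy()
            prop = old * np.exp(scales["eps"] * rng.standard_normal(2))
            cols = kmap == k
            col = target.kernel_column(st.knots[k], prop)
            L_new = L.copy()
            L_new[:, cols] = col[:, None]
            new_mass = target.logmass_with(L_new, st.V, state.z)
            log_corr = (_eps_logprior(prop, st.config) - _eps_logprior(old, st.config)
                        + float(np.log(prop).sum() - np.log(old).sum()))
            if np.log(rng.random()) < new_mass - cur_mass + log_corr:
                st.eps[k] = prop
                L, cur_mass = L_new, new_mass
                accepts["eps"].append(1)
            else:
                accepts["eps"].append(0)

    # stick-swap move: exchange (beta, mu, Sigma) between two sticks and
    # relabel their assignments.  The likelihood and the exchangeable
    # base-measure prior cancel, so acceptance depends only on the spatial
    # assignment mass -- this lets a coefficient cluster migrate to a stick
    # whose kernel footprint matches its region (a standard label-mixing
    # move for truncated stick-breaking samplers).
    K = st.V.shape[0]
    if K >= 2:
        for _ in range(max(2, K // 4)):
            j, k = rng.choice(K, size=2, replace=False)
            z_new = state.z.copy()
            z_new[state.z == j] = k
            z_new[state.z == k] = j
            new_mass = target.logmass_with(L, st.V, z_new)
            if np.log(rng.random()) < new_mass - cur_mass:
                state.z = z_new
                for arr in (state.beta, state.mu, state.Sigma):
                    arr[[j, k]] = arr[[k, j]]
                cur_mass = new_mass
                accepts["swap"].append(1)
            else:
                accepts["swap"].append(0)

    # GWR bandwidth b: random walk on (0, D) against the weighted likelihood
    b_new = state.b + scales["b"] * rng.standard_normal()
    if 0.0 < b_new < config.D:
        if config.likelihood_mode == "plain":
            # the plain likelihood does not involve W: the conditional is the
            # Uniform(0, D) prior and any in-support move is accepted
            state.b = b_new
            weights = gwr_weights(distances, state.b, config.weight_threshold)
            accepts["b"].append(1)
        else:
            w_new = gwr_weights(distances, b_new, config.weight_threshold)
            cur_ll = total_loglik(state, data, weights, config.likelihood_mode)
            new_ll = total_loglik(state, data, w_new, config.likelihood_mode)
            if np.log(rng.random()) < new_ll - cur_ll:
                state.b = b_new
                weights = w_new
                accepts["b"].append(1)
            else:
                accepts["b"].append(0)
    else:
        accepts["b"].append(0)
    return weights


def _warm_start(data: Dataset, config: ModelConfig, distances: np.ndarray,
                rng: np.random.Generator) -> ModelState:
    """Initial state: z from k-means on per-area ridge WLS coefficients,
    everything else from the priors (variances from initial residuals)."""
    from sklearn.cluster import KMeans

    n, p, K = data.n, data.p, config.K
    X, y = data.X, data.y
    w_local = gwr_weights(distances, 1.0, config.weight_threshold)
    coefs = np.empty((n, p))
    for i in range(n):
        w = w_local[i]
        A = (X * w[:, None]).T @ X
        A += 1e-2 * (np.trace(A) / p + 1e-12) * np.eye(p)
        coefs[i] = np.linalg.solve(A, X.T @ (w * y))

    k_init = min(3, K)
    km = KMeans(n_clusters=k_init, n_init=5,
                random_state=int(rng.integers(2 ** 31)))
    labels = km.fit_predict(coefs)

    stick = sample_stick_prior(config.stick, rng)
    Sigma = stats.invwishart.rvs(df=config.c, scale=config.D_scale,
                                 size=K, random_state=rng).reshape(K, p, p)
    mu = np.empty((K, p))
    beta = np.empty((K, p))
    for k in range(K):
        Lk = np.linalg.cholesky(Sigma[k])
        mu[k] = config.m + Lk @ rng.standard_normal(p)
        beta[k] = mu[k] + Lk @ rng.standard_normal(p)
    beta[:k_init] = km.cluster_centers_

    resid = y - np.einsum("ij,ij->i", X, beta[labels])
    s2 = max(float(np.mean(resid ** 2)), 1e-6)
    state = ModelState(
        z=labels.astype(int), beta=beta, mu=mu, Sigma=Sigma,
        sigma2=np.full(n, s2), b=float(rng.uniform(0, config.D)), stick=stick,
    )
    if config.likelihood_mode != "plain":
        # profile the composite likelihood at the warm start to place b in
        # a well-supported region; the random walk refines it from there
        best_b, best_ll = state.b, -np.inf
        for b_try in np.geomspace(0.2, config.D * 0.999, 25):
            w_try = gwr_weights(distances, b_try, config.weight_threshold)
            ll = total_loglik(state, data, w_try, config.likelihood_mode)
            if ll > best_ll:
                best_b, best_ll = float(b_try), ll
        state.b = best_b
    return state


def run_chain(data: Dataset, model_config: ModelConfig,
              chain_config: ChainConfig) -> PosteriorSamples:
    """Run the blocked sampler and return the retained posterior draws."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(chain_config.seed)))
    cfg, chain = model_config, chain_config
    n, p, K = data.n, data.p, cfg.K

    distances = _distance_matrix(data, cfg)
    scaler = UnitScaler(data.coords)
    target = _StickTarget(data, cfg, scaler)

    state = _warm_start(data, cfg, distances, rng)
    weights = gwr_weights(distances, state.b, cfg.weight_threshold)

    scales = {"V": chain.scale_V, "knots": chain.scale_knots,
              "eps": chain.scale_eps, "b": chain.scale_b}

    M = chain.n_retained
    n_knots = cfg.stick.n_knots
    out = PosteriorSamples(
        z=np.empty((M, n), dtype=np.int32),
        beta=np.empty((M, K, p)), mu=np.empty((M, K, p)),
        Sigma=np.empty((M, K, p, p)), sigma2=np.empty((M, n)),
        b=np.empty(M), V=np.empty((M, K)),
        knots=np.empty((M, n_knots, 2)), eps=np.empty((M, n_knots, 2)),
        loglik=np.empty((M, n)), seed=chain.seed,
        likelihood_mode=cfg.likelihood_mode,
    )

    total_accepts = {k: [] for k in list(scales) + ["swap"]}
    m = 0
    for t in range(chain.n_iter):
        prior_p = np.empty(0)
        L = kernel_matrix(target.coords01, state.stick)
        prior_p = stick_weights(state.stick.V, L)
        state.z = update_assignments(state, data, weights, rng,
                                     mode=cfg.likelihood_mode, prior_p=prior_p)
        state = update_regression_blocks(state, data, weights, rng, cfg)
        sweep_accepts = {k: [] for k in scales}
        weights = update_stick_blocks(state, data, rng, config=cfg, chain=chain,
                                      target=target, distances=distances,
                                      weights=weights, scales=scales,
                                      accepts=sweep_accepts)

        if chain.adapt and t < chain.burn_in:
            eta = (t + 1.0) ** -0.6
            for key, accs in sweep_accepts.items():
                if accs and key in scales:
                    scales[key] *= float(np.exp(eta * (np.mean(accs) - TARGET_ACCEPT)))
        if t >= chain.burn_in:
            for key, accs in sweep_accepts.items():
                total_accepts[key].extend(accs)
            if (t - chain.burn_in) % chain.thin == 0 and m < M:
                out.z[m] = state.z
                out.beta[m] = state.beta
                out.mu[m] = state.mu
                out.Sigma[m] = state.Sigma
                out.sigma2[m] = state.sigma2
                out.b[m] = state.b
                out.V[m] = state.stick.V
                out.knots[m] = state.stick.knots
                out.eps[m] = state.stick.eps
                out.loglik[m] = pointwise_loglik(state, data)
                m += 1
        if chain.progress_every and (t + 1) % chain.progress_every == 0:
            rates = {k: (float(np.mean(v)) if v else None)
                     for k, v in total_accepts.items()}
            logger.info("sweep %d/%d acceptance=%s", t + 1, chain.n_iter, rates)

    out.acceptance = {k: (float(np.mean(v)) if v else None)
                      for k, v in total_accepts.items()}
    return out
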