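"""Spatial stick-breaking construction for the Dirichlet process prior.

A truncated Dirichlet process with K sticks is made spatial by attenuating
each stick fraction V_k with a kernel l_k(s) in [0, 1] centred at a knot
psi_k with bandwidth eps_k = (eps_1k, eps_2k):

    V_k(s) = l_k(s) V_k,          V_k ~ Beta(a_v, b_v)
    p_1(s) = V_1(s)
    p_k(s) = V_k(s) prod_{j<k} (1 - V_j(s))

The final stick is pinned at V_K(s) = 1 so the weights sum to one exactly
at every location.  Kernels are either a product of per-axis box
indicators (uniform) or a product of per-axis squared-exponential bumps;
bandwidths are fixed or random according to one of four prior kinds.

Coordinates are affinely rescaled to the unit square before kernel
evaluation so the kernel-scale hyperparameter ``lambda`` has a common
meaning across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

KERNEL_KINDS = ("uniform", "squared_exponential")
#: Bandwidth prior kinds: fixed at lambda; Exp with mean lambda;
#: fixed at lambda^2/2; InverseGamma(1.5, lambda^2/2).
BANDWIDTH_PRIORS = ("fixed_lambda", "exp_lambda", "fixed_lambda_sq_half", "inverse_gamma")

_FIXED_PRIORS = {"fixed_lambda", "fixed_lambda_sq_half"}


def bandwidth_is_fixed(prior_kind: str) -> bool:
    return prior_kind in _FIXED_PRIORS


@dataclass
class StickConfig:
    """Configuration of the spatial stick-breaking prior."""

    truncation_K: int = 20
    knots: int | None = None          # distinct knots; None -> one per stick
    kernel_kind: str = "squared_exponential"
    bandwidth_prior: str = "fixed_lambda_sq_half"
    lam: float = 0.8                  # kernel-scale hyperparameter on the unit square
    beta_a: float = 1.0
    beta_b: float = 1.0

    def __post_init__(self):
        if self.kernel_kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kernel_kind!r}")
        if self.bandwidth_prior not in BANDWIDTH_PRIORS:
            raise ValueError(f"unknown bandwidth_prior {self.bandwidth_prior!r}")
        if self.knots is None:
            self.knots = self.truncation_K
        if not (self.beta_a > 0 and self.beta_b > 0):
            raise ValueError("Beta hyperparameters must be positive")

    @property
    def n_knots(self) -> int:
        return int(self.knots)

    def knot_of_stick(self) -> np.ndarray:
        """Stick -> knot map; sticks share knots round-robin when knots < K."""
        return np.arange(self.truncation_K) % self.n_knots


@dataclass
class StickState:
    """Latent state of the truncated spatial stick-breaking prior.

    ``V`` are the K stick fractions; ``knots`` and ``eps`` hold one row per
    distinct knot (sticks map onto them round-robin).
    """

    V: np.ndarray                     # (K,)
    knots: np.ndarray                 # (n_knots, 2), unit square
    eps: np.ndarray                   # (n_knots, 2), positive
    config: StickConfig = field(repr=False, default_factory=StickConfig)


class UnitScaler:
    """Affine map of a coordinate cloud onto the unit square."""

    def __init__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        self.lo = coords.min(axis=0)
        span = coords.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, 1.0)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.lo) / self.span


def kernel_value(s, psi, eps, kind: str):
    """Kernel l(s) in [0, 1] for location(s) ``s`` against one knot.

    uniform: prod_j 1{|s_j - psi_j| < eps_j / 2};
    squared_exponential: prod_j exp(-(s_j - psi_j)^2 / (2 eps_j^2)).
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    psi = np.asarray(psi, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("kernel bandwidth must be positive")
    diff = s - psi[None, :]
    if kind == "uniform":
        vals = (np.abs(diff) < eps[None, :] / 2.0).all(axis=1).astype(float)
    elif kind == "squared_exponential":
        vals = np.exp(-(diff ** 2) / (2.0 * eps[None, :] ** 2)).prod(axis=1)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return vals if vals.size > 1 else float(vals[0])


def kernel_matrix(coords: np.ndarray, state: StickState) -> np.ndarray:
    """``(n, K)`` matrix of kernel values l_k(s_i) on unit-square coords."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    cfg = state.config
    kmap = cfg.knot_of_stick()
    psi = state.knots[kmap]           # (K, 2)
    eps = state.eps[kmap]             # (K, 2)
    diff = coords[:, None, :] - psi[None, :, :]
    if cfg.kernel_kind == "uniform":
        return (np.abs(diff) < eps[None, :, :] / 2.0).all(axis=2).astype(float)
    return np.exp(-(diff ** 2) / (2.0 * eps[None, :, :] ** 2)).prod(axis=2)


def stick_weights(V: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Location-wise cluster probabilities from sticks and kernel values.

    ``V`` is the length-K stick vector, ``kernels`` an (n, K) matrix of
    l_k(s_i).  The final stick is forced to 1 so each row sums to one
    exactly.  Returns an (n, K) row-stochastic matrix.
    """
    kernels = np.atleast_2d(np.asarray(kernels, dtype=float))
    V = np.asarray(V, dtype=float)
    Vs = kernels * V[None, :]
    Vs[:, -1] = 1.0
    one_minus = 1.0 - Vs
    # exclusive cumulative product of (1 - V_j(s)) over j < k
    cp = np.cumprod(one_minus[:, :-1], axis=1)
    p = np.empty_like(Vs)
    p[:, 0] = Vs[:, 0]
    p[:, 1:] = Vs[:, 1:] * cp
    return p


def sample_bandwidths(config: StickConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (n_knots, 2) bandwidth array from the configured prior."""
    lam = config.lam
    shape = (config.n_knots, 2)
    if config.bandwidth_prior == "fixed_lambda":
        return np.full(shape, lam)
    if config.bandwidth_prior == "fixed_lambda_sq_half":
        return np.full(shape, lam ** 2 / 2.0)
    if config.bandwidth_prior == "exp_lambda":
        return rng.exponential(scale=lam, size=shape)
    # InverseGamma(1.5, lambda^2 / 2)
    return stats.invgamma.rvs(1.5, scale=lam ** 2 / 2.0, size=shape, random_state=rng)


def log_bandwidth_prior(eps: np.ndarray, config: StickConfig) -> float:
    """Log prior density of the bandwidth array (0 for the fixed kinds)."""
    if bandwidth_is_fixed(config.bandwidth_prior):
        return 0.0
    if np.any(eps <= 0):
        return -np.inf
    if config.bandwidth_prior == "exp_lambda":
        return float(stats.expon.logpdf(eps, scale=config.lam).sum())
    return float(stats.invgamma.logpdf(eps, 1.5, scale=config.lam ** 2 / 2.0).sum())


def sample_stick_prior(config: StickConfig, rng: np.random.Generator) -> StickState:
    """Draw V, knots, and bandwidths from their priors."""
    V = rng.beta(config.beta_a, config.beta_b, size=config.truncation_K)
    knots = rng.uniform(0.0, 1.0, size=(config.n_knots, 2))
    eps = sample_bandwidths(config, rng)
    return StickState(V=V, knots=knots, eps=eps, config=config)
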