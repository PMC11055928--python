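# Methods

`sdpgwr` implements a Bayesian spatial Dirichlet process clustered
heterogeneous regression for areal data: a geographically weighted
Gaussian regression whose location-specific coefficient vectors are
clustered by a spatial stick-breaking Dirichlet-process prior, fitted by a
blocked Gibbs / Metropolis–Hastings sampler.

## Model

Each areal unit `s_i` (i = 1..n) carries a response `y(s_i)`, a covariate
vector `x(s_i)` of length p, and a centroid.  A contiguity graph over the
areas yields graph distances `d_ij` (shortest-path edge counts);
great-circle and planar metrics are available as alternatives.  GWR
weights follow the unit-step / negative-exponential rule

    w_ij = 1                 if d_ij <= threshold   (default 1 on the graph scale)
    w_ij = exp(-d_ij / b)    otherwise,

with `w = 0` for areas in different graph components, and a single global
bandwidth `b ~ Uniform(0, D)`, `D = 100`.

Coefficients are cluster-constant: `beta(s_i) = beta_{z_i}` with labels
`z_i in 1..K` drawn from the location-dependent stick-breaking weights

    p_1(s) = V_1(s),   p_k(s) = V_k(s) * prod_{j<k} (1 - V_j(s)),
    V_k(s) = l_k(s) V_k,   V_k ~ Beta(a_v, b_v),

where `l_k(s)` is a uniform-box or squared-exponential kernel centred at a
knot `psi_k` with bandwidth pair `eps_k` (fixed at `lambda`, drawn
Exp(lambda), fixed at `lambda^2/2`, or InverseGamma(1.5, lambda^2/2)).
The final stick is pinned at one so the weights sum to one exactly at
every location.  The conjugate hierarchy is

    beta_k ~ N_p(mu_k, Sigma_k),  mu_k | Sigma_k ~ N_p(m, Sigma_k),
    Sigma_k ~ InverseWishart(D_k, c_k),  sigma^2(s) ~ InverseGamma(a1, a2).

## Likelihood forms

The role of the GWR weights in the joint model is the one genuinely open
question of this model class, and the package exposes three readings:

* **`composite` (default)** — the geographically weighted log-likelihood:
  area i contributes `sum_j w_ij log N(y_j | x_j' beta_{z_i}, sigma^2(s_i))`.
  Raising each local term to the power of its weight is the form used in
  the weighted-likelihood BGWR literature.  Its effective sample size at
  `s_i` is `sum_j w_ij`, which makes the per-area variances identifiable
  and yields correctly scaled variance estimates.
* **`composite_density`** — every term is a full Gaussian density with
  variance `sigma^2(s_i) / w_ij`.  Algebraically this shares the same
  `beta` and `z` conditionals, but each term contributes a whole
  observation's worth of information regardless of its weight.  In
  experiments this drives the bandwidth posterior to the global-weighting
  boundary (`b -> D`), after which every cluster's coefficient vector
  collapses onto the global fit: the partition it reports is carried
  almost entirely by the spatial prior, and coefficient recovery fails.
  The form is kept first-class because it is the literal variance-scaled
  rendering of the model, but it is not recommended for inference.
* **`plain`** — one term per area with self-weight 1 (an ordinary mixture
  of regressions).  The bandwidth then appears nowhere in the likelihood
  and simply follows its uniform prior.  Under the plain likelihood the
  per-area variances are unidentifiable (one observation each), which
  makes cluster labels nearly free and fragments the partition; pair it
  with `variance_mode="shared"` if used for clustering.

Pointwise log-likelihoods for WAIC always use the plain one-term-per-area
form regardless of the fitting mode, so models are compared on the same
data partition.

A related caveat, worth stating plainly: a composite (pseudo-)likelihood
cannot calibrate its own bandwidth.  Under the weighted log-likelihood the
bandwidth conditional concentrates near the lower boundary (weights reduce
to the unit-step neighbourhood disc); under the density form it runs to
the upper boundary (global weighting).  The reported `b` should therefore
be read as a weighting convention, not as an estimated spatial range.

## Sampler

One sweep updates, in order: (1) all labels `z_i` from their categorical
conditionals (log-space with Gumbel-max sampling, never NaN); (2) `beta_k`
from its multivariate-normal conditional, `(mu_k, Sigma_k)` from the
conjugate Normal-Inverse-Wishart update (empty clusters thereby refresh
from the prior), and `sigma^2` from its Inverse-Gamma conditional with the
mode-appropriate effective sample size; (3) the stick blocks — stick
fractions on the logit scale, knots in the unit square, random kernel
bandwidths on the log scale, each by Metropolis–Hastings with the matching
Jacobian, plus the GWR bandwidth by random walk on `(0, D)` against the
weighted likelihood.

Three additions improve mixing without changing the target:

* a *stick-swap move* exchanging `(beta_k, mu_k, Sigma_k)` between two
  sticks together with their labels — likelihood and the exchangeable base
  measure cancel, so a coefficient cluster can migrate to a stick whose
  kernel footprint matches its region;
* *independence refreshes* (probability 0.2) of stick fractions and knots
  drawn from their priors, so a knot can jump across the domain;
* Robbins–Monro adaptation of proposal scales toward 0.3 acceptance during
  burn-in only, keeping the retained chain Markovian.

Initialization is a warm start: labels from k-means (3 groups) on per-area
ridge-weighted local regression coefficients; `b` from a grid profile of
the composite likelihood at that state; variances from the initial mean
squared residual; all remaining parameters from their priors.  All
randomness flows from one integer seed; equal seeds give bit-identical
draw archives.

## Defaults and units

| parameter | default | meaning |
| --- | --- | --- |
| K (truncation) | 20 | sticks retained in the finite approximation |
| knots | K (9 in the study runs) | distinct kernel centres; sticks share them round-robin |
| lambda | 0.8 | kernel scale on the unit square |
| a_v, b_v | 1, 1 | stick Beta prior |
| m, D_k, c_k | 0, I, p + 2 | base-measure hyperparameters |
| a1, a2 | 0.1, 0.1 | variance prior |
| D | 100 | bandwidth upper bound (graph-distance scale) |
| chain | 10000 / 2000 / thin 1 | sweeps / burn-in / thinning (8000 retained) |

`lambda = 0.8` is chosen so the squared-exponential bandwidth
`eps = lambda^2/2 ~ 1/3` matches the spacing of a 3x3 knot tiling of the
unit square.  Much narrower kernels produce a degenerate prior: a
Monte-Carlo check with `lambda = 0.5` puts over half the prior stick mass
on the pinned final stick at a typical location, because all other
kernels vanish there; cluster footprints are then capped at the kernel
width.  Measured partition quality was flat across `lambda` in [0.5, 2],
so the choice follows the geometry, not a metric.

Coordinates are affinely rescaled to the unit square before kernel
evaluation; `lambda` always refers to that scale.  Models are fitted
without an intercept by default (`intercept=True` appends a constant
column).

## Cluster summaries

Dahl's least-squares configuration minimises the Frobenius distance
between a draw's co-clustering matrix and the posterior mean co-clustering
matrix (ties to the lowest draw index).  The posterior-mode configuration
first aligns every draw to the Dahl draw by greedy confusion-matrix
matching (label switching is deliberately unrestricted during sampling),
then takes per-area majority labels, ties to the smaller label.  HPD
intervals use the shortest sorted window containing `ceil(level*M)`
points, earliest start on ties.  Per-cluster coefficient tables are
computed from draws aligned to the chosen configuration; solution clusters
without a matched label in a draw are skipped for that draw, and empty
clusters are flagged rather than dropped.

## Synthetic study

The generator emulates a 159-area Georgia-like lattice: a jittered
13-column grid over a 7x7 box (largest centroid separation about 10, the
scale the `D = 100` bound was calibrated against), Delaunay-triangulated
contiguity, and a deterministic three-band partition of sizes 51/49/59 cut
by x-coordinate rank.  Covariates are six independent draws of a zero-mean
Gaussian process with covariance `exp(-||s_i - s_j|| / phi)`, `phi = 0.9`;
responses add independent `N(0, 1)` noise to the cluster-constant linear
predictor.  The three generating coefficient vectors default to the
published per-cluster posterior means of this design (the original
generating values are not stated anywhere); noise sd 1 is likewise this
package's choice.  The layout is a surrogate: the original study
partitioned real county centroids visually, which fixes only the region
sizes, not the geometry.

What the generator does **not** emulate: irregular county geometries and
their heterogeneous neighbour counts, covariate cross-correlation (the six
GP draws are independent), and any non-Gaussian or heteroscedastic noise.
Passing tests on this generator demonstrate correctness of the pipeline
and qualitative recovery behaviour, not performance on real areal data.

The replicate study (`run_replicate_study`) repeats simulate → fit →
summarize with per-replicate seeds `seed + r`, reporting Rand indices for
the Dahl and mode configurations and the replicate-averaged MAB / MSD /
MMSE of per-area posterior-mean coefficients (MSD uses the R-1 divisor
and is reported missing for a single replicate).

Problem sizes used by the shipped evaluation runs: 159 areas, 10
replicates per kernel configuration, 2000-sweep chains with 500 burn-in.
These reduced chains mix adequately for this generator (acceptance rates
near 0.3 on all MH blocks; longer 10000-sweep chains gave the same
partition structure).

## Known limitations

* With the flat defaults (`Beta(1,1)` sticks, `IG(0.1, 0.1)` variances,
  K = 20), the Dirichlet-process prior is weakly parsimonious: the
  posterior tends to split large homogeneous regions into sub-clusters
  with similar coefficients.  Dahl configurations on the synthetic study
  typically occupy 5–11 clusters rather than the generating 3, and the
  Rand index against truth plateaus around 0.75–0.82 even for long chains.
  Coefficient recovery is unaffected (sub-clusters carry near-identical
  coefficient vectors).  Stronger concentration (larger `b_v`, tighter
  base measure) merges them; those constants are deliberately left at
  their conventional values.
* The cluster count reported by a truncated spatial DP mixture is not a
  consistent estimate of the number of generating components; treat it as
  descriptive.
* WAIC uses the variance penalty with the sample (M-1) divisor; it is
  additive over observations and computed in log space.
* The `composite_density` and `plain` modes are retained for completeness
  and comparison, with the caveats above.
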