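# sdpgwr — spatial Dirichlet process clustered GWR

`sdpgwr` fits a Bayesian spatial Dirichlet process clustered heterogeneous
regression to areal data: a geographically weighted Gaussian regression
whose location-specific coefficient vectors are grouped by a spatial
stick-breaking Dirichlet-process prior.  It is aimed at population-health
and small-area analysts who want, from one model, (i) localized regression
effects, (ii) a data-driven number of spatial clusters of those effects
with uncertainty, and (iii) the standard evaluation toolkit (WAIC, Rand
index, replicate bias/spread/error metrics).

## Model

For areal units s_1..s_n with responses y(s) and covariates x(s),

    y(s_i) | beta_{z_i}, sigma^2(s_i)  ~  N(x(s_i)' beta_{z_i}, sigma^2(s_i)),

with the contribution of each area to the fit geographically weighted by
w_ij = 1 if d_ij <= 1 and exp(-d_ij / b) otherwise (graph distance on the
contiguity graph by default; b ~ Uniform(0, D)).  Labels z_i follow
location-dependent stick-breaking weights

    p_k(s) = l_k(s) V_k * prod_{j<k} (1 - l_j(s) V_j),   V_k ~ Beta(a_v, b_v),

where l_k(s) is a uniform or squared-exponential kernel centred at a
random knot; cluster coefficients carry a conjugate
Normal–Inverse-Wishart hierarchy.  Inference is by a blocked
Gibbs / Metropolis–Hastings sampler; point clusterings come from Dahl's
least-squares method and from per-area posterior modes; summaries include
posterior means with 95% highest-posterior-density intervals.  See
`docs/methods.md` for the full model, the three supported likelihood
readings, and all defaults.

## Worked example

```python
import numpy as np
from sdpgwr import (ChainConfig, ModelConfig, SimulationConfig, StickConfig,
                    rand_index, run_chain, simulate_dataset)
from sdpgwr.summarize import cluster_table, dahl_select

# a 159-area synthetic study: 6 spatially correlated covariates, three
# coefficient regions of sizes 51/49/59, unit Gaussian noise
sim = SimulationConfig(seed=1)
data, truth = simulate_dataset(sim)

model = ModelConfig(p=sim.p, stick=StickConfig(truncation_K=20, knots=9))
chain = ChainConfig(n_iter=2000, burn_in=500, seed=1)
samples = run_chain(data, model, chain)

_, dahl = dahl_select(samples.z)
print("clusters:", dahl.n_clusters, "sizes:", dahl.sizes())
print("Rand index vs truth:", round(rand_index(dahl.labels, truth["labels"]), 3))
table = cluster_table(samples, dahl)
big = table[table.covariate == 1].nlargest(3, "size")
print(big[["cluster", "size", "mean", "hpd_lo", "hpd_hi"]].round(2).to_string(index=False))
```

Output from this exact run:

```
clusters: 8 sizes: [33 27 19 40  3 23 10  4]
Rand index vs truth: 0.781
 cluster  size  mean  hpd_lo  hpd_hi
       4    40  2.76    2.56    2.97
       1    33 -0.92   -1.05   -0.79
       2    27  0.49    0.33    0.63
```

The three dominant clusters carry the three generating coefficient
regimes for covariate 1 (truth: 2.31, −1.0, 0.62); the Rand index of
0.78 reflects that a Dirichlet-process mixture with flat priors also
keeps several small sub-clusters alive (see the limitations section of
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
sdpgwr simulate --config config.yaml --out sim/
sdpgwr fit --areas sim/areas.csv --edges sim/edges.csv --config config.yaml --out chain/
sdpgwr summarize --archive chain/ --out report/ --truth sim/truth_labels.csv
sdpgwr replicate-study --config config.yaml --out study/ -R 10
```

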