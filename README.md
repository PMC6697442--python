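# glvnet

Simulation and Bayesian network inference for small microbial consortia
measured as absolute abundance time series (CFU/ml, e.g. strain-specific
multiplex qPCR).  The package targets the question asked of synthetic
four-member gut communities — *which members help or hurt which others, and
how confidently can the data say so?* — and provides the full loop needed to
study it without wet-lab data: generate realistic knockdown experiments from
a known interaction network, infer the network back, and score the
recovery.

## The model

Community dynamics are discrete-time stochastic generalized Lotka-Volterra
(gLV):

    x[k+1,i] = x[k,i] + x[k,i] ( r_i + Σ_j a_ij z_ij x[k,j] ) Δ_k + w[k,i]

with growth rates `r_i`, interaction coefficients `a_ij` (effect of species
*j* on species *i*), binary edge indicators `z_ij`, and Gaussian process
noise of variance `v_w_i Δ_k`.  Inference is Bayesian variable selection:
a spike-and-slab prior `z_ij ~ Bernoulli(0.5)`,
`r_i ~ N(0, v_r)`, `a_ij ~ N(0, v_a)`, scaled-inverse-χ² hyperpriors on all
variances, and a partially collapsed Gibbs sampler (5,000 sweeps, 1,000
burn-in) in which indicators are updated with coefficients integrated out
analytically.  Edge evidence is a Bayes factor — posterior over prior
inclusion odds — read with the standard thresholds: 3–10 substantial,
\>10 strong (an edge kept in every draw reports BF = ∞).  Ecological
summaries include Pielou evenness `−Σ p_i ln p_i / ln S`, log-fold knockdown
ratios, and four-parameter-logistic EC50 fits for metabolite growth
requirements.  See `docs/methods.md` for the full model and its
assumptions.

## Worked example

Simulate knockdown experiments from the engineered-like preset (two
cross-feeding edges from B. fragilis), infer the network, and score it:

```sh
glvnet simulate --preset engineered --seed 1 --measurement-cv 0 --out run/
glvnet infer --input run/trajectories.tsv --out run/ --seed 1
glvnet evaluate --truth run/ground_truth.yaml \
    --summary run/network_summary.tsv --input run/trajectories.tsv
```

which prints

```
wrote 15 trajectories to run/trajectories.tsv
12 candidate edges summarized (4 with strong evidence); outputs in run
{
  "detection_rate": 1.0,
  "false_edge_rate": 0.0,
  "sign_accuracy": 1.0,
  "coefficient_rmse": 3.428180498139352e-12,
  "evenness_rmse": 0.00025607212237702224
}
```

All four true edges are recovered with strong evidence (`detection_rate`
is the fraction of true edges at BF > 10), none of the eight absent edges
is falsely supported at BF > 3, every detected sign matches the truth, and
the inferred coefficients sit within ~3×10⁻¹² RMSE of the generating
values (the coefficients themselves are of order 5×10⁻⁹).  The network
table itself lives in `run/network_summary.tsv`; the positive edges it
reports are exactly BF→Ec and BF→ST:

```
source  target  inclusion_probability  bayes_factor  category  mean_strength  sign
BF      Ec      1.0                    inf           strong     6.71e-09      +
BF      ST      1.0                    inf           strong     5.51e-09      +
ST      BF      1.0                    inf           strong    -4.02e-09      -
ST      Ec      1.0                    inf           strong    -6.76e-09      -
...
```

The same loop is available as a library through scikit-learn-style
estimators:

```python
from glvnet import SpikeSlabGLV, generate_dataset, make_knockdown_design
from glvnet import preset_engineered_network, NoiseModel
from glvnet.synth import DEFAULT_SPECIES

params = preset_engineered_network(seed=1)
data, truth = generate_dataset(
    params, make_knockdown_design(DEFAULT_SPECIES),
    NoiseModel(measurement_cv=0.0), seed=1)
est = SpikeSlabGLV(random_state=1).fit(data)
print(est.network_[["source", "target", "bayes_factor", "sign"]])
```

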