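# Methods

## The model

`glvnet` simulates and infers discrete-time stochastic generalized
Lotka-Volterra (gLV) dynamics for a small bacterial consortium measured as
absolute abundances (CFU/ml), the measurement currency of strain-specific
multiplex qPCR:

    x[k+1, i] = x[k, i] + x[k, i] * ( r_i + Σ_j a[i, j] z[i, j] x[k, j] ) Δ_k + w[k, i]

* `r_i` — intrinsic growth rate of species *i* (1/h).
* `a[i, j]` — interaction coefficient, effect of species *j* on species *i*
  (1/(h·CFU/ml)); row = target, column = source, matching the sum over
  sources in the growth term.
* `z[i, j] ∈ {0, 1}` — edge indicator; `z[i, i]` is fixed to 1 because
  bounded growth requires self-limitation, so the candidate network over
  S species has S(S−1) interspecies edges (12 for S = 4).
* `w[k, i]` — Brownian-motion increment with variance `v_w[i] · Δ_k`
  (abundance²/h).  The dimensionally consistent Brownian-increment
  convention is used throughout; an alternative reading that scales the
  increment by an extra `Δ_k` differs only by a rescaling of `v_w` on a
  uniform grid.
* Optional higher-order terms `z3_i a3_i Π_{j≠i} x_j` and
  `z4_i a4_i Π_j x_j` extend the per-capita rate; they are treated exactly
  like interaction terms (multiplied by `x[k, i] Δ_k` in the update), which
  keeps the extension inside the gLV per-capita form.

Forward simulation is explicit Euler on the sampling grid with optional
sub-stepping; post-step states are clamped at zero because abundances are
concentrations and additive noise could otherwise turn them negative.
A single self-limited species has carrying capacity `K = −r / a_self`.

## Bayesian spike-and-slab inference

Because the Euler update is linear in `(r_i, a[i, ·])`, each species
contributes a Gaussian linear regression with response
`x[k+1, i] − x[k, i]`, covariates `x[k, i] Δ_k` and `x[k, i] x[k, j] Δ_k`,
and per-row noise variance `v_w[i] Δ_k`.  The prior hierarchy is

    z[i, j] ~ Bernoulli(0.5)            (maximum prior uncertainty per edge)
    r_i | v_r ~ Normal(0, v_r)          v_r ~ Scaled-Inv-χ²(0.1, 0.01)
    a[i, j] | v_a ~ Normal(0, v_a)      v_a ~ Scaled-Inv-χ²(0.1, 1e-14)
    v_w[i] ~ Scaled-Inv-χ²(0.1, 1e4)

The scaled-inverse-chi-squared distribution is parameterized by degrees of
freedom ν and scale τ²; with ν = 0.1 these are heavy-tailed, effectively
uninformative priors, and the θ scales are meaningful on the raw CFU/ml
scale (interaction coefficients for communities near 1e9 CFU/ml are of
order 1e-9, well inside the `v_a` prior's bulk).  `v_a` is shared by all
interaction coefficients, including self-terms and higher-order terms;
only the process-noise variance is per-species.

Sampling is a partially collapsed Gibbs sweep, 5,000 iterations with the
first 1,000 discarded (4,000 retained draws):

1. **Indicators.**  Each off-diagonal (and higher-order) indicator is
   updated with *all* of that species' coefficients integrated out
   analytically; the inclusion odds are the ratio of Gaussian marginal
   likelihoods times the prior odds.  Integrating the coefficients rather
   than conditioning on them avoids the reducibility problem of naive
   spike-and-slab samplers (a coefficient drawn under the slab is almost
   never exactly compatible with the spike).
2. **Coefficients.**  Included coefficients are redrawn jointly from their
   Gaussian full conditional; excluded coefficients are drawn from the
   prior (they do not enter the likelihood but remain part of the state).
   Reinstating the coefficients immediately after the marginalized
   indicator scan is what makes the partially collapsed sweep exact, which
   is why the sweep order is indicators → coefficients → variances.
3. **Variances.**  Conjugate updates: posterior degrees of freedom ν + n
   and scale (ν τ² + SS)/(ν + n), where n counts growth rates for `v_r`,
   all interaction coefficients for `v_a`, and the Δ-standardized residuals
   of the included fit for each `v_w[i]`.

Initialization is deterministic and overdispersed: all edges included,
coefficients from ridge-regularized least squares, variances at prior
scales.  All linear algebra runs on unit-Gram-diagonal rescaled columns so
the 1e8–1e33 dynamic range of the covariates never reaches a Cholesky
factorization.

**Edge evidence.**  For each edge the Bayes factor is the posterior-odds /
prior-odds ratio of inclusion, estimated from the retained draws.  An edge
included in every draw reports BF = +∞ (flagged, not an error); one never
included reports 0.  A Jeffreys-style pseudo-count estimator
((k+0.5)/(n−k+0.5)) is available behind a flag for plotting.  Thresholds
follow the standard interpretation: BF in [3, 10] substantial, BF > 10
strong evidence; no multiplicity correction is applied across the 12
edges.  Edge BFs are reported per edge.

**Plug-in states.**  Observed abundances are used directly as the latent
states of the regression (process noise only, no latent-state filtering).
This is the model's main simplification, and it makes the inference
sensitive to *measurement* error on the covariates: in synthetic
experiments, multiplicative measurement noise of even 1–2% CV produces
spurious high-BF edges in a substantial fraction of runs, because the
errors-in-variables bias grows statistically significant with ~100 design
rows.  Measurement noise in the generator is therefore a robustness
stressor, and quantitative recovery claims are made under process noise
only.  Rows whose source or response observation sits at the detection
floor are excluded from the design by default (`floor_policy="drop"`), as
are rows with non-positive source abundance.

## Synthetic experiments

The generator emulates five-condition batch-coculture knockdown
experiments on a four-member consortium (labels Ec, ST, BT, BF): an
equal-inoculum baseline plus, for each species in turn, a condition with
that species' starting inoculum reduced 10-fold; anaerobic growth over a
27 h horizon.  Defaults, configurable throughout:

* sampling grid 0, 2, 4, 7, 11, 16, 21, 27 h (8 points, denser early where
  growth is fastest; the real experiments' grid is not enumerable from the
  source material, so this is a stand-in);
* baseline inoculum 1e6 CFU/ml per species; 3 replicates;
* multiplicative lognormal measurement error, default CV 10% (typical of
  qPCR absolute quantification), unit mean;
* detection floor 1e3 CFU/ml; censored values are retained and flagged so
  the design can exclude them.

Two ground-truth presets reproduce the qualitative contrasts between a
wild-type and an engineered cross-feeding consortium:

* **WT-like** — growth rates 0.70–0.95 /h, carrying capacities ~1e9
  CFU/ml, 7 of 12 interspecies edges present, all antagonistic, with
  |a[i,j]| ≈ 1.4 · r_i / K; process-noise variance 1e10.
* **Engineered-like** — growth rates exactly one third of the WT preset's,
  carrying capacities 1.5 orders of magnitude lower (~3e7 CFU/ml), exactly
  two positive edges (BF→Ec and BF→ST, the cross-feeding routes) plus two
  residual antagonisms, edge magnitudes ≈ 0.6 · r_i / K (larger in absolute
  terms than WT because interaction strength scales inversely with
  carrying capacity in a gLV model); process-noise variance 1e8.

Each seed jitters rates (±10%) and edge strengths (±20%) so different
seeds give distinct but qualitatively identical truths.  The preset
magnitudes were fixed by deterministic simulation against the intended
contrasts: the engineered community reaches ~20-fold lower total density
at 24 h, WT knockdowns persist through 27 h, and engineered knockdowns
return close to baseline ratios (log-fold ratios nearer 0 than WT for
every knocked species).  What the presets do **not** emulate: resource
(amino-acid) dynamics, lag phases, pH-mediated inhibition, or any
non-gLV curvature — passing recovery tests shows the inference recovers
gLV truths from gLV data, not that real consortia obey gLV dynamics.

## Metrics

* **Pielou evenness** `−Σ p_i ln p_i / ln S` of the proportional
  composition; 1 at equal abundances, 0 under complete dominance, with the
  limit convention 0·ln 0 = 0.
* **Log-fold knockdown ratio** logR_i(t) = log10 of knockdown over
  baseline abundance (base configurable; replicates aggregated by median
  before the ratio, mirroring how such figures typically show medians).
* **EC50** — four-parameter logistic
  `y = bottom + (top − bottom)/(1 + (ec50/c)^hill)`, the common
  variable-slope sigmoid family, least-squares fitted with bottom
  constrained ≥ 0; EC50 is reported in the input concentration units and
  the fitted curve passes through the half-maximum at c = EC50.

## Verification strategy and problem sizes

* Sampler components are checked against closed forms: conjugate
  Normal posteriors for coefficient draws, scaled-Inv-χ² moments for
  variance draws, prior-frequency behavior for zero columns.
* On a 2-species system (2 conditions × 6 time points) the Gibbs
  edge-inclusion probabilities are compared with exhaustive enumeration
  over all four indicator configurations, coefficients integrated out
  analytically, with the three variances fixed on both sides so the
  enumeration stays closed-form; agreement is required within 0.03.
* A scaled-down simulation-based calibration (150 prior-simulated
  replicates, short fixed-variance chains, thinned ranks) checks posterior
  uniformity for growth rates.
* Network recovery runs both presets over 20 seeds each under the default
  knockdown design with process noise only, requiring every true edge at
  BF > 10, every absent edge at BF < 3, all detected signs correct, and
  exactly the two positive edges BF→Ec, BF→ST for the engineered preset in
  ≥ 90% of runs.
* With pairwise ground truth, the higher-order extension must report
  higher-order indicator BFs ≤ 1 (up to Monte-Carlo error of the inclusion
  frequency).

These sizes (≤ 20,000 sweeps, 150 calibration replicates, 20 recovery
seeds) keep the whole suite to minutes on one core and were chosen as the
smallest scales at which the checks are statistically meaningful.

## Known limitations

* Plug-in state treatment (above): no robustness to measurement error on
  covariates; a latent-state filter is out of scope.
* Explicit Euler on the observation grid means coarse grids bias
  coefficients for fast dynamics; sub-stepping exists for forward
  simulation only, never for the likelihood, so simulator and likelihood
  agree exactly on the grid.
* Infinite Bayes factors are a finite-sample artifact of Monte-Carlo
  inclusion frequencies; they mean "included in every retained draw", not
  infinite evidence.
* The EC50 fit requires concentrations spanning the transition; degenerate
  flat curves and fewer than four distinct concentrations are rejected
  rather than extrapolated.
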