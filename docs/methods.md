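# Methods

## The observation process

eDNA surveys confound three distinct failure modes: the target's DNA may be
absent at a site, present but missed by a water sample, or captured but not
amplified by a qPCR replicate. `occuscale` models the resulting nested
binary data with two related hierarchies.

**Two-level model** (`occuscale.classic`). Sampling units (water samples in
a controlled sensitivity trial, or sites in a visual-survey comparison) are
occupied with probability ψ; each replicate of an occupied unit detects
with probability *p*. The marginal likelihood per unit sums over the latent
occupancy state; all-negative histories are the informative mixture term.
Fitting is by BFGS on the logit scale from the 9-point start grid
ψ, p ∈ {0.25, 0.5, 0.75}², gradient tolerance 1e-10, which makes the fit
deterministic; the likelihood depends on the data only through a small set
of sufficient statistics, so unit ordering and the arrangement of
detections across units with equal totals are irrelevant (asserted in the
tests). Standard errors are delta-method transforms of the inverse
observed information (central finite differences on the logit scale).
Boundary estimates (all-positive or all-negative data) are flagged and
their SEs reported as NaN rather than a meaningless quadratic
approximation.

**Three-level model** (`occuscale.multiscale`). Site occurrence
z_i ~ Bern(ψ_i), conditional sample capture a_ij | z_i ~ Bern(z_i θ_ij),
conditional replicate detection y_ijk | a_ij ~ Bern(a_ij p_ijk). Each
probability is a link-transformed linear function of standardized
covariates with an implicit intercept. Ragged designs (unequal samples per
site, replicates per sample) and missing replicates (NaN, skipped by all
likelihood code — never coded as non-detections) are supported throughout.

## Link, priors, and sampler

The default link is the **probit**, with independent **normal(0, 1)**
priors on all coefficients; both choices match the convention of the
multiscale eDNA occupancy literature this package follows, and both are
configurable (`link="logit"`, `prior_sd=...`). For a dataset in which every
site has at least one detection the ψ-intercept posterior is exactly
∝ φ(β) Φ(β)^I, which provides an independent quadrature check of the
sampler used in development.

Inference is Metropolis-within-Gibbs, one chain by default:

- z and a are refreshed each iteration from their exact Bernoulli full
  conditionals (forced to 1 where a detection was observed; a ≡ 0 where
  z = 0).
- Each coefficient block (ψ, θ, p) takes a spherical random-walk Metropolis
  step. Proposal scales adapt every 50 iterations toward ~0.37 acceptance
  during burn-in only and are frozen afterwards, so retained draws come
  from a fixed transition kernel.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical seed, config and data give
  bit-identical draws.

Defaults mirror the study settings: 50,000 iterations, burn-in 5,000, no
thinning. On the ten-site study data this takes a few seconds; a 200-site
synthetic survey fits in ~2 s at 2,500 iterations. Posterior summaries
report mean, median, equal-tailed 95% credible intervals, and a
batch-means Monte Carlo standard error (~√M batches). A covariate effect
is called "supported" when the slope's 95% CRI excludes zero, endpoints
inclusive.

## Model-selection criteria

Both criteria are computed from the retained draws, including the sampled
latent states; both are smaller-is-better. Their exact conventions matter
more than usual here, because several plausible definitions differ by large
factors, so the defaults are pinned to the convention used by the
multiscale eDNA occupancy literature:

- **WAIC**: pointwise observation = the positive-replicate count d_j of
  water sample j, with likelihood Bin(d_j; K_j, a_j p) conditional on the
  sampled capture indicator a_j (an empty sample under a_j = 0 contributes
  likelihood one). Criterion = −(lppd − pW) on the log-score scale, with
  penalty pW = Σ_j var_m log p(d_j | ·). The conventional deviance scale
  (−2(lppd − pW)) and fully latent-marginalized pointwise likelihoods
  (partitioned by sample or by site, the site's occupancy factor
  apportioned equally across its samples) are available as options. Note
  the conditional likelihood makes WAIC insensitive to θ-level covariates
  except through the penalty — a property of the convention, not a bug;
  the marginal options are the right tool when θ-level fit itself is the
  question.
- **PPLC** (squared-error loss, infinite-weight limit): per water sample
  the predictive replicate is d̃_j ~ Bin(K_j, a_j p) conditional on the
  sampled latent state; PPLC = G + P with G = Σ_j (d_j − E d̃_j)² and
  P = Σ_j Var d̃_j. A per-qPCR Bernoulli variant (`level="replicate"`)
  is available.

`rank_models` orders by WAIC with ties broken by fewer coefficients, then
name, and reports the PPLC order alongside.

## Survey effort

Cumulative capture/detection probabilities use θ* = 1 − (1 − θ)^j and
p* = 1 − (1 − p)^k. The minimum effort calculator returns the smallest
integer whose cumulative probability **strictly exceeds** the target
(default 0.95); an exact tie requires one more unit. Credible bands are
computed by applying the transform per posterior draw and taking quantiles,
which is exact under the posterior because the transform is monotone.

## qPCR calling

A replicate is positive iff its threshold cycle is present, at or below
the cutoff (default 34 cycles, ties positive), and its amplification curve
passed visual quality control. Curve-shape QC is a human judgement on the
instrument's amplification plots, so it enters as a boolean override
column rather than being re-derived from fluorescence data. The standard
curve is an ordinary least-squares line of C_T on log10(concentration);
amplification efficiency is 10^(−1/slope) − 1.

## Built-in study data

`occuscale.datasets` ships the central-Texas *Eurycea* survey at the
granularity available in published form: per-site totals (positive samples
/ samples, positive replicates / replicates, visual counts, surveyed
area).
Per-sample replicate outcomes are reconstructed in a canonical arrangement
consistent with those totals. Because every covariate in this study is
site-level, all model fits depend on the data only through the per-site
totals, so the arrangement is irrelevant to estimation (asserted by test);
the conditional-likelihood criteria depend mildly on the within-site
arrangement, which bounds agreement with published criterion values at
roughly the 1% level.

## Synthetic data

`occuscale.simulate` draws the hierarchy forward: covariates from declared
distributions (or fixed per-site values), standardized exactly as the
analysis pipeline standardizes real covariates, so generating coefficients
are directly comparable with fitted ones; then z, a, y as Bernoulli
cascades. The true latent states are returned with the data.
`field_design()` reproduces the ten-site study layout (nine sites with six
1 L samples, one well site with three; triplicate qPCR; the published
per-site densities) with the study's fitted posterior medians as generating
coefficients. What the generator does *not* emulate: spatial or temporal
correlation in eDNA concentration, false positives (contamination), C_T
-level measurement noise, or covariate measurement error — so passing
recovery tests demonstrates correctness of the inference machinery under
the model, not robustness of the model to real-world violations.

Simulation studies in the test suite use sizes chosen to exercise the
asymptotics without waste: coverage of 95% credible intervals is checked
at 200 sites × 6 samples × 3 replicates over 50 seeded surveys (2,500
iterations each), and two-level MLE calibration at 500 units over 100
replicates.

## Numerical choices and limitations

- Probabilities are clipped at 1e-300 before logs in marginal-likelihood
  code; boundary parameters in the two-level likelihood return −inf.
- The MLE grid-search oracle used in tests evaluates a 2000 × 2000 midpoint
  grid, whose resolution (5e-4) sets the achievable agreement; very small
  datasets with near-flat likelihood ridges are excluded from that
  comparison by construction (8–15 units are used).
- Constant covariates (after any subsetting) raise a hard error rather
  than being silently dropped.
- One chain by default; for multi-chain diagnostics run `sample_posterior`
  with different seeds and compare summaries (no built-in R-hat).
- False-positive detections are not modelled: a single contaminated
  replicate forces its sample and site latent states to 1.
- With ten sites, site-level inference (ψ) is prior-sensitive; the
  defaults are weakly informative on the probability scale, and covariate
  conclusions at this scale should be treated as exploratory.
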