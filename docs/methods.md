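# Methods

## Model

Arm-level binary outcomes are modelled directly: for trial *i* in
meta-analysis *m*, control-arm events are binomial with log odds α_im and
treatment-arm events binomial with log odds α_im + θ_im, where θ_im is the
trial's true log odds ratio.  No continuity corrections are ever applied;
double-zero trials contribute through the binomial likelihood as they are.

Trial effects are normal given the trial's characteristic indicators:

* mean d_m + Σ_j X_ijm b_jm,
* variance τ²_m + Σ_j X_ijm κ²_j (additive) or
  τ²_m Π_j (1 − X_ijm + X_ijm λ_j) (label-invariant).

The within-trial bias terms that motivate the additive model are
marginalised: we model θ directly with the inflated variance rather than
sampling a per-trial bias, which has the identical marginal likelihood and
far fewer latent variables.  The multivariable additive variance attaches
each κ²_j only to trials that carry characteristic j (indicator inside
the sum); κ² and λ are common across meta-analyses — one per
characteristic — because meta-epidemiological data rarely support more.

Mean biases are exchangeable, b_jm ~ N(b0_j, φ²_j), and heterogeneity
variances follow τ²_m ~ log-normal(μ, σ²).  The hierarchy refers to the
reference (X = 0) category; after relabelling a characteristic the
reference variance becomes λτ², whose distribution is *not* log-normal, so
likelihood-level label-invariance holds exactly but the full posterior is
invariant only approximately.  This is why the end-to-end invariance check
asserts b0′ ≈ −b0 tightly but only brackets λ·λ′ around 1.

## Priors and their defaults

| parameter | prior | default | notes |
|---|---|---|---|
| α, d_m, b0_j, μ | normal(0, 1000) | variance 1000 (SD ≈ 31.6 log-odds) | "1000" is read as a variance, the only genuinely vague interpretation; configurable via `PriorSpec.location_variance` |
| κ²_j, φ²_j | p0 δ₀ + (1 − p0) inv-gamma(0.001, 0.001) | — | zero-atom mixture; density w.r.t. (δ₀ + Lebesgue) |
| p0 | Beta(1, 1) | one per variance component | with a single atom indicator each, sharing vs. not is nearly immaterial |
| λ_j | log-normal(0, 1) | median 1 = no difference | alternatives: log-normal(0, 0.5²/2²), uniform on log λ over (−log 10, log 10), log-normal(0,1) truncated to (1, ∞) |
| σ | uniform(0, 2) | SD of log τ² | standard weakly-informative choice for hierarchical SDs |

The truncated prior reproduces, analytically, median 1.96 and 95% range
(1.03, 9.41); it mimics the additive model by allowing only inflation.
The sensitivity family is exposed because the exact shapes of "vague"
λ priors are a modelling judgement; all are centred on (or bounded by)
the null ratio 1.

## Sampler

Metropolis-within-Gibbs, chosen because the zero atom in the variance
priors rules out gradient-based samplers:

* **Exact Gaussian conditionals** for d_m, b0_j, b_jm and μ.
* **Collapsed (φ²_j, b0_j, b_jm) block.**  φ² = 0 collapses every b_jm
  onto b0_j, so naive conditional updates could never re-enter the atom.
  We therefore update φ²_j and b0_j with the b_jm integrated out
  analytically (one-factor covariance, Sherman–Morrison), then redraw the
  b_jm from their exact conditionals — a partially collapsed Gibbs step
  that mixes across the atom correctly.
* **Mixture moves for zero-atom components.**  From the slab: with
  probability ½ propose the atom, otherwise a log-scale random walk.  From
  the atom: propose from an adaptive log-normal pseudo-proposal whose
  location tracks accepted slab values during burn-in.  All Hastings
  ratios are taken w.r.t. the (δ₀ + Lebesgue) dominating measure.
* **Log-scale random walks** for τ²_m (vectorised across meta-analyses)
  and λ_j; reflected-rejection random walk for σ on (0, 2).  α and θ
  updates are vectorised random-walk Metropolis across all trials.
* **Adaptation:** per-parameter step sizes follow a Robbins–Monro recursion
  toward 44% acceptance and are frozen at the end of burn-in, preserving
  the correct stationary distribution afterwards.  λ chains are initialised
  at the 25/50/75% quantiles of the λ prior, which disperses them while
  guaranteeing in-support starts (a start outside a truncated prior's
  support would be frozen in place by the same adaptation).

**Cut rule.**  A meta-analysis with fewer than two trials in either
category of a characteristic cannot separate τ²_m from κ²/λ.  Its trial
likelihood terms are excluded from the κ/λ acceptance ratio while the
current κ/λ value still enters its trial-effect variances — feedback is
blocked in one direction, as with the BUGS `cut` device.  The target is
therefore a cut posterior, not the full joint; `joint_logposterior`
deliberately computes the *full* joint, and the cut lives only in the
update rule.  A full cut-distribution treatment (e.g. multiple imputation
across the blocked factor) is out of scope.

**Convergence.**  The Brooks–Gelman–Rubin potential scale reduction factor
is computed per retained parameter; any value above 1.05 attaches a
warning (never an exception).  Finite-sample noise can push the classic
estimator slightly below 1, so it is floored at 1.  Note that BGR on
spike-and-slab components (φ², κ²) is conservative: chains that agree on
the atom probability but differ in a handful of slab excursions can show
inflated values.

**DIC.**  The total residual (saturated) deviance
D = Σ 2[r log(r/(n p̂)) + (n−r) log((n−r)/(n−n p̂))] is accumulated every
retained iteration; p_D subtracts the deviance at the posterior *mean of
the fitted probabilities* (not of the parameters), which is the stable
choice when the likelihood is non-linear in the parameters.  Draw storage
keeps the per-iteration deviance trace and the running mean fitted
probability per arm rather than the full fitted-probability history, which
is exactly sufficient for DIC and keeps memory flat in chain length.

## Reporting

Posterior medians, SDs and equal-tailed 95% credible intervals of
chain-pooled draws; exp(b0) reported as a relative odds ratio; κ and φ
reported on the SD scale.  The predictive heterogeneity distribution is
summarised by a log-normal fitted to simulated log τ²_new values (one per
retained iteration), with the 95% range from the 1.96 normal multiplier on
the fitted parameters; raw empirical quantiles are exposed alongside.
Implied combined bias for a trial with several characteristics is the
draw-wise sum of the selected b0_j, so its interval reflects posterior
correlations.  Monte-Carlo standard errors of medians use
1.2533·sd/√ESS with ESS from arviz.

## Synthetic data

The generator runs the hierarchical model forwards.  Default shape
choices, made once for realism and testability:

* trials per meta-analysis: 5 + NegBin(r = 0.8, p = 0.1194) truncated to
  [5, 75], which has quartiles exactly (6, 9, 13) and mean ≈ 10.9 —
  matching the skewed size distribution of large Cochrane-style
  collections;
* arm sizes log-uniform on [10, 500], so a "< 100 total participants"
  indicator splits trials roughly in half (that threshold is computed on
  total analysed participants, n_control + n_treat, strict inequality);
* control-arm log odds N(−1, 0.5²) (event risks centred near 27%);
* baseline effects d_m ~ N(−0.3, 0.5²), heterogeneity
  τ²_m ~ log-normal(−2.5, 0.8²), characteristic prevalence 0.45.

`robes_like_config` scales this to 179 meta-analyses and uses
log-normal(−2.94, 1.69²) heterogeneity with b0 = −0.16, λ = 1.88 —
magnitudes typical of fitted meta-epidemiological analyses.

What the generator does **not** emulate: correlated characteristics are
off by default (a Gaussian-copula option is not implemented; indicators
are independent Bernoulli), event rates are homogeneous within trials, and
arm sizes are independent of effect sizes — so passing recovery tests
shows the inference machinery is correct under the model, not that the
model is adequate for any particular real database.

## Test problem sizes

Recovery and invariance checks run on 60 meta-analyses (~700 trials) at
3 chains × 20 000 iterations (5 000 burn-in); the additive-ordering check
on 20 meta-analyses; null calibration on 10 replicates of 30
meta-analyses at 2 × 6 000.  These sizes give Monte-Carlo error well below
the tolerances asserted while keeping the default suite fast.

## Known limitations

* Binary outcomes only; no continuous-outcome likelihoods.
* No interactions between characteristics and no per-meta-analysis κ²_m.
* The cut implementation blocks feedback within an MCMC run; it is not a
  two-stage cut-distribution sampler.
* BGR values on atom-carrying variance components should be read
  alongside the atom frequency, not mechanically against 1.05.
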