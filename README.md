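# metaepi

Bayesian hierarchical models for **meta-epidemiological data**: collections
of meta-analyses used to estimate how binary study-level characteristics —
small sample size, inadequate or unclear sequence generation, allocation
concealment, blinding — are associated with the average intervention effect
and with between-trial heterogeneity.

It is written for biostatisticians running meta-epidemiological analyses of
binary-outcome trial collections (e.g. Cochrane-style databases of
meta-analyses with risk-of-bias assessments), and for methodologists
studying the behaviour of the two competing variance structures on
simulated data.

## The models

For trial *i* in meta-analysis *m*, arm-level event counts are binomial,

```
r_c,im ~ Bin(n_c,im, expit(α_im))
r_t,im ~ Bin(n_t,im, expit(α_im + θ_im))
```

with θ_im the trial's log odds ratio (coded so θ < 0 favours the
intervention).  Given indicators X_ijm for *p* characteristics, trial
effects are normal with

```
mean      d_m + Σ_j X_ijm · b_jm
variance  τ²_m + Σ_j X_ijm · κ²_j           (additive, Welton-type)
variance  τ²_m · Π_j (1 − X_ijm + X_ijm λ_j) (label-invariant)
```

The mean-bias terms are exchangeable across meta-analyses, b_jm ~ N(b0_j,
φ²_j), and the heterogeneity variances follow a log-normal hierarchy,
τ²_m ~ log-normal(μ, σ²), which yields a predictive distribution for the
heterogeneity expected in a new meta-analysis.

The additive structure forces trials *with* a characteristic to be at least
as heterogeneous as those without (the excess is κ²_j ≥ 0).  The
label-invariant structure replaces the sum with a variance *ratio* λ_j > 0,
so heterogeneity can be larger (λ > 1) or smaller (λ < 1), and swapping the
category labels simply maps b0 → −b0, λ → 1/λ.  exp(b0_j) is reported as a
**relative odds ratio (ROR)**; ROR < 1 means effects are exaggerated toward
benefit in trials with the characteristic.

Variance components κ² and φ² carry zero-atom ("spike and slab") priors —
a point mass at zero mixed with an inverse-gamma(0.001, 0.001) slab, with a
Beta(1, 1) prior on the atom probability — so the posterior can express
"no extra variation" exactly.  Sampling is by an adaptive
Metropolis-within-Gibbs scheme (gradient-based samplers cannot represent
the point mass); meta-analyses with fewer than two trials in either
category are blocked, cut-style, from informing κ/λ while still using the
current value in their variances.  Model comparison uses DIC computed from
the residual (saturated) binomial deviance, with the effective number of
parameters evaluated at the posterior mean of the fitted values.

## Worked example

```python
from metaepi import (TruthConfig, generate, ModelSpec, McmcConfig, fit,
                     report_table, percent_change, summarize)

cfg = TruthConfig(n_meta=60, b0=(-0.2,), phi=(0.15,), lam=(2.0,),
                  tau2_dist=(-2.5, 0.8), seed=42)
dataset, truth = generate(cfg)            # 709 trials in 60 meta-analyses
draws = fit(dataset, ModelSpec(),          # label-invariant, log-normal(0,1) prior on lambda
            McmcConfig(n_iter=20000, n_burnin=5000, n_chains=3, seed=7))
print(report_table(draws, dataset).text)
```

This prints (numbers from this exact seed):

```
Model: label_invariant
Parameter               Median      SD              95% CI
b0[X1]                   -0.24    0.06    -0.36 to -0.14
ROR[X1]                   0.79    0.04     0.70 to 0.87
lambda[X1]                1.76    0.52     1.04 to 3.05
phi[X1]                   0.00    0.11     0.00 to 0.34
Predictive tau2_new: log-normal(-2.40, 1.05^2), median = 0.09, 95% range 0.012-0.71
D_res = 1473, p_D = 1030, DIC = 2503
```

Read: trials with the characteristic show intervention effects exaggerated
by about 21% on average (ROR 0.79, true value exp(−0.2) = 0.82), and their
heterogeneity variance is estimated to be 76% larger
(`percent_change(1.76)` → `+76.0`; true λ = 2.0 is inside the 95%
interval).  The φ interval touching zero reflects the zero atom: many
draws put all between-meta-analysis variation in mean bias at exactly 0.

The same analysis from the shell:

```sh
metaepi simulate sim.yaml --out data/
metaepi fit data/dataset.csv --structure label-invariant --out run/
metaepi fit data/dataset.csv --relabel X1 --out run_flipped/   # invariance check
metaepi sensitivity data/dataset.csv --prior lognormal_1 --prior truncated --out sens/
```

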