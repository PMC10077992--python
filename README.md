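# ddpsa — wind-dependent Dirichlet-process source apportionment of PNSD

`ddpsa` apportions **particle number size distributions** (PNSD) — hourly
counts of airborne particles binned by diameter — into an *unknown* number
of latent emission sources.  It is aimed at exposure scientists and
biostatisticians who would otherwise reach for positive matrix
factorization (PMF) but want (i) the number of sources inferred rather than
fixed, (ii) principled uncertainty on every quantity, (iii) missing time
steps handled by the model, and (iv) meteorology informing the allocation.

## Model

For bin `p = 1..P` and reduced time step `t = 1..T`:

```
log y[p,t] ~ Normal(log μ[p,t], σ_p)            multiplicative error
    μ[p,t] = Σ_k λ[p,k] f[k,t]                  profile × contribution
    f[k,t] = s[k,t] · c_t,     log c_t ~ Normal(μ_c, σ_c)
```

Each profile `λ[:,k]` is a probability vector over size bins.  The mixing
weights `s[:,t]` come from a truncated dependent Dirichlet process: with
truncation level `K`,

```
s[1,t] = ξ[1,t],   s[k,t] = ξ[k,t] Π_{l<k} (1 − ξ[l,t]),   ξ[K,t] = 1
ξ[k,t] = w[k,t] · η[k,t],      η[k,t] ~ Beta(1, α)
w[k,t] = exp(−(ν₁k − ws_t)² / 2h₁k) · exp(−sin²((ν₂k − wd_t)π/360) / 2h₂k)
```

so each component is boosted when the wind blows at its preferred speed
`ν₁k` (m/s) and from its preferred direction `ν₂k` (degrees); when `w ≡ 1`
this is an ordinary time-varying stick-breaking DP.  The last component
takes the remaining mass and carries no kernel.  `K` caps, but does not
set, the number of sources: a component counts as a real source only if its
posterior share of the total contribution exceeds a threshold (1% by
default).

Inference is adaptive random-walk Metropolis-within-Gibbs with log / logit /
additive-logistic / circular reparameterizations, posterior-predictive
imputation of missing time steps inside the chain, and split-chain
Gelman–Rubin diagnostics.  Preprocessing reduces a raw hourly panel by
greedy correlation-driven aggregation of size bins (summed) and hours of
day (averaged) at a threshold τ, replaces below-detection zeros by half the
bin minimum, and mean-imputes missing wind.

## Worked example

Fit a truncated model (K = 6) to a synthetic three-source benchmark panel
(15 bins × 150 time steps, ~7% of time steps missing):

```python
import numpy as np
import ddpsa
from ddpsa.postprocess import (source_shares, count_nonempty,
                               match_profiles, posterior_mean_profiles)

spec = ddpsa.benchmark_spec()                       # K_true = 3 ground truth
data, wind, truth = ddpsa.generate_dataset(spec, T=150, seed=42)
data, n_zeros = ddpsa.replace_zeros(data)

config = ddpsa.ModelConfig(K=6)
settings = ddpsa.MCMCSettings(n_iter=4000, burn_in=2000, thin=5, seed=1)
draws = ddpsa.run_mcmc(data, wind, config, settings)

shares = source_shares(draws)
print("posterior mean shares:", np.round(shares, 3))
print("non-empty sources (1% rule):", count_nonempty(shares, 0.01))
perm, sims = match_profiles(truth.state.lam, posterior_mean_profiles(draws))
print("cosine similarity to true profiles:", np.round(sims, 3))
```

which prints

```
posterior mean shares: [0.    0.    0.441 0.    0.281 0.278]
non-empty sources (1% rule): 3
cosine similarity to true profiles: [1.    0.987 1.   ]
```

Three of the six components carry essentially all of the contribution —
the 1% rule recovers the true number of sources — and their posterior-mean
profiles match the generating profiles nearly perfectly.  The remaining
components are empty (shares ≈ 10⁻⁵ or below).

The same pipeline is available from the shell:

```
ddpsa simulate --hourly --days 30 --seed 5 --out-dir sim/
ddpsa preprocess sim/pnsd.csv sim/wind.csv --tau 0.97 --out-dir prep/
ddpsa fit prep/ --iters 4000 --burnin 2000 --thin 5 --k 6 --seed 1 --out-dir fit/
ddpsa summarize fit/ --threshold 0.01 --plots --out-dir summary/
```

`preprocess` writes the aggregation-plan audit (`plan.json`) and a cleaning
report; `fit` writes draws, a manifest and a split R-hat table; `summarize`
writes tidy CSVs of shares, profiles (natural and logit scale), temporal
summaries, correlation matrices and optional figure panels.

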