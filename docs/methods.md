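# Methods

## The model

The package decomposes a particle number size distribution (PNSD) panel
`y[p, t]` (bins × time steps, particles/cm³) into latent sources.  The
observation layer is log-normal with bin-specific sd `σ_p`, so errors are
multiplicative — appropriate for concentrations spanning orders of
magnitude and strictly positive by nature.  The mean factorizes as
`μ = Λ F` with column-simplex source profiles `Λ` (each column is a
probability distribution over size bins) and contributions
`F[k, t] = s[k, t]·c_t`, where `c_t` is the total concentration (log-normal
around `μ_c` with sd `σ_c`) and `s[:, t]` is a simplex of mixing weights.

The weights follow a truncated stick-breaking construction in which the
break proportions are damped by a wind kernel, `ξ[k, t] = w[k, t]·η[k, t]`
with `η ~ Beta(1, α)` i.i.d. over components and time.  The kernel is
Gaussian in wind speed and in `sin((ν₂ − wd)·π/360)`, giving a 360°-periodic
bump with mode exactly 1 at the knots `(ν₁, ν₂)` — the mode must be 1 for
the construction to remain a valid stick-breaking process.  Components are
therefore *a priori* exchangeable in profile but ordered in allocation:
earlier sticks take more mass, and the final component absorbs whatever is
left (`ξ[K−1, t] = 1`) and has no kernel.  `K` is a truncation level, not a
source count; the number of sources is read off *a posteriori* as the
number of components whose share of the total contribution exceeds a
threshold (default 1%).

Assumptions worth keeping in mind: profiles are constant in time (only the
allocation varies); the wind enters only through the allocation, not the
profiles; observation errors are independent across bins and times given
`μ`; and missing time steps are missing at random given the model (they are
imputed from the posterior predictive inside the chain).

## Priors

All Gamma distributions are shape–rate.

| parameter | prior | rationale |
|---|---|---|
| `μ_c` | Normal(0, sd 10) | vague on the log-total scale |
| `σ_c` | Gamma(1, 0.001) | vague (mean 1000) |
| `σ_p²` | Gamma(1, 1) | weakly informative on the variance |
| `Λ[:,k]` | Dirichlet(0.5, …, 0.5) | Jeffreys-type, mildly sparse profiles |
| `α` | Gamma(1, 1); options (1, 10), (1, 0.1) | sensitivity alternatives exposed in `ModelConfig` |
| `η[k,t]` | Beta(1, α) | stick-breaking |
| `1/h₁, 1/h₂` | Gamma(1, 0.001) | vague on inverse bandwidths |
| `ν₁` | Uniform(0, max observed wind speed) | spans the covariate range |
| `ν₂` | Uniform(0, 360) | uninformative on the circle |

`log_prior` is the joint density over the coordinates
(`μ_c, σ_c, {σ_p²}, {Λ columns}, α, {η}, {ν}, {h}, {log c}`): the
measurement-error prior is evaluated on the variance scale as written, the
bandwidth priors are evaluated in h-space with the `1/h` change-of-variables
term, and the hierarchical Normal layer on `log c_t` lives in the prior,
not the likelihood.  The sampler adds its own proposal-side Jacobians on
top of this fixed reference parameterization.

## Preprocessing conventions

* **Bin aggregation** walks bins left to right; the group anchored at bin
  `p` absorbs `p+q` while `corr(y_p, y_{p+q}) ≥ τ`, with the correlation
  always anchored to the *first* bin of the group (not chained pairs).
  Member concentrations are **summed** (so total particle count is
  conserved); the representative size is the geometric mean of member
  midpoints (sizes are log-spaced) with the nm endpoints retained.
* **Hour aggregation** applies the same greedy rule to the 24 hours of day,
  correlating across days, and produces one partition shared by all bins.
  A merge requires the **minimum** correlation over bins to reach τ
  (conservative); a pooled-correlation variant is available via
  `method="pooled"`.  Member hours are **averaged** over non-missing hours;
  a reduced step is missing only when all member hours are.
* Correlations are Pearson on raw (untransformed) concentrations over
  pairwise-complete observations — the minimal convention; whether a log
  transform would change the partition can be probed by transforming the
  input panel first.
* **Zeros** (below-detection artifacts) become half the bin's minimum
  non-zero observed value; the operation never decreases a value and never
  touches non-zero entries.
* **Missing wind** is mean-imputed: arithmetic mean of the degree values
  for direction by default (matching plain mean imputation), with a
  circular-mean option off by default.  Meant for small missing fractions
  (a warning fires above 5%).  When an hourly wind series is aggregated to
  blocks, speed is averaged arithmetically and direction by vector
  (circular) mean, the standard convention for directional data.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs targeting
`log_likelihood + log_prior`, with blocks and reparameterizations:

* profile columns — additive-logistic transform (reference category: last
  bin), whole-column proposals, Jacobian `Π_p λ_p` included;
* `η[k, :]` — logit scale; for fixed `k` the entries at different `t` are
  conditionally independent given everything else, so all T proposals are
  accepted/rejected in one vectorized pass (similarly `log c_t` per time
  step and `log σ_p` per bin).  This keeps an iteration at a few dense
  P×T operations (~3–4 ms on the benchmark);
* scalars `μ_c`, `log σ_c`, `log α`;
* kernel parameters per component: `ν₁` (rejected outside its uniform
  support), `ν₂` as a circular random walk modulo 360, `log h₁`, `log h₂`.

Proposal scales follow a Robbins–Monro recursion toward acceptance 0.234
for the multivariate profile columns and 0.44 for scalar coordinates,
**during burn-in only**; scales are frozen afterwards, so all kept draws
come from a fixed Markov kernel.  Missing cells are drawn each kept
iteration from `exp(Normal(log μ[p,t], σ_p))`.  Missing columns contribute
nothing to the likelihood, so these draws are exact posterior-predictive
samples.

One master seed drives everything; chain `i` uses `seed + 100003·i`.  Two
runs with the same settings are bit-identical (the draws directory of
per-parameter `.npy` files is byte-stable).

Convergence is assessed per chain by the split-half potential scale
reduction factor `R̂ = sqrt(((n−1)/n·W + B/n)/W)`; the CLI warns (but does
not fail) above the conventional 1.1.

## Postprocessing conventions

* Shares are computed **per draw** as `Σ_t f[k,t] / Σ_t c_t` and then
  averaged, so they sum to 1 exactly for every draw.
* The logit profile is `log(λ/(1−λ))` of the posterior-mean profile, with
  values clipped at 1e-12.
* Correlations (inter-source, and with external pollutants) are Pearson on
  posterior-mean contribution series, pairwise-complete in the pollutant.
* Label alignment between runs maximizes total cosine similarity between
  posterior-mean profile columns via the optimal assignment (verified
  against exhaustive permutation search for K ≤ 6).
* The last component has no wind kernel; `kernel_surface` refuses it with
  an explanatory error.

## Synthetic data and the recovery benchmark

`generate_dataset` runs the generative model forward: Beta(1, α) breaks,
kernel weights from an AR(1)-type wind series (log-scale AR(1) speed,
wrapped mean-reverting direction), log-normal observations, then two
artifact layers that mimic field data: the smallest `zero_rate` fraction of
cells is set to exactly 0 (detection-limit artifacts are censored small
values, not random ones), and whole time-step intervals are masked
(instrument downtime hits every bin simultaneously).

The default `TruthSpec` is the recovery benchmark used throughout the test
suite: K_true = 3 sources over P = 15 log-spaced bins (14–600 nm), profiles
built from log-normal bumps peaking near 25 nm (fresh combustion), 70 and
250 nm (aged/urban, bimodal) and 160 nm (secondary aerosol); total
concentration `exp(9.2) ≈ 10⁴` particles/cm³ with log-sd 0.5; measurement
log-sd 0.15; ~7% of time steps missing in two blocks; zero rate 0.16%.
The two kernel-bearing sources sit at 3.0 and 4.5 m/s with broad
bandwidths (h₁ = 10, h₂ = 2) and the concentration is α = 1, chosen so the
three sources contribute comparable shares (≈ 0.46/0.21/0.33).  With a
large α or narrow kernels the truncation remainder dominates the truth,
and the benchmark would then measure the truncation convention rather than
source recovery — a remainder-dominated truth is also exactly the regime
in which the posterior legitimately splits one source across two
same-profile components.

The benchmark fit uses K = 6, 4 000 iterations with half burn-in and
1-in-5 thinning (≈ 16 s single-core); the run-stability check repeats it at
half length.  These sizes are the package's scaled-down analogue of a
production run (the defaults in `MCMCSettings` are 120 000/60 000/60).
What passing the benchmark shows: the pipeline recovers the number, shape
and rough magnitude of well-separated sources from data generated by its
own model.  What it does not show: robustness to model misspecification
(real aerosol dynamics, autocorrelated contributions beyond wind,
non-log-normal noise), performance at the full 28×1604 scale, or
identifiability when sources share profiles.

## Numerical choices

* `η` is clipped to `[1e-12, 1 − 1e-12]` before stick-breaking.
* The wind kernel may underflow to exactly 0 at extreme distances; the
  stick-breaking remainder guarantees `μ > 0` regardless.
* In prior-only runs the vague `σ_c` prior lets `log c` wander by
  hundreds; proposals are clipped at ±700 before exponentiation and
  unobserved cells are excluded by masking, so no overflow can leak into
  accept ratios.
* Circular means are wrapped so floating-point `−ε mod 360` can never
  return 360.0.
* Degenerate inputs raise informative errors: bins with no non-zero
  values, constant chains in `R̂`, all-missing covariates or panels,
  fewer than 2 jointly observed time points for a correlation.

## Known limitations

* **Splitting degeneracy.** When two components carry the same profile the
  likelihood cannot distinguish how their contributions are divided; the
  non-empty-source count can read high in such regimes.  The threshold
  rule mitigates but does not remove this.
* **Share attribution between overlapping profiles** is only weakly
  identified: on the benchmark, matched shares land within ~0.07 of truth
  while profile shapes are essentially exact.
* The direction knots of empty components have a flat circular posterior;
  their random-walk acceptance sits near 1 by construction and is excluded
  from the acceptance-rate calibration checks.
* Wind-direction mean imputation is non-circular by default (by
  convention, to mirror plain mean imputation); use
  `circular_direction=True` near the 0/360 seam.
* The hour-aggregation rule with `method="min"` is conservative; with very
  noisy bins it can refuse merges a pooled estimate would make.
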