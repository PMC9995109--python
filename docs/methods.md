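# Methods

This note documents the statistical models implemented in `itcddm`, the
numerical choices behind them, and their known limitations.

## 1. Scientific setting

The package analyses **intertemporal choice** data: on each trial a
participant chooses between a smaller–sooner (SS) reward and a
larger–later (LL) reward, under a drug versus placebo manipulation. Two
study layouts are supported:

- **within-subject** ("D2"-style): every participant completes a placebo
  and an active session; the drug regressor is coded 0/1 within person.
- **between-subject** ("D1"-style): each participant is randomised to one
  dose group; group-level means are estimated per dose group and the drug
  slope terms drop out of the individual-level model.

Choices and response times (RTs) are modelled jointly with a two-boundary
Wiener diffusion (drift-diffusion model, DDM): evidence accumulates from a
starting point `z·a` with drift `v` and unit diffusion until it hits 0
(SS choice) or `a` (LL choice); the RT is the first-passage time plus a
non-decision time `τ`.

## 2. Wiener first-passage density and simulator

**Density.** The defective first-passage density uses the
Navarro–Fuss (2009) pair of series expansions (small-time and large-time),
switching automatically to whichever needs fewer terms at truncation error
`1e-12`. The lower-boundary density is evaluated directly; the upper
boundary uses the reflection identity (`v → −v`, `z → 1 − z`). The
closed-form upper-boundary absorption probability
`P(upper) = (1 − e^(−2 v a z)) / (1 − e^(−2 v a))` is implemented with an
`expm1` formulation, a series limit `z` as `v → 0`, and an exponential
asymptote for large `|v a|` to avoid overflow.

**Simulator.** Trials are simulated by an Euler scheme with **exact
Brownian-bridge crossing corrections**: each Gaussian one-step transition
is exact for constant drift, and at every step the probability that the
bridge between consecutive interior points crossed a boundary,
`exp(−2 (a − x)(a − x′)/dt)`, is evaluated and a crossing drawn
accordingly. With the default `dt = 1e-3` the residual error is the
within-step timing discretisation (≤ `dt`) plus neglected double
crossings; choice fractions and mean decision times match the closed forms
within Monte-Carlo error at n = 100,000 (verified in the test suite and the
acceptance script). This is substantially more accurate per unit cost than
a plain Euler–Maruyama scheme at a much smaller step. DDM-6 uses a
two-segment piecewise-drift version of the same scheme.

## 3. The six model variants

All variants share a fixed 17-slot coefficient vector so that one compiled
likelihood kernel serves every model. Trial regressors are z-scored
magnitude difference (LL − SS), delay difference, and delay/magnitude sums;
the drug regressor is 0/1.

| Variant | Drift | Bias | Notes |
|---|---|---|---|
| DDM-1 | sigmoid(β₁..β₄ attribute weights), bound ±v_max | β₇ + β₈·Drug + (β₉ + β₁₀·Drug)·Delay_diff | full model |
| DDM-2 | as DDM-1 | fixed 0.5 | no bias regression |
| DDM-3 | constant v = β₅ + β₆·Drug | as DDM-1 | attribute-free drift |
| DDM-4 | as DDM-1 | bias regressed on Delay_sum | |
| DDM-5 | difference of hyperbolically discounted values (raw magnitudes/delays), discount weight k + k_drug·Drug | as DDM-1 | value-first model |
| DDM-6 | duration-weighted time-varying attribute drift with onset asynchrony τ_diff | as DDM-1 | relative-starting-time DDM |

The sigmoidal link is `v = v_max · tanh(v′/2)`, odd and bounded by
±v_max, with `v_max > 0` enforced wherever it acts as a saturation bound.
In DDM-3 the "drift" slots are the drift itself (no link), so they are
sign-free; with the link a zero attribute predictor would pin the drift at
0 and leave `v_max` unidentified. DDM-6's drift is the duration-weighted
average of the early (single-attribute) and late (both-attribute) drift
segments, with the early segment lasting `min(τ_diff, decision time)`;
generation uses the true two-segment process, estimation uses the
weighted-average approximation (exact when τ_diff ≥ RT or τ_diff = 0).

Bias is kept inside (0.02, 0.98): the sampler and the generator reject
parameter draws whose implied bias leaves this interval on any trial, a
guard against boundary-degenerate likelihoods rather than a substantive
prior.

## 4. Hierarchical model and priors

For participant *i* and effect *j* (the variant's active slots):

- `θ_ij ~ Normal(μ_{g(i), j}, λ_j)` — individual coefficients around the
  group mean of the participant's group (single group in the within-subject
  design; one per dose group in the between-subject design).
- `μ_{g j} ~ Normal(0, 1)` — weakly informative on the standardised
  regressor scale.
- `λ_j ~ Gamma(1, 1)` — individual-level SD, shared across dose groups.

These defaults are deliberately generic: regressors are z-scored, so unit
group-mean scale covers the plausible effect range, and Gamma(1,1) puts
prior mass on SDs between ~0.05 and ~3 with mean 1.

## 5. Sampler

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme compiled
with numba:

- Individual coefficients update in three blocks (drift, bias,
  threshold/non-decision) with per-(participant, block) **Haario-style
  adaptive multivariate normal proposals**: proposal covariance from a
  Welford running estimate, Cholesky refreshed every 50 warmup sweeps,
  frozen after warmup; a Robbins–Monro log-step adaptation targets 28%
  acceptance. Two full individual scans run per sweep.
- Group means update by conjugate Gibbs draws; λ updates by log-scale
  random-walk MH with the Jacobian absorbed into the Gamma kernel.
- A **group translation move** (shifting a group mean and all member
  coefficients jointly, accepted on the full group likelihood) breaks the
  mean/individual posterior correlation that otherwise slows mixing.

Proposal step sizes are initialised from a per-slot reference scale
(`REF_SCALE`) reflecting the typical posterior SD of each coefficient type.
Defaults are 2 chains × 20,000 sweeps (10,000 warmup, thin 5);
`MCMCSettings.paper_scale()` switches to a long-run protocol
(2 × 500,000 / 450,000 burn within-subject; 2 × 100,000 / 50,000
between-subject). Convergence is summarised by rank-normalised split-R̂
and ESS (via arviz); fits flag R̂ > 1.01 without aborting.

**Model comparison** uses DIC: `DIC = D̄ + p_D` with
`p_D = D̄ − D(θ̄)`, `θ̄` the posterior mean of the individual-level
coefficients.

## 6. Synthetic data generator

The generator is a first-class component: it draws a task design, samples
individual coefficients around specified group means, and simulates every
trial with the bridge-corrected simulator.

- **Within-subject template** (defaults: 56 participants × 2 sessions ×
  20 trials): SS magnitude 5–250, SS delay 0–30 d, LL magnitude 15–300,
  LL delay 3–90 d, drawn conditionally uniform with strict LL > SS
  dominance in magnitude and delay; session order counterbalanced.
- **Between-subject template** (120 participants in 4 dose groups, 54
  trials): a full factorial of 9 SS magnitudes (0–16, step 2) against LL
  16 at 6 delay levels. The delay levels {0, 14, 30, 60, 90, 180} were
  chosen to span 0–180 d with denser spacing at short delays, where
  hyperbolic discounting changes fastest.
- **Default truths.** `D2_GROUP_MEANS` holds a realistic group-mean
  coefficient set (strong positive magnitude weight, negative delay
  weight, positive drug×magnitude and small negative delay-bias effects);
  `D2_LAMBDA` sets each individual SD at roughly 15–25% of the
  corresponding mean's scale. Individual draws are rejected (≤ 500 tries)
  until they are admissible (positive threshold/non-decision, bias in
  bounds on all trials).

Realism and limits: the generator reproduces the qualitative structure of
real intertemporal-choice data (choice proportions responsive to both
attributes, right-skewed RTs of a few seconds, individual heterogeneity)
but assumes stationarity within session — no fatigue, learning, lapses, or
contaminant RTs.

## 7. Preprocessing

`standardize_attributes` z-scores the attribute differences and sums
(sample SD, ddof = 1) and stores the scaling so fitted coefficients can be
mapped back to raw units. `trim_rts` removes RTs outside the
2.5%/97.5% pooled quantiles (participant-wise scope optional), reporting
counts per group. Trimming is intended for real data, where the tails are
contaminated by lapses and anticipations; on clean simulated data it
truncates the genuine fast tail and biases the non-decision time upward,
so the package's own recovery and predictive checks fit untrimmed
synthetic data.

## 8. Behavioural models

- **Hyperbolic discounting:** `SV = M / (1 + k·D)` with a softmax choice
  rule of inverse temperature β. The Bayesian fit uses a probit-normal
  bounded parameterisation, `k = Φ(raw_k)` ∈ (0,1) and
  `β = 5·Φ(raw_β)` ∈ (0,5), with Normal(0,1) priors on the raw scale —
  bounds wide relative to typical estimates, and the transform keeps the
  posterior proper when a participant's choices are one-sided (such fits
  are additionally flagged).
- **Robust Bayesian t-test** (BEST-style): Student-t likelihood, normal
  prior on means (SD = 1000 × pooled SD), log-uniform σ,
  ν − 1 ~ Exponential(1/29); two-group and paired modes.
- **Mixed GLMs:** hierarchical logistic (choice) and Gaussian (log-RT)
  regressions with per-participant random intercepts and slopes;
  fixed effects ~ Normal(0,5), random-effect SDs ~ half-Normal(1).

## 9. Posterior predictive check

Trials are re-simulated from the individual posterior means (full-draw
mode optional), binned into quintiles of the magnitude and delay
differences per drug condition (stable-sort tie handling; bin sizes differ
by at most one), and observed vs simulation-averaged mean RTs are compared
per cell. The report gives each cell's simulated 95% envelope and a pooled
mean-squared-difference score.

## 10. Parameter recovery protocol

`parameter_recovery` generates datasets from known group-level truths,
refits, and checks whether each truth falls in its 95% highest-density
interval. Coverage is evaluated over **all** group-level parameters — the
group means *and* the per-effect λ SDs — since both are generated ground
truth; with only ~14 means, a single unlucky miss (expected ~5% of the
time per parameter, and more often when the realised sample of 20
participants drifts from the population mean) would dominate the summary.

## 11. Limitations

- DIC is the only model-comparison criterion implemented; it is known to
  under-penalise hierarchical complexity relative to WAIC/LOO.
- The DDM-6 estimation likelihood is the duration-weighted approximation,
  not the exact two-segment first-passage density.
- Inter-trial variability parameters (drift, bias, or τ variability across
  trials) are not modelled.
- The sampler freezes proposal adaptation after warmup but keeps standard
  MH asymptotics; very small datasets (< ~20 trials per participant) can
  still mix slowly in the v_max/attribute-weight ridge of DDM-1-type
  models.
- Non-decision time estimates are sensitive to the fastest observed RTs;
  trimming real data shifts them upward by construction.
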