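# Methods

## Model

Two momentary love ratings per prompt — felt love ("right now") and
expressed love ("since the last survey"), each 0–100 — are modelled as
noisy readings of a latent bivariate Ornstein–Uhlenbeck (OU) process per
person:

    d eta_p(t) = (A_p eta_p(t) + b_p) dt + S_p dW(t)
    y_p(t)     = eta_p(t) + tau_p + eps_p(t)

* `A_p` — 2×2 drift (1/hour), channel order fixed as (felt, expressed).
  Diagonals are inertia (negative = mean-reverting; closer to zero =
  more persistent), off-diagonals the cross-influences; entry [0, 1] is
  the effect of expressed on felt love.
* `b_p` — continuous-time intercept, fixed to zero during inference:
  `tau_p` and `-A_p^{-1} b_p` are not jointly identified, so the whole
  mean level lives in the manifest intercept `tau_p` (scale points).
* `S_p` — diagonal diffusion coefficient (scale points/√hour); `S S'` is
  the instantaneous innovation covariance.
* `eps` — diagonal Gaussian measurement error, standard deviations shared
  across persons (the two items are distinct; nothing in the design
  motivates correlated residuals or person-specific noise).

Between prompts the model is discretised exactly: transition matrix
`exp(A·Δ)`, transition intercept `A^{-1}(exp(AΔ)-I)b`, transition noise
`Q(Δ) = G − exp(AΔ) G exp(AΔ)'` with `G` the stationary covariance solving
`AG + GA' + SS' = 0`. The likelihood of one person's irregular series is
computed by a continuous-discrete Kalman filter started from the
stationary distribution; missing components are handled by dropping the
corresponding measurement row at that prompt. A dense joint-Gaussian
construction of the same density (stack all occasions, build
`Cov(eta(t),eta(s)) = exp(A|t−s|)G`, evaluate one multivariate normal)
serves as an independent oracle; the two agree to 1e−6 on hundreds of
random instances in the test suite.

Bounded 0–100 responses are treated as unbounded Gaussian — no censoring
correction — deliberately matching the original analysis. The
consequences are quantified below.

## Hierarchical structure and priors

Each person contributes an 8-vector on an unconstrained sampling scale:
drift diagonals through a strictly negative softplus map
(`a_ii = −log(1+e^θ)`), diffusion SDs through the positive softplus,
off-diagonal drift and `tau` untransformed. Random effects are
independent normals `θ_pk ~ N(μ_k, σ_k)`. Hyperpriors: group means
N(−0.35, 1) for transformed drift diagonals, N(0, 0.5) for off-diagonals,
N(0, 5) for transformed diffusion, N(50, 20) for `tau`; group SDs
half-normal(1) (half-normal(10) for `tau`); measurement SDs
half-normal(10). The diffusion mean-prior scale of 5 matters: softplus-
scale diffusion consistent with 0–100 EMA data sits well above 1, and a
unit-scale prior there is not weakly informative at the data's scale — it
drags diffusion down and biases the drift. All priors are overridable via
`GroupPrior`.

Drift draws whose determinant is non-positive (non-stationary systems)
receive zero likelihood, so the posterior is conditioned on stationarity
and every retained draw yields convergent lag curves.

## Sampling

No gradient-based PPL is used; the sampler is an adaptive
Metropolis-within-Gibbs scheme written for this model:

* person blocks: 8-dimensional random-walk Metropolis with Haario
  covariance adaptation during warmup, several sweeps per scan;
* group means: conjugate Gibbs;
* group SDs: adaptive Metropolis on the log scale, plus non-centred
  rescale moves (scale all persons' deviations and `σ_k` together);
* coherent group translations, axis-aligned and along adaptively
  estimated 2-D ridge directions (inertia with its channel's diffusion,
  expressed inertia with the expressed→felt effect) — person-level
  likelihood ridges couple these coordinates across the cohort, and
  axis-aligned single-person moves stall across them;
* shared measurement SDs: joint log-scale Metropolis.

One configured "iteration" is one full Gibbs scan (the default 2 chains ×
3000 iterations, first half warmup, therefore performs many elementary
updates per iteration). Initial values come from a gap-aware per-person
VAR regression mapped through a matrix logarithm. Convergence is
summarised by split-R̂ and bulk ESS (arviz) over all group-level
parameters; any R̂ > 1.05 flags the run non-converged in the output and
the manifest — never silently. The per-person Kalman recursion and its
2×2 matrix exponential/Lyapunov algebra are compiled with numba; the
closed-form path is verified against the scipy-based reference filter.

Two group summaries are emitted: the default averages person-level
natural-scale drift entries per draw (population mean of person
parameters); the alternative transforms the group-mean transformed
parameters. Person point estimates are posterior means of natural-scale
drift entries.

## Evidence statistics

Bayes factors for correlations use the exact sampling density of r given
(ρ, n) under bivariate normality (hypergeometric form) with a symmetric
stretched-beta(1/κ, 1/κ) prior on ρ, κ = 1 (uniform) by default, computed
by adaptive quadrature; values agree with the published defaults of
standard Bayesian-correlation software to well under 1%. Evidence labels:
BF10 ≤ 1 favours the null, (1,3] anecdotal, (3,10] substantial, >10
strong (boundaries closed from above). The power analysis inverts the
exact power function of the two-sided t-test of ρ = 0; the exact
distribution matters — it returns a minimum n of 46 for ρ = 0.4 where the
Fisher-z approximation gives 47. A vectorised Monte-Carlo simulation of
the test is included as an independent check. Sex is coded Male = 0,
Female = 1 and enters the same product-moment formula (point-biserial).
No multiple-testing adjustment is applied across the 4×4 grid, matching
the per-cell reporting convention.

## Synthetic cohorts

The generator emulates the study protocol: 28 days × up to 6 prompts/day,
uniform within a 09:00–21:00 waking window with 30-minute minimum spacing
(the protocol states only "regular waking hours"; these values make six
spaced prompts feasible). Compliance is Bernoulli per prompt with a
beta-distributed per-person rate (mean 0.93, SD 0.087), calibrated so
completed surveys average ~157 with a between-person SD of ~15 — a single
shared rate cannot reproduce that SD (binomial SD would be ~3). Person
parameters are drawn around the reported group drift means with
rejection to stationarity; person-mean levels use the reported means/SDs
(felt 68.44 ± 15.23, expressed 64.62 ± 17.63). Latent states are
simulated by exact OU transitions; responses add measurement noise and
are clipped to [0, 100] (clipping, not truncation-resampling, mirrors the
instrument's bounds and deliberately mismatches the Gaussian measurement
model; under defaults it affects ~4.7% of observations, logged per run).

Diffusion defaults (0.9, 5.3 scale-points/√hour) and measurement SD (2.5)
balance three constraints that cannot all be met with larger spreads: the
fixed between-person spread of mean levels, keeping clipping below 5% of
observations, and keeping the fast expressed channel's latent variance
above its measurement noise so its inertia is identifiable at 2–3-hour
prompt gaps.

Trait variables are generated on their summary scales around the reported
means/SDs. Targeted trait–dynamics associations (default: flourishing
with felt-love inertia at r = 0.411) use mixing noise orthogonalised
against the standardized generating feature, so the synthetic cohort's
*sample* correlation equals the target exactly (the published value is
itself a sample statistic); scale clipping attenuates it slightly. An
item-level mode exists for flourishing (8 items summing to the score) to
exercise trait scoring.

What the generator does not emulate: diurnal or weekend structure,
missing-not-at-random prompts, within-prompt item nonresponse by default,
correlated random effects, or mean–variance dependence near the scale
bounds. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model-plus-clipping world, not robustness
to every feature of real EMA data.

## Data cleaning

Per person, after sorting: the first completed survey is removed (the
expressed item refers to a previous survey that does not exist), then a
forward scan removes any record less than one minute after the previously
retained record; times are re-expressed in hours from the first retained
record. Persons with fewer than 3 retained records are excluded with a
warning — fewer cannot inform a bivariate dynamic model. Both rules are
idempotent in already-clean mode, and removal counts are logged.

## Numerical choices

Matrix exponentials use scipy's dense algorithm in the public API
(eigendecomposition appears only as a test oracle) and a closed-form 2×2
formula inside the compiled filter. The 3×3 stationary-covariance system
has determinant 4·tr(A)·det(A) and is solved in closed form; degenerate
proposals are rejected rather than raised. The joint-Gaussian oracle adds
1e−8 jitter once before declaring a covariance non-positive-definite.
Peak-lag search scans a dense grid over (0, 24] h, refines with bounded
scalar minimisation to better than 0.01 h, and returns none when the
cross-effect is identically zero. Bayes-factor quadrature targets 1e−9
relative error with an integration breakpoint at the observed r.

## Parameter recovery and known limitations

A scaled-down recovery study (20 persons × ~60 occasions — the rough
per-person count the model family is reported to need — 2 chains × 1500
iterations) is part of the acceptance tests. The credible intervals
cover most generating drift entries in most replicates, but two stated
bounds fail under the default generating conditions, and ablations
pin the cause on the bounded scale:

* With clipping disabled (all else identical), every tried replicate
  covers 4/4 drift entries with small, sign-varying bias.
* With clipping active, the expressed-love inertia posterior mean is
  biased fast (≈ −0.2) and cross-influence is attenuated; at ~60
  occasions this exceeds the intended |bias| < 0.15 and costs CI
  coverage in some replicates.
* At the full 28-day design (~157 occasions), diagonal drift bias
  vanishes (< 0.02) even with clipping.

This is a property of fitting the no-censoring Gaussian observation model
to bound-clipped data at short series lengths, not of the sampler (it
reproduces across sampler-effort settings and chain lengths). Users
analysing real sliding-scale data with appreciable mass at the bounds
should expect the same effect; a censored-observation likelihood is the
natural extension and is out of scope here by design.

Other limitations: random effects are independent across parameters (no
group-level correlation matrix); measurement noise is shared across
persons; the expressed channel's fast dynamics are weakly identified at
2–3-hour prompt spacing, so its posterior has a heavy fast-reversion tail
and mean summaries of it are less stable than medians.
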