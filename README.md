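# lovedyn

Continuous-time dynamics of feeling and expressing love in daily life.

`lovedyn` analyses intensive longitudinal (ecological momentary assessment,
EMA) data in which people repeatedly rate, at irregular random times, how
loved they feel right now and how much love they have been expressing, each
on a 0–100 sliding scale. It is written for affect-dynamics researchers who
want the full chain — data cleaning, hierarchical continuous-time
state-space estimation, derived inertia/cross-influence curves, and
trait-association statistics — as a reproducible pipeline with a matching
synthetic-data generator, so every stage is testable without access to the
original cohort.

## Model

The latent state **η**ₚ(t) = (felt, expressed) of person *p* follows a
bivariate Ornstein–Uhlenbeck process

  d**η**ₚ(t) = (**A**ₚ **η**ₚ(t) + **b**ₚ) dt + **Σ**ₚ d**W**(t),

observed at prompt times with a manifest intercept and Gaussian noise,
**y**ₚ(t) = **η**ₚ(t) + **τ**ₚ + **ε**ₚ(t). The drift matrix **A**ₚ
(units 1/hour) carries each channel's *inertia* on the diagonal and the
*cross-influences* off the diagonal; exp(**A**ₚΔ) gives the implied
regression of the state on itself Δ hours earlier, the lag curves whose
diagonal entries decay from 1 and whose off-diagonals rise and fall.
Because prompts are irregular, the exact likelihood comes from a
continuous-discrete Kalman filter (matrix-exponential transition,
Lyapunov-equation stationary covariance). Person-specific parameters get
independent normal random effects on an unconstrained scale inside a
hierarchical Bayesian model sampled by an adaptive Metropolis-within-Gibbs
scheme, with split-R̂/ESS diagnostics.

Trait associations (sex, general happiness, flourishing, emotional
well-being against the four drift entries) are summarised by Pearson
correlations with default two-sided Bayes factors: a stretched-beta
(width 1) prior on ρ and the exact sampling density of r given (ρ, n),
integrated by adaptive quadrature. The same exact density drives the
correlation power analysis.

## Worked example

```
$ lovedyn power --rho 0.4
minimum n = 46 (power 0.8023)
```

Forty-six participants suffice to detect a medium (ρ = 0.4) correlation at
two-sided α = 0.05 with 80% power under the exact sampling distribution of
r (the Fisher-z approximation would say 47).

```
$ lovedyn simulate --n-persons 8 --days 6 --seed 7 --out-dir demo
$ lovedyn dynamics --drift -0.065 0.820 -0.038 -0.900 --out demo/curves.csv
expressed_to_felt: peak 0.712 at 2.79 h
felt_to_expressed: peak -0.033 at 2.79 h
```

At the group-level drift used here, expressing love raises subsequent felt
love with the effect peaking 2.8 hours later (entry 0.71 of exp(AΔ)),
while felt love slightly suppresses later expression (−0.03).

```
$ lovedyn fit demo/ema.csv demo/traits.csv --chains 2 --iterations 400 \
      --seed 1 --out-dir demo/out
$ head -5 demo/out/group_summary_rendered.csv
feature,mean,95% CI
felt love inertia,-0.099,"[-0.152, -0.050]"
expressed love inertia,-1.353,"[-2.201, -0.764]"
expressed→felt cross-influence,0.924,"[0.721, 1.138]"
felt→expressed cross-influence,-0.097,"[-0.203, 0.033]"
```

Each row is the posterior mean and equal-tailed 95% credible interval of a
group-level drift entry (a short demonstration run like this one is
flagged `"converged": false` in `demo/out/manifest.json`; real analyses
use the default 2 chains × 3000 iterations). `associations.csv` holds the
4 × 4 trait grid as `r[BF10]` cells with an asterisk marking Bayes factors
above 10, e.g. `0.347[0.587]`.

The same steps are available from Python:

```python
import lovedyn as ld

ds = ld.simulate_cohort(n_persons=52, seed=0)      # 28-day protocol
series = ld.clean_series(ds.ema)                   # drop initial + <1-min records
post = ld.fit_hierarchical(series)                 # 2 chains x 3000 iterations
ld.summarize_group(post)                           # drift means + 95% CIs
```

## Input formats

EMA CSV: columns `person_id,timestamp,felt,expressed` with ISO-8601
timestamps and 0–100 (or empty) responses. Trait CSV: one row per person
with `person_id`, `sex` (Male = 0, Female = 1) and either scored summaries
(`happiness` mean of 4 items on 1–7, `flourishing` sum of 8 items on 1–7,
`well_being` mean of 4 items on 1–6 after reverse-keying) or the raw item
columns (`happiness_1..4`, `flourishing_1..8`, `well_being_1..4`), which
`score_traits` scores.

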