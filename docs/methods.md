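# Methods

## Model

Each disease is analyzed independently. For sex class *i* (a subset of
{F, NF, M, NM}; pyometra has only the female classes) with `total_i` dogs
and `cases_i` affected,

    cases_i ~ Binomial(total_i, p_i),    logit(p_i) = η_i.

The class log-odds are exchangeable around an unknown per-disease level μ:

    η_i | μ, σ ~ Normal(μ, σ²),   μ ~ flat,   σ ~ half-Cauchy(0, 25).

The flat level is integrated out analytically, giving the proper
exchangeable prior on the effects

    p(η | σ) = (2πσ²)^-((k-1)/2) · k^(-1/2) · exp(−Σ(η_i − η̄)² / 2σ²),

so the sampled state is (η₁…η_k, log σ). Two consequences matter:

* **Shrinkage is toward the pooled disease log-odds**, not toward p = 0.5.
  Classes whose raw rate sits far from the disease mean with few cases
  (e.g. six lupus cases among 9,133 intact females) are pulled in
  noticeably; well-populated classes move negligibly. This is what
  stabilizes risk ratios for rare conditions, and it is a deliberate
  design choice: with effects centered at zero instead, the fitted scale σ
  would inflate to the magnitude of the log-odds themselves (≈5–7) and
  shrinkage would vanish, leaving crude ratios inflated by ratio-of-draws
  skew. The shrinkage invariant tested is therefore "posterior-mean
  log-odds lies between the empirical class logit and the pooled disease
  logit".
* With a single class the effect prior is flat, so the posterior of p is
  Beta(cases, total − cases) and its mode is the MLE — a convenient exact
  check for the quadrature oracle.

Risk quantities are formed draw-by-draw (`RR_F = p_NF/p_F` per retained
draw, then averaged), so the reported point estimate is the posterior mean
of the ratio, its SD the posterior SD, and the interval the equal-tailed
2.5/97.5% quantiles. A quantity is flagged significant when that interval
excludes 1; this is the operational reading of the significance markers in
the source analysis, which reports no separate frequentist test.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n_chains` | 4 | independent MCMC chains |
| `n_total` | 20,000 | draws per chain, warm-up included |
| `n_warmup` | 5,000 | discarded initial draws |
| `thin` | 20 | keep every 20th post-warm-up draw (3,000 retained total) |
| `prior_scale` | 25 | half-Cauchy scale of σ (log-odds units; weakly informative) |
| `master_seed` | — | root of all randomness |

The MCMC protocol defaults are the study's own. `prior_scale = 25` is far
above any plausible between-class spread in log-odds (observed spreads are
0.3–1.6), so the hyperprior is effectively uninformative about σ except
for regularizing the σ → ∞ direction.

## Sampler

Componentwise adaptive random-walk Metropolis on (η, log σ):

* **Initialization**: continuity-corrected empirical logits
  `logit((cases+0.5)/(total+1))` per class, σ = 1, jittered N(0, 0.1²) per
  chain. Chains and all innovations derive from `master_seed` via
  `SeedSequence`, so identical inputs give bit-identical draws.
* **Adaptation**: per-chain, per-coordinate proposal scales follow a
  Robbins–Monro recursion toward 0.44 acceptance during warm-up only;
  scales are frozen afterwards, so the retained draws come from a valid
  fixed-kernel chain.
* **σ on the log scale** with the Jacobian added; σ ≤ 0 is impossible by
  construction, and the likelihood uses `logaddexp(0, η)` so arbitrarily
  large |η| cannot overflow.
* The binomial coefficients are constant in the parameters and omitted
  inside the sampler (they cancel in Metropolis ratios); the public
  `log_likelihood` includes them.

Convergence is assessed with the classic (unsplit) Gelman–Rubin potential
scale reduction factor on the retained draws, per parameter, with the
adequacy threshold 1.05. The split-chain and rank-normalized variants
postdate the protocol being reproduced; the unsplit statistic is the one
specified, and the pipeline flags (or fails, under `--strict`) any disease
with PSRF ≥ 1.05. With identical chains the statistic attains its floor
√((n−1)/n) < 1, which the tests pin down.

## Quadrature oracle

For one- and two-class tables the exact posterior is integrated on a dense
grid: η axes span ±12 posterior-SD-equivalents around the empirical logits
(always including the pooled logit ± 2), σ on a log grid over [1e-6, 1e5].
Two numerical points deserve note:

* The marginalized prior behaves like σ⁻¹·exp(−(η₁−η₂)²/4σ²) — an
  *integrable* singularity along η₁ = η₂ as σ → 0. A pointwise Riemann sum
  gives the grid diagonal finite weight on that singularity and diverges
  logarithmically in the lower σ limit. The Gaussian factor is therefore
  cell-averaged exactly in the difference coordinate (an erfc difference),
  which bounds the integrand and converges under refinement (posterior
  means stable to ~1e-6 when the resolution is doubled).
* Any mass on the grid boundary above 1e-6 raises an error rather than
  silently truncating the posterior.

The oracle is used only to validate the sampler (agreement within 0.005
absolute on class probabilities is enforced in the tests) and in the
`oracle` CLI subcommand; it is never the production estimator.

## Record preprocessing

`classify_status_at_diagnosis` implements the status-at-diagnosis rule: a
dog neutered on or before its first confirmed diagnosis was neutered when
the disease arose; a dog never neutered, or neutered any time after the
diagnosis, was intact at diagnosis. The 150-day argument documents the
reclassification allowance of the original record-mining protocol (dogs
neutered within 150 days after diagnosis count as intact); with fully
dated records every post-diagnosis neuter is intact regardless, so the
boundary offsets 149/150/151 all classify intact — which the tests
enumerate. Same-day neuter and diagnosis counts as neutered. Aggregation
assigns each dog exactly once: cases to their status-at-diagnosis class,
undiagnosed dogs to their final-status class; empty classes are dropped.

## Synthetic data

The count-table generator draws `cases_i ~ Binomial(total_i, p_i)` with
known p. Default denominators mirror the cohort profile (9,133 / 36,574 /
12,555 / 31,828). The record generator emulates the cohort only as far as
the pipeline consumes it: sex ratio 0.507 female, neuter probabilities
0.80 (female) / 0.717 (male) matching the cohort composition, lognormal
neuter ages with median ≈ 13 months, per-class Bernoulli disease
incidence, and a configurable fraction of diagnoses placed 1–150 days
before the neuter date to exercise reclassification. It deliberately
omits time-to-event hazards, breed structure, referral bias and the
cohort's declining prevalence over calendar years — so passing tests
demonstrate correctness of counting, classification and inference
machinery, not realism of any temporal or breed pattern. A master seed
feeds per-replicate spawned streams, so replicate *k* is reproducible in
isolation.

## Calibration and recovery experiments

Two complementary designs:

* **Fixed truth** (hypothyroidism prevalences, cohort denominators): the
  95% interval for RR_F must cover the generating ratio 3.021 in ≥ 93 of
  100 replicates.
* **Exchangeable truth**: per replicate, class log-odds are drawn
  N(−5.3, 0.5²) — matching the model's exchangeability assumption — and
  per-class interval coverage is pooled over 200 replicates (band
  93–97%), with the posterior-mean RR bias required to vanish within
  Monte-Carlo error (3 SE). The exchangeable design is used for per-class
  coverage because shrinkage estimators are deliberately biased at any
  *fixed* truth far from the pooled level; averaged over an exchangeable
  truth distribution, Bayesian calibration is the correct expectation.

These experiments run with shortened chains (2 chains, 2,600 draws, 600
warm-up, thin 2 → 2,000 retained draws), a problem size chosen so the
whole suite remains quick while 95% intervals are still well resolved;
the full-protocol properties are exercised separately on the cohort fits.

## Known limitations

* Quantities whose 95% interval grazes 1 can flip significance between
  runs; the cohort's lupus female OR/RR (interval edge ≈ 1.0–1.1) and
  hypoadrenocorticism female OR/RR (edge ≈ 0.98) are the borderline rows,
  and the reproduction test treats interval edges within 0.05 of 1 as
  borderline rather than asserting the flag.
* The quadrature oracle is limited to two classes (dense grids beyond
  that are wasteful); four-class fits are validated instead through
  exchangeability, shrinkage-direction, large-count-consistency and
  calibration properties.
* One model per disease: σ is shared across sex classes within a disease
  but never pooled across diseases, and no covariates (age, breed,
  calendar year) enter the model.
* Multiple-testing correction across diseases is intentionally absent,
  matching the analysis being reproduced.
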