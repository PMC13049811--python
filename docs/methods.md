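# Methods

## Model

Each arm's outcomes are binomial. Inference is parameterised as
`(θ, β) = (logit(p_A), log OR)` with independent normal priors; `p_B` is
always the derived quantity `expit(θ + β)` and never carries a prior of its
own. The printed baseline prior "N(0, 0.3)" is interpreted as **(mean,
precision)**: precision 0.3 (sd ≈ 1.826) closely matches the logit
transform of a uniform(0,1) prior on `p_A` (variance π²/3 ≈ 3.29 →
precision ≈ 0.30), whereas sd 0.3 would contradict that construction.

Priors on the odds ratio are stored as normal distributions on the log
scale only; probability-scale summaries are always derived. An OR credible
interval `[1/u, u]` converts to `σ = ln(u) / z`, with `z` the two-sided
normal quantile at the configured credible level (default 0.95, a
documented knob — the neutral interval's level is not intrinsically fixed
by its definition, and 95% is assumed for uniformity with the sceptical
priors).

| prior | OR 95% CrI | σ on log(OR) |
|---|---|---|
| neutral | 1/30 – 30 | 1.7353 |
| moderate sceptical | 0.82 – 1.22 | 0.1015 |
| extreme sceptical | 0.92 – 1.08 | 0.0393 |

## Posterior computation

Decision quantities are tail probabilities of Δ = p_B − p_A:
`Pr(Δ > 0)`, `Pr(Δ < 0)` and the indifference mass `Pr(|Δ| < δ)` with
δ = 0.01. The literal event |Δ| > 0 has probability 1 under a continuous
posterior, so the efficacy rule uses the directional reading
`max(Pr(Δ>0), Pr(Δ<0)) ≥ S`.

Two backends:

* **approx** (default): Laplace approximation. Damped Newton ascent on the
  strictly concave log-posterior of (θ, β) (analytic gradient/Hessian,
  convergence at gradient norm < 1e-9, at most 100 iterations), then
  `n_draws` i.i.d. draws from the bivariate normal at the mode with
  covariance `(−H)⁻¹`, transformed to (p_A, p_B, Δ). 10,000 draws per
  analysis by default. Degenerate counts (0 or all successes) need no
  special-casing: the normal priors keep the mode finite.
* **sample**: independence Metropolis–Hastings targeting the exact
  posterior, proposing from the Laplace normal with standard deviations
  inflated ×1.1 (covering the target's mild skew), burn-in 1,000, no
  thinning. A random-walk Metropolis variant was implemented first but its
  autocorrelation (effective sample size ≈ 6k of 50k draws) left too much
  Monte-Carlo noise to resolve 0.01-level disagreements with the
  approximation; the independence sampler is near-i.i.d. while remaining
  exact via the MH correction.

Validation: on a grid of counts (n/arm ∈ {50, 200, 1000}; observed rates
0.5 vs {0.40, 0.50, 0.55}) × all three priors, both backends agree with a
dense 2-D quadrature of the unnormalised posterior to within ±0.01 on all
decision probabilities (test suite, 50,000 draws). The Laplace tail-
probability bias is ≤ ~0.006 even at the first 50/arm look, well below the
Monte-Carlo wobble the stopping rules already tolerate from 10,000 draws.

Accuracy note: the extreme sceptical prior (σ = 0.039) is *not* swamped
even by 10,000 observations per arm when the observed log-OR is ~0.2; the
posterior means of p_A and p_B then sit visibly between the observed
proportions and equality. This is the exact posterior's behaviour (checked
by quadrature), not an approximation artefact.

## Decision noise at interim analyses

A stopping rule fires when the *estimated* posterior probability crosses
its threshold, so the Monte-Carlo error of the per-analysis estimates is
itself a design property: over hundreds of looks, a noisier analysis
engine crosses thresholds earlier and more often, visibly shifting
operating characteristics in cells decided deep in the race between the
two rules (e.g. S = 99%, or a relaxed E with a sceptical prior).

The historical benchmark for this class of design is a 10,000-iteration
Gibbs (JAGS-style) analysis per look. Running that exact model in JAGS
across representative count regimes gives effective sample sizes of
roughly 2,700–8,000 per 10,000 iterations (harmonic mean ≈ 3,800) for the
decision probabilities. The engine therefore estimates each interim
decision from `posterior_draws × mc_efficiency` independent draws, with
`mc_efficiency = 0.4` by default — i.e. ~4,000 effective draws per
10,000-iteration analysis. The same JAGS runs double as an external check
of the quadrature oracle (means agree to four decimals). Setting
`mc_efficiency = 1` gives the idealised i.i.d.-draw variant; rates in
boundary-race cells then shift by several points (for instance, the
true-equivalence rate at S = 99% under no true difference rises by ~7
points), while well-separated cells barely move.

## Trial engine

Allocation is deterministic 1:1 per batch; per-batch outcomes are drawn as
binomial counts (the sum of the batch's Bernoulli outcomes — only counts
enter the likelihood). No loss to follow-up or outcome delay is modelled;
outcomes are assumed observable by the next look. Rules are checked in the
order equivalence → efficacy, so the theoretical both-rules-met case
resolves to equivalence; the engine records a `both_rules_met` flag so its
frequency can be reported (it is ~0 in practice). Winner on an efficacy
stop is the arm with the higher posterior mean success probability; an
exact tie (measure-zero) falls to arm A with a logged warning.

The cap `max_total_n` must be even (an odd total is unreachable under 1:1
allocation). If the look grid does not land on the cap, the final batch is
truncated so that the last analysis happens at exactly the cap; all preset
designs have caps on the grid, so truncation only affects user-supplied
designs. A trial that reaches the cap without triggering a rule stops as
inconclusive.

Seeds: a trial is a pure function of (design, scenario, seed). The outcome
stream uses `SeedSequence(seed, spawn_key=(0,))`; the posterior draws of
interim *k* use `SeedSequence(seed, spawn_key=(1, k))`. Replicate seeds
derive from a master seed via `SeedSequence((master, replicate_id))`, so
collections are order-independent and bit-reproducible.

## Outcome taxonomy and measures

With Δ_true the true risk difference and δ the indifference half-width,
"perform equally" is operationalised as |Δ_true| < δ (strict inequality;
only the 0-difference scenario of the standard grid falls inside the ±1%
zone, so the boundary convention is inert there but matters for user
scenarios). Inconclusive (cap) trials form their own class rather than
being folded into equivalence. Rates are reported with binomial Monte
Carlo errors √(p(1−p)/n).

Coverage uses the **equal-tailed** 95% interval of the final posterior
draws of Δ (HPD would be a defensible alternative; equal-tailed is chosen
and fixed). Bias is `estimate − Δ_true` averaged over replicates, with the
estimate either the final posterior mean of Δ (prior included) or the raw
difference of observed proportions (prior excluded); a quartile-binned view
by final sample size accompanies the mean. Adoption probability credits
the truly superior arm whenever the final posterior means (or observed
proportions, in `observed` mode) rank it first, across *all* trials
including equivalence/inconclusive ones, using the stored final analysis;
exact ties count ½. The fixed-RCT comparator resolves observed ties by a
fair coin — ties are non-negligible only at very small n, where the
comparator is also checked against exact enumeration of the joint binomial
outcome space.

## Simulation scales and defaults

The scenario grid fixes p_A = 0.50 and varies the absolute difference over
0–5 points, the range where design choices matter for marginal QI
improvements. The headline replication size is 1,000 per cell (MC error
0.95% for a 90% rate); the package's fast profile uses 300–500 replicates
with the approximate backend, widening tolerances per the MC-error formula.
The test suite and the acceptance script run at the fast profile; the CLI
defaults to 1,000.

Design presets store per-arm schedule values; the candidate-design table's
"initial 100 / every 100" counts participants across both arms, i.e.
50/arm, identical to the reference schedule (the two notations are
consistent: 50/arm = 100 total).

## Known limitations

* The simulator models instant outcome ascertainment, perfect adherence
  and no drift in baseline rates; real QI data streams have delays,
  seasonality and clustering that these operating characteristics do not
  capture.
* Only two arms, binary endpoints and 1:1 allocation are supported.
* The Laplace backend's tail-probability error (≲0.01) slightly perturbs
  stopping times relative to exact posterior computation; all reported
  rates carry an explicit allowance for this.
* The design sweep applies no multiplicity adjustment across candidate
  designs — by construction, as the evaluation is exploratory.
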