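# Methods

`oralsim` is a pre-deployment evaluation test bed for online reinforcement
learning algorithms that decide, twice a day, whether to send a user an
engagement message ahead of a scheduled tooth-brushing window. It answers the
question a study team faces before a trial starts: *given only sparse,
no-intervention observational data, which candidate algorithm — which reward
model, and how much pooling across users — should go into the field?* The
package implements the three layers needed to answer that by simulation:
reward-generating environments fitted to brushing data, candidate
Thompson-sampling contextual bandits, and personalization metrics over Monte
Carlo replications of a full incremental-recruitment trial.

## The decision problem

Each user i faces decision times t = 1, …, T (two per day, morning and
evening; T = 140 over ten weeks by default). At each t the algorithm
observes a state

    f = [1, time_of_day, prev_day_brushing, weekend]

with `time_of_day` 1 for evening, `prev_day_brushing` the sum of the previous
day's two rewards scaled into [0, 1] by 360, and `weekend` an indicator under
the convention that day 1 is a Monday (days ≡ 6, 0 mod 7 are weekend days).
It then selects an action A ∈ {0, 1} (send / don't send) with a logged
probability, and observes the reward

    R = min(D, 180)

where D is the subsequent brushing duration in seconds. Truncation at 180 s
avoids rewarding over-brushing; 120 s is the dentist-recommended duration.

## Synthetic data generator

The generator emulates the shape of a small observational brushing study:
32 users, 28 days, two sessions per day, roughly 40 % of sessions with no
brushing at all, and marked between-user heterogeneity. Its defaults *are*
the study conditions for every downstream test.

Per user u: a zero propensity p0_u ~ logit-normal centred at
`zero_prob_mean` (0.40; `zero_prob_user_sd` = 0.7 is the standard deviation
on the logit scale), and a target mean nonzero duration
m_u ~ N(`duration_mean` = 120 s, `duration_user_sd` = 25 s). Per session: a
skip with probability p0_u, otherwise duration round(x²) with
x ~ N(sqrt(m_u − s²), s) on the square-root scale, where s is set from
`duration_within_sd` = 40 s via the delta method
(s = duration_within_sd / (2 sqrt(duration_mean))); subtracting s² inside the
square root makes E[x²] equal m_u exactly. This is deliberately a member of
the `hurdle_sqrt` model class fitted downstream, so the fitting layer can be
tested against data whose generator it can in principle recover.

What the generator does *not* emulate: feature-dependent brushing propensity
(the synthetic zero propensity is constant within user), sensor dropout,
app-opening behavior, or brushing-quality scores. Consequently, passing
tests show that the pipeline is correct and that the algorithm comparison
behaves as expected in a realistically sparse, heterogeneous, zero-inflated
world — not that any candidate will achieve specific reward levels on real
study data.

RNG discipline: one root seed; each user's records come from an independent
substream spawned from it, so enlarging the sample never changes earlier
users' data.

## Environment construction

**Base models.** For each user, three generative model classes of duration
under no action are fit to that user's sessions, all on the feature vector g
(the state above; the nonstationary variants append day_in_study scaled into
[0, 1] by the study length):

- `zip` — zero-inflated Poisson with *latent* intent:
  Z ~ Bern(sigmoid(g·w_b)), D = Z · Poisson(exp(g·w_n)). Fit by maximum
  likelihood (L-BFGS on the exact likelihood, analytic gradient, five
  jittered restarts, tolerance 1e-6 on the log-likelihood).
- `hurdle_sqrt` — observed Bernoulli component (logistic regression of
  D > 0 on g) and a linear model of sqrt(D) on g over nonzero sessions,
  residual sd sigma_n.
- `hurdle_log` — the same with log(D).

The class kept per user is the one with the lowest RMSE between observed
durations and the model's expected duration E[D | g]:
sigmoid(g·w_b)·exp(g·w_n) for `zip`, sigmoid(·)·((g·w_n)² + sigma²) for
`hurdle_sqrt`, and sigmoid(·)·exp(g·w_n + sigma²/2) (the lognormal mean
correction) for `hurdle_log`. RMSE against the *expected* duration (rather
than against simulated draws) was an open design choice; it is deterministic
and is the convention used throughout. Ties break by the fixed class order
zip, hurdle_sqrt, hurdle_log; non-finite RMSEs are excluded with a warning.

Users with fewer than two zero or two nonzero sessions cannot identify both
components; they receive a degenerate model with the Bernoulli component
saturated toward their observed behavior and are flagged.

**Fit checks.** `validate_fit` simulates replicate datasets from a fitted
model on the user's observed feature sequence and compares zero fraction,
mean nonzero duration and within-user variance with the observed records
(between-user variance requires a pool and is reported per dataset by
`summarize_dataset`). The variance convention, fixed here because the terms
are often left undefined: between-user variance is the sample variance of
per-user mean durations; within-user variance is the mean of per-user sample
variances.

**Imputed treatment effects.** The data contain no intervention actions, so
action effects are imputed rather than estimated. An action adds delta_b to
the Bernoulli linear predictor and delta_n to the nonzero-component linear
predictor. Population-level sizes follow the heuristic that a message's
effect should be on the order of baseline feature effects: delta is the
average over users and non-intercept features of |fitted weight|, computed
separately per component. Heterogeneous (per-user) sizes are drawn once,
seeded, from N(population delta, v) where v is the across-user sample
variance of per-user mean absolute non-intercept weights, floored at zero so
that treatment never hurts by construction (a flag disables the floor for
sensitivity analyses). Effects enter as intercept shifts only; a
feature-interacting effect hook exists but is off by default.

Crossing {stationary, nonstationary} base with {population, per-user}
effects gives the four variants S_Pop, NS_Pop, S_Het, NS_Het. Environments
are point-estimated (no posterior over environment parameters) and serialize
to JSON.

## Algorithm candidates

Both candidates are Thompson samplers with mean-zero Gaussian priors of
variance 25 per coordinate (the "uninformative" realization; exact prior
scales are a free design choice and are config-exposed). Emitted action
probabilities are clipped into [0.35, 0.75] to preserve post-study causal
and off-policy analyses; the clip range is asserted at every decision of
every simulated trial.

**BLR with action centering.** The reward model is

    R = f·alpha0 + pi f·alpha1 + (a − pi) f·beta + eps,   eps ~ N(0, eta²)

with pi the logged selection probability. The centered parameterization
makes the advantage term f·beta estimable even under an arbitrary, wrong
baseline model (verified by simulation in the tests). The posterior is
conjugate Gaussian over the stacked (alpha0, alpha1, beta); the update is
the closed form Sigma' = (Sigma⁻¹ + XᵀX/eta²)⁻¹, mu' = Sigma'(Sigma⁻¹mu +
Xᵀr/eta²) on design rows x = [f, pi·f, (a−pi)·f]. The Thompson probability
of sending is analytic: P(f·beta > 0) = Phi(f·mu_beta / sqrt(f·Sigma_beta·f)),
identical in distribution to sampling beta and comparing. The noise variance
eta² is fixed, not learned; by default it is set to the observed variance of
truncated rewards in the data the environment was built from.

**ZIP reward model.** P(brush) = sigmoid(f·w_b + a f·delta_b); duration
given intent ~ Poisson(exp(f·w_n + a f·delta_n)); latent-intent
zero-inflation as in the environment's `zip` class. The posterior has no
closed form; it is approximated by a Laplace approximation at the penalized
MAP. The MAP is found by damped Newton iterations with the analytic Hessian
(ridge-stabilized when indefinite, Armijo backtracking), warm-started
between weekly updates from the previous MAP, with seeded jittered restarts
on cold starts and an L-BFGS fallback; the covariance is the inverse Hessian
at the MAP. The latent-intent likelihood is non-concave, so the Hessian at
the stopping point can be indefinite; its eigenvalues are floored at the
prior precision (1/prior_scale) with a logged warning, so that no direction
of the Gaussian approximation is ever wider than the prior.
Thompson probabilities are Monte Carlo: draw parameters from the Laplace
posterior (100 draws per update by default, refreshed at each update and
frozen between updates) and estimate P(E[R | f, a=1] > E[R | f, a=0]) with
exact ties counted 1/2, so a posterior point mass at zero effect gives 0.5.
Mean comparison (rather than sampled-reward comparison) was an open choice;
it matches the analytic BLR rule, which also compares means.

## Trial engine

A trial draws N = 72 users from the fitted pool *with replacement*, recruits
4 per week (all of a week's recruits start on the week's first day), and
groups users into clusters of k ∈ {1, 4, N} by entry order. Each cluster
runs one algorithm instance on its pooled history; clusters never see each
other's data. Updates are weekly on each cluster's own clock — the first
after the cluster's first members have completed 14 decision times, i.e., at
the end of the cluster's 7th day — and continue while any member is still in
the study; probabilities between updates come from the posterior frozen at
the last update. Cluster-relative (rather than global-calendar) update
clocks were an open reading of the weekly-update rule; cluster-relative
matches the per-cluster phrasing and makes k = 1 and k = 4 behave
identically at entry.

Numerical/performance notes: decisions are vectorized across all active
users per calendar slot; nonzero-component linear predictors are capped at 8
before exponentiation (exp(8) ≈ 2981 s, far beyond the 180 s reward cap) to
prevent overflow in degenerate fits; BLR updates recompute the posterior
from the prior and the full cluster history (exactly equal to sequential
conjugate updating). Within a trial a single generator, consumed in a fixed
user order, drives action and reward draws; user-model sampling uses a
separate substream. Everything is deterministic given the trial seed, and
Monte Carlo sweeps derive disjoint per-trial seeds from the root seed, the
same per-trial seeds for every candidate — so candidate comparisons are
paired across trials.

## Metrics

Per trial: `avg_reward` = (1/N) Σ_i (1/T) Σ_t R_it; `pct25_reward` = lower
25th percentile of the N per-user time averages (linear interpolation
between order statistics — the estimator is config-exposed because the
convention shifts values slightly at N = 72); `checkpoint_rewards` = the
same average over the first t0 decisions for t0 ∈ {20, 40, …, 140}. Across
trials: mean and standard error (sample sd, n−1 denominator, over trials,
divided by √n_trials). The 25th percentile is *not* bounded by the mean in
general; only min ≤ pct25 ≤ max over user averages is guaranteed.

## Problem sizes used in the shipped checks

The packaged acceptance checks run the full trial shape (72 users, 140
decisions, weekly updates) with reduced Monte Carlo replication: 25 trials
per candidate-variant pairing in the test suite's headline comparison and 15
in `scripts/acceptance.py`, against environments fitted to the default
synthetic dataset. Parameter-recovery checks use 50 replicate users of 56
sessions for the environment classes and n = 5000 logged decisions for the
bandit ZIP model; recovery is summarized by the median over the parameter
vector of the absolute relative error of median-of-replicates estimates,
because single Bernoulli-component coefficients are not estimable to 10 %
at these sample sizes (their sampling errors are ~0.1–0.3).

## Known limitations

- Treatment effects are imputed, not estimated; all conclusions are
  conditional on the imputation heuristic.
- eta² fixed at the observed reward variance favors BLR relative to
  learning the noise online.
- The Laplace approximation can be poor early in a trial when cluster
  histories are short; the clip interval bounds the damage.
- The synthetic generator's zero propensity ignores context, so fitted
  non-intercept Bernoulli weights on synthetic data reflect sampling noise;
  the imputed effect sizes inherit that scale (which is the intended
  order-of-baseline-effects behavior, but on real data they would reflect
  systematic structure instead).
- Environments beyond the four variants (greater heterogeneity, lower
  noise, demographic covariates) are out of scope.
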