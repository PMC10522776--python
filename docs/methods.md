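# Methods

## Model

For country *c*, year *t* and age group *a* ∈ {0–4, 5–14, 15–24} the sex
ratio of mortality (male:female ratio of the probabilities of dying) is

    S(c,t,a) = f_a(Q(c,t,a)) · exp(δ(c,t,a)),

where Q is the published both-sex probability of dying and the two factors
separate the *global* association between the sex ratio and the mortality
level from *country-specific* deviation.

**Global curve f_a.** Piecewise linear in (log Q, log S) with flat
extrapolation beyond its end knots. Knots are placed at equally spaced
quantiles (default 1%–99%, 6 knots) of log Q over the estimation grid, so
the flexible part of the curve sits where there is information. Priors:
Normal(0, 1) on the first knot value and Normal(0, 0.1) on second
differences of the knot values — a random-walk-2-style smoothness prior
that shrinks toward local linearity without forcing monotonicity, because
the expected ratio is known to rise as mortality falls and then stabilise
or reverse at very low mortality.

**Country multipliers.** δ(c,·,a) follows a stationary AR(1) process with
mean 0, lag-one correlation ρ ∈ (0,1) and stationary SD τ ≥ 0, with one
(ρ, τ) pair per age group shared across countries. This is the lightest
process that lets multipliers "fluctuate around 1" while pooling
information over time; countries without data revert to the curve with
full prior width. Priors: Uniform(0,1) on ρ, half-Normal(0, 0.5) on τ.

**Observation model.** An observation *i* of source type *j* contributes
log y_i ~ Normal(log S, v_i + σ²_j): v_i is the sampling variance of the
log ratio supplied with the observation (or computed as 1/D_male +
1/D_female from backing death counts via the Poisson delta method), σ_j is
a source-type non-sampling SD with a half-Normal(0, 0.5) prior. Decimal
reference years are assigned to the nearest model year; ties break to the
earlier year.

Each age group is fitted independently with its own curve, (ρ, τ) and
σ_j's; the 0–4 configuration is the reporting-group-level simplification of
the classical under-5 sex-ratio model, and the same unified machinery
serves 5–14 and 15–24.

## Inference

Conditional on the curve values and hyperparameters the model is
linear-Gaussian, and the implementation exploits that exactly rather than
approximating:

1. Observations in the same (country, year) cell are collapsed to a
   precision-weighted pseudo-observation (with the exact δ-independent
   likelihood constant retained).
2. The AR(1) multipliers are integrated out analytically with a scalar
   Kalman filter (stationary initialisation N(0, τ²)), giving the exact
   marginal likelihood of (curve values, ρ, τ, σ_j) — roughly 12 free
   parameters per age group.
3. That marginal posterior is sampled with emcee (affine-invariant
   ensemble; differential-evolution moves, which mix much faster than
   stretch moves at this dimensionality). Defaults: 28 walkers, 1500
   burn-in and 1200 retained steps, thinned evenly to 500 draws.
   Transformed parameters (logit ρ, log τ, log σ_j) carry the appropriate
   Jacobians.
4. For each retained draw, multiplier trajectories are drawn exactly by
   forward-filter backward-sampling; S follows as f(Q)·exp(δ) on the full
   grid.

Split-chain R-hat (walkers treated as chains) is computed per parameter
with arviz; values above 1.05 produce a logged warning and a `converged:
false` flag in the diagnostics, never a silent failure. Fits are
bit-reproducible given the configured seed. Any subset of
{curve, ρ, τ, σ_j} can be fixed, in which case sampling reduces to the
exact conditional FFBS draws — this is also how the conjugate-case oracle
tests work.

**Quantiles.** All summaries use the median and the 5th/95th percentiles
(90% uncertainty intervals) under the linear-interpolation ("type 7")
order-statistic convention; this is fixed so that interval tests are exact.

**Sex-specific rates.** With exposure share w (male share of entrants; for
0–4, SRB/(1+SRB) with SRB defaulting to 1.05):

    q_female = q_total / (w·S + 1 − w),   q_male = S · q_female,

which satisfies the conservation identity w·q_male + (1−w)·q_female =
q_total to machine precision. When the totals carry uncertainty draws, each
sex-ratio draw is paired with one total-mortality draw after an independent
seed-driven shuffle — independence between the two sources is assumed
(nothing stronger is justified), and marginal uncertainty reflects both.

**Excess female mortality.** Male mortality is the reference: per draw,
q_male is taken at its estimated level, the expected female rate is
q_male/S_expected with S_expected = f(Q) (no multiplier), and excess =
estimated − expected female rate, so q_f_est/q_f_exp = S_exp/S_est exactly.
Excess deaths convert the estimated:expected ratio R into counts as
deaths_female_est × (1 − 1/R). A country-year is outlying iff the posterior
probability of positive (or of negative) excess is ≥ 0.95 and the absolute
median excess exceeds 0.001 (one death per 1000); both thresholds are
arguments.

**Aggregation.** Regional death counts are within-draw sums of country
draws (counts = rates × sex-specific entrants); regional sex-specific rates
apply the regional death shares to the exposure-weighted regional total,
which conserves the total exactly. Crisis-related deaths enter, if at all,
as user-supplied additive sex-specific counts after modelling.

**Validation.** A fraction (default 20%) of observations is held out —
uniformly at random within each age group by default, or the most recent
fraction with `scheme="recent"` to probe short-term projection — the model
is refitted on the remainder, and 90% predictive intervals (posterior of
log S plus each record's full observation noise, with σ_j taken from the
refit posterior medians) are checked against the held-out log ratios.

## Synthetic data

The generator emulates the full input stack with known truth: total
mortality declines exponentially per country (log q0 uniform over an
age-appropriate range, annual decline 1–4%, log-scale noise SD 0.03,
clipped to (1e-6, 0.9)); the true surface is the default curve times
stationary AR(1) multipliers; observations arrive Poisson per cell with a
source mix, source-specific sampling-SE ranges (VR 0.01–0.05, FBH/SBH
0.05–0.15, CENSUS 0.03–0.10 — registration data carry little stochastic
error, survey ratios much more) and additive Normal sampling and
non-sampling errors on the log scale.

Default study conditions: 60 countries, 1990–2021, age group 0–4, ρ = 0.9,
τ = 0.1, σ = (VR 0.025, FBH 0.05, SBH 0.075, CENSUS 0.10), source mix
0.4/0.3/0.2/0.1, one expected observation per country-year (~2000
observations). These defaults define the recovery and calibration studies
in the test suite and the acceptance script.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: systematic (non-zero-mean) source biases,
sex-differential registration completeness, crisis mortality shocks,
cross-age-group correlation of deviations, and totals that are themselves
biased. The noise structure matches the model's own assumptions by design,
so the recovery tests are well-posed tests of the machinery, not of
robustness to misspecification.

## Numerical choices and edge cases

* Extreme-observation filter: default bounds [0.2, 5.0] on the ratio,
  symmetric on the log scale; the removed share is reported per age group
  (real-database analyses report it below 2.4%).
* τ = 0 makes the multiplier process degenerate at zero; the density is 0
  for an all-zero series and −∞ otherwise, and FFBS guards the 0/0 with
  explicit zero gains.
* A zero total observation variance is an error (degenerate likelihood),
  as is an implied q_male ≥ 1 in the sex split (inconsistent inputs).
* Interpolation design matrices reproduce `np.interp` exactly, including
  flat extrapolation, so curve evaluation is invariant under adding a
  collinear knot.
* The holdout split sizes are `round(fraction · n)` within each age-group
  stratum.
* Country-years with no observations are handled by the filter/FFBS
  prediction steps; no imputation occurs.

## Problem sizes

The default study (60 countries × 32 years, ~2000 observations, 500
posterior draws) fits in about one minute on a single CPU; the acceptance
script, which runs the study twice (full fit plus holdout refit), completes
in a few minutes. Unit and property tests use smaller grids (6–20
countries, 8–12 years) chosen to exercise every code path quickly while
Monte-Carlo checks retain enough draws (10⁴–2·10⁵) for three-standard-error
assertions.

## Known limitations

* Fitting is per age group; the cross-age correlations present in real
  data are neither modelled nor used.
* Totals enter the likelihood at their point values; their uncertainty
  propagates only into derived sex-specific quantities.
* The exposure weight is fixed at age-group entry (births via SRB for 0–4,
  population shares otherwise); the within-interval survivorship
  refinement is ignored, a second-order effect at these mortality levels.
* No covariates are used, and projections beyond roughly two decades are
  outside the model's validated range.
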