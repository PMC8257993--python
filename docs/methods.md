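# Methods

This note records the models, the numerical choices behind them, the
defaults of the synthetic-data generator, and what the test suite does and
does not establish.

## Conjugate outcome models

Binary outcomes are arm-specific binomials with Beta priors. "Flat prior"
means Beta(1, 1); Jeffreys Beta(0.5, 0.5) is available via the prior
parameters but is not the default. Continuous outcomes summarised as
(mean, SD, n) get the standard noninformative treatment: the posterior of
each arm mean is x̄ + (s/√n)·t(n−1). Posterior intervals are central
(equal-tailed) by default with a highest-density option for Beta rates;
dose-comparison probabilities (pp) do not depend on the interval
convention, which is why they are the quantities the package leans on.

**How pp is computed.** The deterministic path integrates
∫ F_high(x) f_low(x) dx by adaptive quadrature (or the exact finite-sum
identity when all Beta parameters are integers — used inside simulation
loops where speed matters, and as an independent oracle in tests). The
sampling path is *stratified conditional Monte Carlo*: draw the low-arm
parameter by stratified inversion (one draw per equal-probability stratum,
jittered, seeded) and average the exact conditional CDF of the high-arm
parameter. Conditioning removes the Bernoulli indicator noise and
stratification removes most of the remaining variance, so 40,000 draws sit
within ~1e-4 of quadrature rather than the ~2.5e-3 standard error naive
indicator averaging would give. Burn-in has no effect on this i.i.d.
scheme; the settings object retains the burn-in/keep split for the Gibbs
and Metropolis samplers that do need it.

**Missing binary outcomes** are multiply imputed inside the model: each
posterior draw of the rate fills the missing outcomes Bernoulli at that
rate, and summaries are marginal over the resulting completed-data
posteriors. Imputation at the posterior rate is mean-preserving, so pp
values move little; with zero missing the machinery reduces exactly to the
conjugate update. The published posterior means for some outcomes reflect
an imputation over full enrolment denominators whose mechanics are not
printed; pp values, which are robust to this, are what the acceptance
checks target.

**Number needed to treat** is round(100 / (rate_low% − rate_high%)),
signed, with equal rates raising an error rather than returning infinity.

## Gestational-age mixture model

Three normal components with strictly ordered means; means and SDs shared
across arms, mixing weights arm-specific. Sharing components borrows
strength across arms while still yielding arm-specific EPB rates; a fully
arm-separate fit is available by fitting each arm's data separately.

Priors (all configurable): component means Normal at (180, 238, 273) days
with SD 20; component variances inverse-gamma with shape 2 and scale 225
(prior mean SD ≈ 15 days); weights Dirichlet(1, 1, 1) per arm. The
inverse-gamma variance prior keeps every conditional in closed form so the
sampler is pure Gibbs; a half-normal SD prior would need a Metropolis step
for no practical difference at these sample sizes.

Label switching is handled by re-sorting components by mean after every
sweep and permuting SDs and weights identically — a relabelling that
leaves the likelihood unchanged (asserted in tests). Chains (default 4)
run sequentially from distinct substreams of one seed; split-R̂ on means
and weights is computed via arviz and reported, not enforced. Degenerate
inputs (fewer than three distinct gestational ages, or fewer than 30
observations in an arm) raise immediately rather than producing a
zero-variance component.

The fitted mixture is dichotomised analytically:
rate = Σ w_k Φ((238 − μ_k)/σ_k), checked against numeric CDF integration
to 1e-6. Gestational ages are exact observed days; there is no censoring.

## Adverse-event model

Per category j: events are binomial with logit p_low = θ_j and
logit p_high = θ_j + δ_j; θ_j ~ N(μ_θ, τ_θ²), δ_j ~ N(μ_δ, τ_δ²);
hyperpriors μ_θ ~ N(−3, 2²), μ_δ ~ N(0, 1), τ ~ half-normal(1). AE and SAE
slices, and maternal and neonatal populations, are separate runs. The
sampler is a component-wise adaptive random-walk Metropolis: proposal
scales adapt toward ~44% acceptance during burn-in only, then freeze, so
retained draws form a valid chain; everything is driven by one seeded
generator. Two pooled probabilities are reported — the hyper-level
P(μ_δ < 0) and the summed-count conjugate comparison — because a single
"pooled pp" is ambiguous between the two and both are defensible.

## Adaptive engine

Design constants: 1100-enrolment cap, 5% expected dropout, blocks of 4,
interims every 13 weeks once 300 are enrolled, early-stop check from 800
enrolled at pp > 0.99, allocation cap [0.1, 0.9].

The allocation rule maps the interim pp to a target probability
pp^c / (pp^c + (1−pp)^c). The exponent default c = n/(2·n_max) is the
standard stabilised choice: flat early (protecting against wild swings on
few events) and approaching the square-root rule at full enrolment. c = 0
recovers fixed 1:1 allocation exactly. Non-1:1 targets inside blocks of 4
use randomised rounding of the expected high-dose count per block, so
per-block counts differ by at most one from 4·target and the long-run
frequency equals the target exactly.

At each interim, every site's table keeps its issued prefix untouched,
drops only never-issued assignments, and appends a fresh segment at the
new target, so the updated ratio takes effect at the next enrolment.
Early stopping uses the rule exactly as specified: no stop before 800
enrolments regardless of evidence.

The final success threshold used by the operating-characteristics harness
(not part of the stopping rule) defaults to 0.95 and is always printed
with results, since the design's published power statement does not pin a
final cut.

## Synthetic-data generator

The generator emulates the trial's cohort structure: ~1100 enrolments over
three sites (probabilities 0.23/0.33/0.44), Poisson enrolment at 5.86 per
week — chosen so that a full trial spans ~188 weeks and produces the
design's ten adaptive allocation rounds after the 300th enrolment —
enrolment RBC DHA from Normal(6.38, 1.77)% (implying 41.5% of the cohort
below the 6% low-status cutoff), 6% missing outcomes
(missing-completely-at-random by default, with an informative-missingness
odds multiplier for robustness experiments), and secondary outcomes at the
arm-wise rates and moments the trial reported.

Gestational ages come from a three-normal truth with components at
(224, 252, 273) days and SDs (14, 10, 8) — a realistic left-skewed shape
consistent with the reported arm SDs (16.3 vs 11.1 days). Only the early
component's weight is tuned (Brent root-finding, to 1e-6) to hit each
arm's target EPB rate; targets below the default configuration's floor
drain the moderately-preterm share instead, and targets below the term
component's irreducible left-tail mass (~6e-6) or above the early
component's own rate raise an explicit infeasibility error. Per-stratum
EPB truths (low/high DHA status) are supported for subgroup experiments.

What the generator does *not* emulate: correlation between gestational age
and anthropometrics (birth weight is drawn independently of gestational
age), demographic covariates, site differences in outcome rates, and
seasonal or pandemic-era enrolment pauses. Passing tests therefore show
the machinery is correct under the stated generating assumptions, not that
the trial's real data meet them.

## Operating characteristics

Each replicate streams enrolments through the real engine: per-site block
consumption, interim re-targeting, the 800/0.99 stop check, and a final
conjugate analysis of observed (non-missing) outcomes. A participant's
outcome becomes visible to an interim only after her simulated birth week,
enrolment_week + max(0, ga_days/7 − 16), taking enrolment at the midpoint
of the 12-20-week eligibility window. Replicates are seeded by
(seed, replicate_index), so any partition of the replicate range pools to
identical results. Success-threshold grids reuse stored decision-time pp
values, making power exactly monotone in the threshold.

At desk scale (500 replicates, the default) the harness reproduces the
design's planning behaviour: type-I error ≈ 5% under a (3%, 3%) null at
threshold 0.95, and power ≈ 79% under the (3%, 1%) planning scenario —
run times are a few seconds per 100 replicates. Protocol-scale design
comparison grids are out of scope.

## Numerical and testing notes

* Problem sizes in the test suite: conjugate checks run at the printed
  trial denominators; mixture parameter recovery uses 5,000 gestational
  ages per fit across 10 seeds (2,000 burn-in + 6,000 retained draws,
  2 chains); operating characteristics use 500 replicates per scenario.
* Quartile assignment uses empirical 25/50/75 cutpoints with boundary ties
  going to the lower quartile, so heavily tied data collapse downward;
  with continuous data group sizes are within 1 of n/4.
* The 6% DHA-status cutoff is strict (< 6 is low); the boundary value is
  high status. The published analysis does not state its convention at
  exactly 6.000; strict is this package's documented choice.
* EPB and preterm flags are strict (< 238, < 259 days); the boundary day
  belongs to the non-event side.
* The mixture rows of the published primary table are structural templates
  only: without participant-level gestational ages they are not
  numerically reproducible, and the package makes no attempt to fake them.
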