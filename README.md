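# dhatrial

Bayesian machinery for a two-dose, response-adaptive superiority trial of
prenatal docosahexaenoic acid (DHA) supplementation, with early preterm
birth (EPB, birth before 34 completed weeks = 238 days of gestation) as the
primary outcome. The package is for trial statisticians and methods
researchers who want to run, stress-test, or teach this class of design:
every analysis stage — outcome models, subgroup and quartile analyses,
safety monitoring, the randomization engine, and design simulation — works
end-to-end on synthetic data, so nothing requires access to participant
records.

## The models

**Primary and binary secondary outcomes.** Each arm's event rate is
binomial with a flat Beta(1, 1) prior, so the posterior after *e* events in
*n* participants is Beta(1 + *e*, 1 + *n* − *e*). The headline quantity is
the posterior probability (pp) that the high dose (1000 mg/day) is better
than the standard dose (200 mg/day) under a declared direction of benefit:

    pp = P(p_high < p_low | data)   (for events you want fewer of)

computed either by quadrature or by a seeded stratified Monte Carlo scheme;
the two agree to well within 0.002 at 40,000 draws.

**Continuous secondary outcomes** (birth weight, gestational age, delivery
DHA levels) use flat priors on summary statistics, under which each arm
mean has a Student-t posterior, t(n−1, x̄, s/√n), and pp = P(μ_high > μ_low).

**Gestational age as a continuous outcome.** A three-component normal
mixture (early pathological tail / moderately preterm / term) is fitted by
Gibbs sampling with component means and SDs shared across arms and
arm-specific weights. The fitted distribution is dichotomised at 238 days:

    EPB rate(arm) = Σ_k w[arm,k] · Φ((238 − μ_k) / σ_k),

which uses the whole gestational-age distribution rather than only the
event counts, and is the more efficient of the two primary analyses.

**Safety.** Adverse-event counts by body-system category enter a
multilevel binomial model with normal hyperpriors on category log-odds and
log-odds-ratios (partial pooling), giving per-category and pooled
probabilities that the high dose has fewer events.

**The adaptive design.** Enrolment starts 1:1 in blocks of 4 per site.
From 300 enrolments, an interim analysis every 13 weeks converts the
running EPB posterior into a new allocation probability
pp^c / (pp^c + (1−pp)^c) with c = n/(2·n_max), clipped to [0.1, 0.9], and
appends fresh blocks to each site's table. From 800 enrolments the trial
stops early if max(pp, 1−pp) > 0.99; otherwise it runs to the 1100 cap.

## Worked example

Generate a synthetic trial under the design's planning scenario (3% EPB on
the standard dose, 1% on the high dose) and analyze it:

```bash
dhatrial simulate-trial --seed 11 --out demo/
dhatrial analyze demo/participants.csv --seed 11 --out demo/report
```

Abbreviated output from that exact run:

```
== Primary efficacy: early preterm birth (<34 weeks) ==
   model  low_events  low_n  high_events  high_n  low_mean_pct  high_mean_pct  pp_high_better
binomial          14    516            4     512          2.90           0.97           0.991
 mixture          14    516            4     512          3.10           1.29           0.997

NNT (overall, from posterior means 3.1% vs 1.3%): 55
```

Reading this: 14 of 516 low-dose and 4 of 512 high-dose births were early
preterm in this synthetic cohort. The binomial model turns those counts
into posterior mean rates of 2.9% vs 1.0% and a 0.991 probability that the
high dose has the lower rate; the mixture model, using every gestational
age rather than just the dichotomised counts, concurs at 0.997. The
number-needed-to-treat line says roughly 55 pregnancies would need the
higher dose to avert one early preterm birth at these posterior means.

Design operating characteristics (power under the planning scenario):

```bash
dhatrial oc --reps 500 --seed 0 --threshold 0.95 --out oc.csv
```

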