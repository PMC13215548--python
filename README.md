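# u5trends

Subnational under-five mortality (U5MR) trends from full-birth-history
survey data: direct estimation, functional ANOVA of mortality curves, and
Bayesian space-time smoothing with forecasts.

The package is written for demographers and biostatisticians who estimate
child mortality from DHS-style household surveys and need (i) annual
region-level U5MR with design-based uncertainty, (ii) a formal test of
whether regional mortality *curves* differ, and (iii) smoothed,
forecastable surfaces that pool strength across space and time. Because
the microdata such analyses run on are usually restricted, the package
ships a first-class synthetic-data generator that reproduces the survey's
statistical structure (two-stage stratified cluster sampling, age-band
hazards driven by a latent space-time field), so every stage is testable
against known truth.

## What it computes

**Direct estimation.** Each child contributes weighted person-months at
risk to the DHS age bands (0, 1–11, 12–23, 24–35, 36–47, 48–59 months)
of the calendar years it traverses; a death adds a weighted event to the
band and year of the death month. With monthly band hazards
h_a = deaths / person-months, the period estimate is the synthetic-cohort
probability

    q5 = 1 − ∏_a (1 − h_a)^{n_a},   n_a = (1, 11, 12, 12, 12, 12),

reported per 1,000 live births. Sampling variance is a delete-one-cluster
jackknife on logit(q5).

**Functional ANOVA.** Each trajectory is smoothed onto a cubic B-spline
basis (roughness penalty on the integrated squared second derivative,
weight chosen by GCV). One-way FANOVA fits y_i(t) = μ(t) + β_{g(i)}(t) +
ε_i(t) pointwise and tests group differences with a permutation null:
pointwise 95th-percentile critical curve plus a max-statistic threshold
that controls the familywise error over the whole period.

**Space-time smoothing.** The logit-scale direct estimates enter a
Gaussian pseudo-likelihood with known design-based variances,

    y_it ~ N(η_it, v_it),
    η_it = μ + α_t + γ_t + θ_i + φ_i + δ_it,

with α_t iid time, γ_t a random walk of order 1 (Model I) or 2
(Model II), θ_i iid space, φ_i intrinsic CAR (ICAR) over the region
adjacency graph, and δ_it iid interaction. All five precisions get
Gamma(0.5, 0.001) (shape/rate) priors on structure matrices rescaled to
unit typical marginal variance. Fitting is by Gibbs sampling with exact
conjugate full conditionals; the confounded pairs (θ, φ) and (α, γ) are
handled with partially collapsed precision updates and joint constrained
block draws (see `docs/methods.md`). Model choice uses DIC (lower better)
and the sum of log conditional predictive ordinates, LCPO (higher
better); forecasts extend only the structured temporal term through the
random-walk recursion, so intervals widen with the horizon.

## Worked example

The bundled demo configuration simulates a small survey (8 regions x
12 years, ~6,700 children) and runs the full pipeline in well under a
minute:

```bash
u5trends all --config configs/demo.yaml
```

```
[simulate] 6702 children across 8 regions
[estimate] 96 region-year cells, 32 missing
[fanova] global p = 0.0200 (max crit 8.03)
[fit] RW1 done: 500 retained draws
[fit] RW2 done: 500 retained draws
[assess] selected RW2
[forecast] 8 regions x 4 years
```

`demo_out/assessment.txt` then reports, for this run:

```
model        dic       p_d  mean_deviance       lcpo
  RW1 152.396485 28.746835     123.649650 -83.249017
  RW2 151.290746 27.666969     123.623777 -89.252744

component                         interpretation  percentage
    theta Space unstructured (independent space)        5.08
      phi          Space structured (ICAR space)       84.17
    gamma     Time structured (random-walk time)        0.34
    alpha   Time unstructured (independent time)        0.46
    delta   Space-time interaction (independent)        9.95
```

Reading the output: the RW2 temporal prior attains the lower DIC and is
selected; the variance decomposition attributes ~84% of the fitted
surface variation to the structured spatial term — the generator's truth
for this demo is indeed dominated by the ICAR component. The FANOVA
global p-value of 0.020 says the simulated regional curves differ beyond
what label permutation explains: the observed maximum F (11.2) exceeds
the max-statistic threshold (8.0). `demo_out/forecast.csv` holds
per-region posterior medians and 95% intervals through the horizon, and
`demo_out/figures/` contains the raw-vs-smoothed curves, the mean curve
with its band, the F-statistic with both critical lines, the spatial
effect chart, and the history-plus-forecast panel with the SDG reference
line at 25 deaths per 1,000.

Each stage can also be run separately (`u5trends simulate|estimate|
fanova|fit|assess|forecast|report`), and everything is importable as a
library (`u5trends.direct_estimation`, `u5trends.spacetime_model`, ...).

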