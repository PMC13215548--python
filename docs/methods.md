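# Methods

This note documents the models, the numerical choices, and the design
decisions behind `u5trends`, in the order the pipeline runs them.

## Synthetic study design

The generator produces the two objects every downstream stage needs: a
ground-truth mortality surface and a survey that observes it.

**Truth surface.** The logit-scale five-year death probability is
η_it = μ + α_t + γ_t + θ_i + φ_i + δ_it over regions i and years t, with
α iid N(0, σα²), θ iid N(0, σθ²), δ iid N(0, σδ²), γ an order-1 or
order-2 random walk with innovation variance σγ², and φ an intrinsic CAR
draw (covariance σφ²·Q⁺, Q = D − W on the adjacency graph). γ and φ are
projected to sum to zero (γ additionally orthogonal to a linear trend for
order 2) so they are identified against μ and a global slope; the
projection leaves random-walk differences untouched. A consequence worth
stating plainly: the synthetic truth has no secular linear trend — a
deliberate match between what the generator produces and what the
identified model can attribute to each component.

Defaults (`default_truth_spec`): μ = logit(0.06) (typical q5 near 60 per
1,000, the right order of magnitude for a high-mortality transition),
σφ² = 0.15, σθ² = 0.02 (structured-to-iid spatial ratio 7.5:1, echoing
the strongly spatial variance decompositions such surveys produce),
σγ² = 10⁻⁴ (small innovations integrate to visible smooth swings over 33
years), σα² = σδ² = 0.005.

**Survey.** Two-stage stratified cluster sampling: region × urban/rural
strata, a fixed number of clusters per stratum, a fixed number of
interviewed women per cluster, Poisson births per woman, birth months
uniform over the study window. Defaults (42 clusters/stratum × 16 strata
≈ 672 clusters, 45 women each, 2.13 births/woman) yield ≈64,000 child
records — the scale of a national DHS. Weights are inverse stratum
sampling fractions (urban oversampled), normalised to mean 1; the
estimator is weight-scale invariant, so normalisation is cosmetic.

**Mortality mechanism.** Each region-year's q5 is converted to six
monthly age-band hazards h = c·shape by scalar root-finding
(`hazards_from_q5`); the default shape (60, 4, 1.2, 0.8, 0.6, 0.5) makes
~43% of under-five deaths neonatal, ~31% post-neonatal infant, ~26% ages
1–4 — a typical high-mortality split. Children are then followed month by
month under **period** hazards: in each month of age the child faces the
hazard of the band it occupies and the calendar year it occupies. This
matches the period estimand of the synthetic-cohort estimator (it is not
birth-cohort mortality). Follow-up stops at the interview month, giving
right censoring exactly as a retrospective survey would.

What the generator does **not** emulate: date heaping and displacement,
recall bias, within-mother correlation of sibling outcomes, PPS cluster
selection against real census sizes, and non-response. Tests passing on
this generator therefore validate the estimators' statistical logic under
a clean design, not robustness to DHS data-quality pathologies.

## Direct estimation

Weighted deaths and weighted person-months are tabulated per (region,
year, band); a death month counts as an at-risk month (discrete-time
hazard convention, h = d/n). Hazards in cells with zero exposure are
*missing*, never zero. The q5 chain 1 − ∏(1 − h_a)^{n_a} is exactly the
month-by-month survival product, which is what the brute-force oracle in
the tests recomputes by explicit enumeration.

Numerical choices:

- **Zero-death cells** would give logit(0); they receive half the minimum
  positive weighted death mass observed anywhere in the dataset, spread
  over bands proportionally to exposure (a uniform monthly-hazard bump).
  Spreading proportionally — rather than into one band — keeps the
  correction invariant to rescaling all weights. Configurable off, in
  which case such cells raise.
- **Variance** is a delete-one-cluster jackknife on logit(q5), floored at
  10⁻⁶ (identical clusters would otherwise report zero design variance,
  which the smoother cannot accept). Cells with a single contributing
  cluster are flagged missing with an error message pointing to pooling.
- Periods are single calendar years (33 annual estimates per region);
  missing cells are excluded from FANOVA but passed as missing
  observations to the smoother, which interpolates them.

## Functional ANOVA

Curves live on a cubic B-spline basis with equally spaced interior knots
(default 10 over the study window, basis size 14). Smoothing is penalised
least squares with the integrated squared second derivative as roughness;
λ is chosen by GCV over a 49-point log grid spanning 10⁻⁸–10⁸ (a 10⁻¹²
ridge stabilises near-singular systems). The λ → ∞ limit is the
least-squares straight line (penalty null space), a property the tests
assert.

FANOVA is fitted pointwise on a one-point-per-year grid under the
weighted sum-to-zero constraint Σ n_g β_g(t) = 0, so μ(t) is the overall
mean and β_g(t) the group deviations. Inference is by label permutation
(default 1,000 permutations, seed mandatory): the pointwise critical
curve is the per-year 95th percentile of permuted F values and the global
threshold is the 95th percentile of max-over-years F, with the add-one
p-value (1 + #{max F* ≥ max F}) / (n_perm + 1).

Replication: a one-way ANOVA needs more curves than groups. Region-level
curves alone (one per group) leave no residual degrees of freedom, so the
pipeline uses the 16 urban/rural stratum curves as replicates with region
as the factor. This is a design choice of this package, stated here
because it is the only reading under which the F statistic is defined.
F can be computed on raw or GCV-smoothed curves (config switch; default
smoothed).

## Space-time model

Gaussian pseudo-likelihood y_it ~ N(η_it, v_it) with the design-based
logit variances treated as known; η as in the generator. Priors:
μ ~ N(0, 10⁶); all five precisions τ ~ Gamma(0.5, 0.001) parametrised as
shape/**rate** (prior mean 500 — diffuse on the variance scale). The
interaction is iid (the simplest space-time interaction type).

**Scaled structure matrices.** Inside the sampler, Q and the random-walk
structure R = DᵀD are rescaled so the geometric mean of their marginal
variances (diag of the pseudo-inverse) is 1. After scaling, τ = x means
"typical effect variance 1/x" for every component, so a single
Gamma(0.5, 0.001) prior treats iid, ICAR and random-walk terms
comparably — the convention under which such priors are usually
calibrated. Without it the prior systematically favours whichever
component needs the larger precision for the same field size (verified:
pure ICAR fields were attributed to the iid term in 16/20 replicates
unscaled, 5/20 scaled). The public `build_icar_precision` /
`build_rw_precision` return the unscaled matrices; scaling is applied at
fit time, and the forecast recursion uses the correspondingly scaled
innovation precision (`PosteriorSamples.gamma_scale`).

**Sampler.** All full conditionals are conjugate. The subtlety is that
θ/φ and α/γ enter the likelihood only through their sums, so plain
one-block-at-a-time Gibbs leaves the *split* between each pair almost
unmoved — the chain locks into whichever component first absorbed the
pattern. The default sampler therefore, per sweep:

1. updates μ from its Normal conditional;
2. slice-samples τα, then τγ, from their marginal posteriors with the
   (α, γ) pair integrated out (a 1-D log-scale slice sampler against a
   (T−1)-dimensional Gaussian marginal, Cholesky per evaluation), then
   redraws (α, γ) jointly as one 2T-dimensional Gaussian block;
3. does the same for τθ, τφ and the (θ, φ) pair in 2n dimensions;
4. updates δ cellwise and τδ from its Gamma(a + rank/2, b + ‖δ‖²/2)
   conditional.

Sum-to-zero (and, for order-2, orthogonal-to-linear on γ) constraints are
imposed exactly by conditioning-by-kriging on the joint draws; δ is
double-centred by rows then columns (both exactly zero after the two
passes). Effective ranks in the Gamma shapes are the constrained ones:
T−1, T−order, n−1, n−1, (n−1)(T−1). The collapsed attribution was checked
against an exact two-dimensional grid integration over (τθ, τφ): sampler
and exact marginal agree. The plain conjugate scheme remains available
(`precision_sampler="conjugate"`) and reduced single-block models
(`include=`, `fixed_precisions=`) are compared against closed-form
Gaussian posteriors in the tests.

Defaults: 20,000 iterations, 5,000 burn-in, thin 5 (3,000 retained
draws); the tests and the acceptance script use shorter chains
(500–6,000 iterations) chosen so the whole suite completes in a few
minutes — adequate here because the collapsed updates mix quickly, as the
ESS diagnostics (`effective_sample_size`, via arviz) show. Missing cells
simply contribute zero data precision; a fully missing region or year is
drawn from its prior conditional.

**A known identification limit.** With 8 regions the spatial field has 7
degrees of freedom, and one realised field cannot reliably reveal whether
it came from the iid or the ICAR prior: exact marginal-posterior
computation (independent of the sampler) attributes a genuinely
ICAR-dominant mixture to the right component only ~50–75% of the time
under these priors. Coverage and point recovery of η are unaffected — the
*sum* θ + φ is well identified — but variance-decomposition shares for
the two spatial terms should be read as a model-based attribution, not as
estimates with frequentist guarantees. The same caveat applies to any
analysis of this form at a handful of regions.

**Forecasting.** Per retained draw, γ is extended H steps by its
recursion (order 2: γ_{T+h} = 2γ_{T+h−1} − γ_{T+h−2} + ε, ε ~ N(0,
1/(τγ·scale))); the future η is μ + γ_{T+h} + θ_i + φ_i. The iid terms α
and δ carry no autoregressive structure and are not projected forward.
In the no-innovation limit with a linear γ the forecast continues the
line exactly (random-walk-2 null space); on stochastic fits interval
width grows with the horizon. Because the identified γ is orthogonal to a
linear trend, forecasts from the synthetic studies plateau rather than
extrapolate a slope — consistent with the trend-free synthetic truth.

## Model assessment

- **DIC** = D̄ + pD with pD = D̄ − D(η̄) (posterior-mean plug-in). The
  identity DIC − D̄ = pD holds by construction; negative pD is reported,
  not clipped, as a mixing diagnostic.
- **CPO** by the harmonic-mean identity, computed with log-sum-exp;
  non-finite cells are flagged and excluded from the sum. **LCPO** is the
  *sum* of log CPO (higher = better); the mean of −log CPO is available
  behind a flag.
- **Variance decomposition**: empirical variance (ddof 1) of the
  posterior-median elements of each component — over regions for spatial
  terms, years for temporal terms, all cells for the interaction —
  expressed as percentages of the total. Empirical variances of the
  identified, constrained effects are used because intrinsic (ICAR/RW)
  variance parameters are defined only conditionally.
- **Comparison rule**: lower DIC wins, ties keep the first model, and a
  disagreement between the DIC and LCPO orderings is flagged in the
  report.

## Pipeline and reproducibility

One global seed expands through a seed sequence into per-stage seeds, so
stages are individually reproducible and the full run is deterministic:
two runs of the same config produce byte-identical tabular outputs, and
the manifest records a SHA-256 hash of every artifact. Outputs are plain
CSV/JSON; figures are PNG. The map-style spatial figure is a per-region
bar chart of φ posterior medians (no shapefile dependency). Problem sizes
in the tests (demo studies of 6–8 thousand children, chains of a few
thousand iterations, 20-replicate calibration loops) were chosen as the
smallest sizes at which the statistical checks have useful power.
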