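# Methods

This note documents the statistical models implemented in `respmix`, the
assumptions behind them, the synthetic cohort that stands in for trial
data, and the numerical choices that make the results reproducible.

## Observation model and trajectory families

The repeated outcome is the BDI-II total (0–63), observed at irregular
per-subject times measured in weeks from the pre-treatment baseline
(t = 0). Three mean functions are supported for subject *i*:

| family       | mean at week t                  | subject parameters |
|--------------|---------------------------------|--------------------|
| linear       | b0 + b1·t                       | b0, b1             |
| quadratic    | b0 + b1·t + b2·t²               | b0, b1, b2         |
| exponential  | b0·exp(−λ·t), λ ≥ 0             | b0, λ              |

Observations get a normal likelihood with a common residual SD σ across
subjects and occasions — the simplest model consistent with treating an
integer scale as continuous. The generator rounds and clamps scores to
the BDI-II range; the fitted likelihood deliberately ignores rounding.
Subject-level parameters are constrained by group-level normal
distributions (truncated at zero for λ), which is what shrinks the many
per-subject coefficients toward a common population and tempers the
multiple-comparison problem the covariate analyses would otherwise have.

### Default priors

All priors are weakly informative on the raw score/weeks scale and
overridable through `PriorConfig`:

* group mean of b0 ~ N(20, 10²) — keeps the implied baseline
  distribution inside the instrument's range (>95% of prior-predictive
  mass in [0, 63], a property the test suite checks);
* group mean of λ ~ N(0.1, 0.2²) truncated ≥ 0 (week⁻¹);
* group means of b1 ~ N(0, 2²) (points/week) and b2 ~ N(0, 0.5²)
  (points/week²);
* score-scale group SDs and σ ~ half-normal(5);
* the decay-rate group SD ~ half-normal(0.5): decay rates live around
  0.1/week, so a score-scale half-normal(5) would put nearly all prior
  mass on physically meaningless rates;
* class-membership (β) and slope-regression (α) coefficients ~ N(0, 1)
  on standardized covariates — the prior whose density at zero the
  Savage–Dickey Bayes factors divide by.

### Covariate preprocessing

Continuous and ordinal covariates are standardized to mean 0, SD 1
(population SD over observed entries); binary covariates are centered
only, so their coefficients read as full 0-vs-1 contrasts. The scaling
record inverts the transform. Missing covariate values (capped at 20%
per covariate, warning above 11%) are mean-imputed by default; the
`none` strategy leaves them missing, and the model fits then refuse
incomplete rows.

## The restricted 2-class mixture

Each subject carries a latent class indicator z (1 = responder).
The *restriction* that gives the classes their meaning: nonresponders
are flat (decay fixed at 0; in the quadratic variant, zero slope and
curvature), responders draw a positive decay from the group
distribution. Baseline levels b0 share one group distribution across
classes. Membership follows a logit link on the standardized covariates.
Because the flat class is nested in the responder class at λ → 0, labels
cannot switch, and the reported responder class is by construction the
one with the strictly larger group-mean decay; the fit still records the
fraction of draws violating the separation (responder group decay at
zero) and warns above 1%.

`P_resp` is the posterior mean of z — a full-posterior quantity, not a
plug-in from posterior-mean coefficients — so classification uncertainty
propagates into the responder split. The default classification
threshold is 0.5 (the natural posterior decision rule); 0.05 is offered
as the replication setting for the published split criterion, and with
the strongly bimodal `P_resp` distributions these fits produce, the two
thresholds give nearly identical splits.

## Strength of response

The slope analysis uses the quadratic family (a unit change of the
exponential rate does not have a constant effect on trajectories, so
"slope" is only well-defined there): b1_i ~ N(α₀ + Σ α_k x_ik, τ²), with
covariate-free group priors on b0 and b2. Reported α coefficients are
sign-flipped from the raw regression scale so that a positive value
always means *faster* symptom decline, matching the sign convention of
the directional odds-ratio tables. With no covariates the model reduces
exactly to the plain hierarchical quadratic fit, with α₀ in the role of
the slope group mean.

## Sampler

Fitting is by an adaptive Metropolis-within-Gibbs scheme written for
these models (the architecture a Gibbs-sampler program would generate,
with conjugate updates used wherever the conditional is available):

* polynomial-family subject coefficients: exact batched
  multivariate-normal conjugate draws (the model is linear-Gaussian
  given σ and the group level);
* exponential-family subject parameters: vectorized per-subject
  random-walk Metropolis (conditionally independent given the group);
* class indicators: **collapsed** updates that integrate the responder
  decay over its group distribution — 32-node equal-mass quadrature for
  the exponential family, exact closed form (Woodbury / determinant
  lemma) for the quadratic — followed by a redraw of the responder
  parameters from the (approximated resp. exact) conditional. Without
  collapsing, a flat subject that enters the responder class can park
  its personal decay near zero and never leave: the classic stickiness
  of data-augmented nested mixtures;
* membership coefficients β: independence Metropolis from the Laplace
  approximation of the logistic conditional (Newton iterations to the
  conditional mode);
* group means: conjugate normal draws; slope-regression coefficients α:
  conjugate ridge draws;
* group SDs and σ: log-scale random-walk Metropolis with half-normal
  priors, plus **interweaved non-centered moves** for the decay/slope/
  curvature SDs (propose a new SD and rescale all subject deviations
  with it). These cross the funnel that makes small group SDs
  (≈ 0.01–0.05 here) mix poorly under purely centered updates;
* proposal scales adapt by Robbins–Monro toward standard acceptance
  targets during warmup only, so the post-warmup chain is a valid Markov
  chain.

Determinism: each chain's generator derives from
`SeedSequence([seed, chain])`; identical seed and settings give
bit-identical draws, CSVs included. Defaults are 4 chains ×
1000 warmup / 2000 draws; `thin` keeps every k-th post-warmup iteration,
which the latent-class fits use (thin 4–6) because the class/SD cycle
has the longest autocorrelation time.

### Family selection

Families are ranked by WAIC computed from the pointwise log-likelihood
of the posterior draws (via arviz): elpd = Σ_i log mean_s p(y_i|θ_s) −
Σ_i var_s log p(y_i|θ_s); higher is better, and the criterion and its
standard error are carried in the output table. A failed fit yields a
flagged row rather than aborting the comparison.

## Evidence layer

* **Posterior mode** — argmax of a Gaussian KDE (Scott bandwidth) on a
  fixed 1024-point grid: deterministic given the draws.
* **HDI** — narrowest contiguous interval containing ⌈mass·n⌉ sorted
  draws; never wider than the equal-tailed interval.
* **Directional odds ratio** — max(p⁺,p⁻)/min(p⁺,p⁻) from the posterior
  sign counts, zero draws split evenly between the sides; the minority
  side is floored at 1/(2n) and the result flagged "saturated" when no
  draws fall on it.
* **Savage–Dickey BF₁₀** — prior density at zero (analytic, from the
  N(0,1) coefficient prior) divided by the estimated posterior density
  at zero. Within 2.5 posterior SDs of zero the estimate is the same KDE
  as the mode; beyond that a KDE at a far-tail point is driven by a
  handful of extreme draws, so the density comes from a moment-matched
  normal approximation of the posterior — the usual tail treatment for
  Savage–Dickey ratios. Underflowed densities are floored and flagged.
* **Jeffreys categories** — boundaries at 1, 3, 10, 30, 100 and their
  reciprocals; a boundary value goes to the stronger category; BF = 1 is
  "no evidence".

Evidence tables sort by posterior mode (coefficient tables) or by BF
ascending (Bayes-factor table); CSVs print 4 significant figures with
full-precision companion columns. Bayes factors are computed for the
slope-regression coefficients; for the latent-class model the package
follows the same practice as the analysis it implements and reports
directional odds ratios and probability-of-response curves instead,
point-null evidence in mixture posteriors being an unsettled problem.

## Diagnostics

R-hat is the split-chain potential scale reduction,
sqrt(((n−1)/n·W + B/n)/W) over the half-chains, matching arviz's
"split" method to numerical precision; the default pass threshold is
1.05 (configurable). Note the formula gives sqrt((n−1)/n) slightly below
1 for perfectly agreeing chains; the report's invariant tolerates 1e-3.

Posterior predictive checks simulate replicate datasets on the observed
time grids from the fitted observation model at randomly selected
posterior draws, then compare observed weekly mean and SD summaries
(visits binned to integer weeks, since schedules are irregular) against
the replicated 2.5/50/97.5% envelope, with one tail probability per bin.

## Synthetic cohort

The generator emulates the structure of an 82-subject guided
internet-CBT depression trial and is the package's only data source:

* baseline BDI-II ~ N(21.3, 6.6²) truncated to the 10–40 inclusion
  window;
* treatment span ~ N(9.6, 4.8²) weeks truncated to [1, 22]; occasions
  (max 11) follow a geometric per-session dropout rule (default hazard
  0.10, giving ≈ 7–8 occasions on average, in line with the ≈ 7 sessions
  of the emulated trial); gaps are positive gamma jitter around the even
  schedule and sum exactly to the span;
* 20 baseline covariates with the emulated trial's marginals (gender
  73% female, age 36 ± 11.7, married/cohabiting 54%, SWLS 16.7 ± 5.1,
  dysfunctional-thinking score 82.8 ± 25.1, …) and per-covariate MCAR
  missingness at the reported rates (1–11%);
* class membership from the logit model (default intercept
  logit(0.74) ≈ 1.05, reproducing the ≈ 74/26 responder split);
  responder decay ~ N(0.15, 0.03²) week⁻¹ truncated at 0, nonresponders
  ≈ flat; residual SD 3 BDI-II points;
* a quadratic world for the slope analysis: responder slope
  ~ N(−1.2, 0.3²) points/week shifted by −Σ α_k x_ik (so positive α
  means faster decline), curvature ~ N(0.04, 0.02²) for responders and 0
  for nonresponders (the flat class is genuinely flat); generating α/β
  maps are free parameters of the config.

What the generator does *not* emulate: covariate correlations (marginals
only — the emulated trial reports e.g. a 0.86 correlation between
module completion and session counts that is absent here), informative
dropout, autocorrelated residuals, floor effects beyond clamping, or
item-level instrument structure. Recovery and calibration results on
these cohorts therefore demonstrate that the machinery is correct under
its own assumptions, not that those assumptions hold in any particular
clinical dataset.

## Test and verification sizes

Unit and acceptance tests run reduced problem sizes chosen to keep the
full suite in the low minutes while leaving comfortable statistical
margins: recovery cohorts of n = 40–100 subjects, 2 chains with 300–800
warmup and 400–1000 retained draws (thinned up to 6× for the mixture
convergence checks), 10–20 seeded replicates per recovery rate, and a
compact 3-covariate table (one binary, one continuous signal carrier,
one continuous null) for the recovery fixtures. The sign-recovery
effects ride on continuous covariates because coefficients are
per-standardized-unit: a centered binary covariate has SD 0.5, so the
same nominal coefficient carries half the per-unit signal and the
realized association in a 100-subject cohort is materially noisier.
`scripts/acceptance.py` re-runs all of these conditions from scratch
under a user-supplied seed.

## Known limitations

* The common-σ normal likelihood ignores the discreteness and bounds of
  the score scale; severe floor effects would bias the decay estimates.
* Only two latent classes, and covariates act on membership only, not on
  within-class trajectory shape.
* Mean imputation understates covariate uncertainty; at the ≤ 11%
  missingness the generator emulates this is minor, but the `none`
  strategy exists for users who want to handle missingness upstream.
* The collapsed exponential-family class update uses 32-point
  equal-mass quadrature; the residual discretization error is far below
  Monte-Carlo noise at these sizes but is an approximation nonetheless
  (the quadratic variant's collapse is exact).
* WAIC compares in-family fits; it is not a substitute for marginal-
  likelihood model probabilities.
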