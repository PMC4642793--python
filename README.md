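# respmix

Bayesian latent-class growth mixture modelling of treatment response in
longitudinal depression-score data.

## The problem

Guided internet-based CBT helps many depressed patients but not all, and
clinicians would like to know in advance who is likely to respond. Given
repeated BDI-II measurements per patient (irregular visit times, in weeks
from a pre-treatment baseline) and a table of baseline characteristics,
`respmix` answers two questions:

1. **Who responds?** A restricted 2-class latent growth mixture model in
   which responders follow a declining trajectory, nonresponders stay
   flat, and baseline covariates predict class membership through a logit
   link.
2. **How strongly?** A hierarchical quadratic model in which covariates
   act as linear predictors on each subject's symptom slope.

Evidence for each predictor is reported the way a Bayesian reanalysis
would print it: posterior modes, 95% highest-density intervals,
directional odds ratios, Savage–Dickey Bayes factors, and Jeffreys
verbal evidence grades.

## The model

Individual-level trajectory (exponential family, the default):

    y_ij ~ Normal(b0_i * exp(-lambda_i * t_ij), sigma^2)

with subject parameters constrained by group-level distributions
(`b0_i ~ N(mu_b0, sd_b0^2)`, `lambda_i ~ N(mu_lam, sd_lam^2)` truncated at
zero). Linear and quadratic families are available and comparable by WAIC.

Latent classes: each subject carries an indicator `z_i`; nonresponders
are restricted to a flat trajectory (`lambda_i = 0`), responders draw a
positive decay from the group distribution, and

    P(z_i = 1) = logistic(beta_0 + sum_k beta_k x_ik)

over standardized covariates `x_ik`. A subject's responder probability
`P_resp` is the posterior mean of `z_i`. The strength-of-response model
instead regresses the quadratic slope: `b1_i ~ N(alpha_0 + sum_k alpha_k
x_ik, tau^2)`, with reported `alpha_k` sign-flipped so that "+" always
means faster symptom decline.

All models are fit with an in-package adaptive Metropolis-within-Gibbs
sampler (collapsed class-indicator updates, conjugate draws for the
linear-Gaussian blocks, interweaved non-centered moves for the group
SDs); convergence is checked with the split Gelman–Rubin statistic and
posterior predictive checks. No trial data ships with the package — a
seeded synthetic-cohort generator reproduces the structure of an
82-subject guided-iCBT trial (baseline BDI-II 10–40, mean 21.3, SD 6.6;
up to 11 occasions over 9.6 ± 4.8 weeks; ~74%/26% responder split; 20
baseline covariates with realistic marginals and missingness) and
provides the ground truth that the recovery tests measure against.

## Worked example

```python
import respmix as rm

# synthetic stand-in for an 82-subject guided-iCBT trial
config = rm.GeneratorConfig(seed=1, true_beta={"marital": 0.8, "swls": 0.9})
dataset, truth = rm.generate(config)

covariates, scaling = rm.standardize_covariates(dataset.covariates)
covariates = rm.impute_covariates(covariates, "mean")

posterior = rm.fit_latent_class(
    dataset, covariates,
    sampler=rm.SamplerConfig(chains=2, warmup=800, draws=1000, seed=2, thin=4),
)
labels, fraction = rm.classify(posterior.p_resp, threshold=0.5)
print(f"responders: {int(fraction * dataset.n_subjects)} of {dataset.n_subjects} "
      f"({fraction:.0%})")

rows = rm.evidence_table({n: posterior.beta_draws(n) for n in posterior.covariate_names})
for r in rows[-3:]:
    print(f"{r.name:>22s}  mode {r.mode:+.2f}  "
          f"95% HDI ({r.hdi_low:+.2f}, {r.hdi_high:+.2f})  OR {r.or_value:.2f}{r.or_sign}")

report = rm.convergence_report(posterior.draws)
print(f"max R-hat: {report.worst:.3f} ({'pass' if report.passed else 'FAIL'})")
```

Output:

```
responders: 63 of 82 (77%)
            employment  mode +0.64  95% HDI (-0.61, +1.85)  OR 6.14+
            motivation  mode +0.78  95% HDI (-0.18, +1.36)  OR 20.51+
                  swls  mode +1.14  95% HDI (+0.54, +2.19)  OR 1999.00+
max R-hat: 1.018 (pass)
```

Reading: 63 of the 82 simulated subjects have posterior responder
probability above 0.5; the three covariates with the largest positive
posterior modes are listed with their 95% HDIs and directional odds
ratios (`OR 20.51+` means a positive effect on response probability is
20.5 times more probable than a negative one). Life satisfaction (SWLS),
which truly drives class membership in this simulation (generating
coefficient +0.9), is recovered with an HDI excluding zero.

## Command line

The same pipeline is scriptable from a shell via a YAML config
(`respmix config-template` prints a commented template):

```bash
respmix simulate run.yaml     # synthetic cohort + ground truth to CSV
respmix fit run.yaml          # family selection / latent class / slope regression
respmix report results/       # markdown summary of a result bundle
```

`fit` writes per-subject responder probabilities, evidence tables shaped
like the published coefficient and Bayes-factor tables,
probability-of-response curves, convergence and posterior-predictive
reports, and a JSON manifest; it exits nonzero if any group-level
parameter fails the R-hat threshold.

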