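# Methods

## Problem setting

In prospective cohorts with rare outcomes, an expensive covariate (a
"phase-II" biomarker Z, e.g. a blood hormone assay) can only be measured
on a subset of the cohort, while cheap "phase-I" covariates X are known
for everyone. The analysis model is the Cox proportional hazards model

    lambda(t | X, Z) = lambda_0(t) * exp(beta'X + alpha'Z),

and the design question is which m << N subjects to assay so that alpha,
the biomarker log hazard ratio, is estimated efficiently.

`gofsurv` implements a goodness-of-fit (GOF) two-phase sampling design:
given an external working model on X only,

    lambda_e(t | X) = lambda_e0(t) * exp(eta'X),
    S_e(t | X) = exp(-Lambda_e0(t) * exp(eta'X)),

each subject is scored by the lack-of-fit quantity

    D(T, delta, X) = | delta - 1 + S_e(T | X) |,

the absolute gap between the observed event status by the end of follow-up
and the event probability the working model predicted over that same
follow-up. D = S_e(T|X) for cases (an event the model considered unlikely
scores high) and 1 - S_e(T|X) for controls (a survivor the model
considered at high risk scores high). Phase-II selection is independent
Bernoulli with probability min{1, c_k * D}, k = delta, where the
constants c_k are calibrated so the expected phase-II composition hits a
prespecified case-control ratio. Subjects the working model explains
poorly are exactly the ones whose risk the missing biomarker might
explain, so oversampling them concentrates information about alpha.
Analysis is by inverse-probability-weighted (IPW) Cox partial likelihood
with robust (sandwich) standard errors.

## Modules and estimators

### Weighted Cox estimation (`gofsurv.coxph`)

The fitting objective is the standard weighted log partial likelihood
(Breslow ties):

    l(b) = sum_i w_i d_i [ b'x_i - log sum_{j: T_j >= T_i} w_j exp(b'x_j) ].

The design-form likelihood that motivates IPW — weight appearing once
inside each event's ratio rather than multiplying the whole term — is
exposed as `weighted_log_partial_likelihood` for transparency; the two
have the same maximizer whenever every event has unit weight, which holds
by construction in the all-cases designs simulated here. The standard form
is what `coxph(weights=)`-style software maximizes, and it is the form our
oracle tests compare against.

Newton-Raphson with step-halving (accepted steps never decrease the
objective), convergence when the largest absolute score component falls
below 1e-8, at most 50 iterations and 10 halvings. Covariates are centered
internally for exponent conditioning; results are reported on the
original scale. Constant columns are rejected up front with the offending
names; a singular information matrix raises rather than returning garbage.
Non-convergence is flagged on the result, not raised, so a Monte-Carlo
loop can count and skip such replicates.

The model-based covariance is the inverse observed information A^-1. The
robust covariance is the sandwich A^-1 B A^-1 with B the cross-product of
per-subject weighted score residuals

    r_i = d_i (x_i - xbar(T_i)) - exp(lp_i) [ x_i H(T_i) - G(T_i) ],

where H is the weighted Breslow cumulative hazard and G its companion
accumulating xbar at each event time. Weights are treated as fixed and
known: the selection probabilities come from the external model, not from
the analysed sample, so no weight-estimation correction term is included.
Efron tie handling is available for estimation; the robust residuals use
the Breslow form (exact whenever event times are untied, which is
measure-zero in these simulations).

### Cohort generator (`gofsurv.cohort`)

Defaults emulate a cohort of women under 50 followed up to 25 years:

| parameter | default | notes |
|---|---|---|
| N | 2000 | per simulated cohort |
| beta (AGE, AGEMEN, BIOPSY, FTP, REL, RACE) | (0.028, -0.034, 0.431, -0.105, 0.541, 0.347) | log HRs per year / indicator |
| alpha (Z) | 0.2 or 0.5 | weak / strong biomarker |
| baseline | Lambda_0(t) = 0.002 * t^0.929 | Weibull, shape/rate convention |
| censoring | min(Exponential(lambda*), 25 y) | lambda* calibrated to the event rate |
| event rate | 5% or 10% | expected fraction with delta = 1 |
| Z | -2.15 + 0.05 * AGE + N(0,1) | corr(Z, AGE) ~= 0.2 |

The Weibull baseline uses the proportional-hazards shape/rate convention
Lambda_0(t) = scale * t^shape; with the defaults this yields a plausible
5-11% cumulative incidence over 25 years. Event times come from the
inverse-cumulative-hazard transform T* = (E / (scale * e^lp))^(1/shape),
E ~ Exponential(1).

Covariate marginals are synthetic stand-ins (the motivating study's
individual-level values are not public): AGE ~ Normal(43, 4.8^2)
truncated to [30, 50), AGEMEN ~ Normal(12.8, 1.5^2) truncated to [9, 17],
BIOPSY ~ Bern(0.15), FTP ~ Bern(0.75), REL ~ Bern(0.10),
RACE(white = 1) ~ Bern(0.80). The AGE parent SD of 4.8 is chosen so the
*truncated* SD is ~4.11, which makes corr(Z, AGE) =
0.05 * sd / sqrt(0.0025 * sd^2 + 1) come out at ~0.20; using 4.1 directly
would undershoot the correlation (~0.18) because truncation at the
enrollment window shrinks the realized spread. All marginals are
configurable, and the Z intercept/slope/noise form a correlation knob.

Censoring calibration solves E[P(T* <= min(C, 25))] = target for the
exponential dropout rate lambda* by Brent root search. The expectation
marginalizes over a fixed-seed draw of 40000 covariate vectors and
integrates the event-time density against the censoring survival by
128-node Gauss-Legendre quadrature, so the calibrated rate is
deterministic and smooth in lambda* (no Monte-Carlo noise in the time
dimension). Calibration happens once per scenario, not per replicate. An
unattainable target (administrative censoring alone produces too few
events; the ceiling is ~11.5% under the defaults) raises an error naming
the achievable ceiling.

Random streams: a cohort seed spawns separate substreams for covariates,
event times and censoring; the Monte-Carlo engine derives per-replicate
seeds from (master_seed, replicate_index) and separate substreams for the
external-model bootstrap, the GOF draw and the subcohort draw. Designs
within a replicate therefore see the identical cohort, and every run is
reproducible bit-for-bit from its manifest.

### External working model (`gofsurv.external`)

Fit on a bootstrap-enlarged sample (default 10000 draws with replacement)
of the cohort's phase-I data; the biomarker is structurally excluded. The
baseline cumulative hazard is the weighted Breslow step function, extended
flat beyond the last event time and evaluated right-continuously. The
model is refit per replicate by default (no information leakage across
replicates); a fixed pre-supplied model is supported via
`ScenarioConfig.refit_external=False` and by passing any object with a
`survival_at(t, x)` method, which is the hook for published risk
calculators.

### GOF selection (`gofsurv.gof`)

The sampling constant solves sum_i min(1, c * d_i) = target by bisection
(the left side is continuous, piecewise linear, nondecreasing, saturating
at the count of positive D values); the returned root leaves a residual
below 1e-5. All cases are kept by default (probability 1, weight 1), and
c_0 is calibrated on the realized cohort's control D values with target
ratio x (case count) — per-realization, not on population expectations.
Controls with D = 0 have selection probability exactly 0, which is
harmless for the weighted estimator (they are never selected); an optional
probability floor is available but off by default. Realized phase-II size
is random (independent Bernoulli draws), matching the min{1, c D}
probability law; no fixed-size conditional sampling is attempted. The
balanced variant calibrates c_0 within each stratum (default rule: split
at the median AGE) so each stratum achieves the target ratio locally.

### Case-cohort comparator (`gofsurv.cc`)

Simple random subcohort (optionally stratified with exact per-stratum
sizes) plus all cases, analysed with inverse-selection-probability
weights: cases weight 1, non-case subcohort members weight 1/q with q the
realized fraction of non-cases entering the subcohort (per stratum when
stratified). This weighted form is the common reduction of the Prentice
and Borgan I estimators, so design comparisons are not confounded by
estimation differences; the time-shifted Prentice pseudo-likelihood
risk-set convention is out of scope. Size matching sets the subcohort size
to round(expected GOF controls / (1 - event proportion)) so expected total
phase-II sizes agree between designs.

### Monte-Carlo engine (`gofsurv.engine`)

Per replicate: one cohort; full-cohort fit; external model; GOF selection
+ IPW fit; size-matched case-cohort draw + weighted fit. Per design and
coefficient across replicates: bias, empirical SD, mean and SD of the
robust SE, 95% CI coverage, Wald rejection rate (type-I error under a
null biomarker, power otherwise), mean realized phase-II size, and the
count of converged replicates (non-converged ones are excluded pairwise
per design and reported). Relative efficiency is the mean per-replicate
ratio of robust variances — robust rather than model-based, consistent
with the inference used throughout. Monte-Carlo standard errors (binomial
for proportions, emp_sd/sqrt(R) for bias) accompany every summary.

## Problem sizes and numerical choices

Default replicate counts are 500 for sampling-distribution summaries and
2000 for type-I error and power (raisable in `ScenarioConfig`); these are
the package's study sizes and give Monte-Carlo SEs of ~0.005 on a nominal
0.05 rejection rate and ~3% relative on an empirical SD. Root searches
use scipy's Brent method (censoring) and plain bisection (sampling
constants). Ties in simulated times are measure-zero; file round-trips can
create them, hence the Breslow default and optional Efron handling.

## What the generator does and does not emulate

It reproduces the covariate *marginals*, the Z-AGE link, the stated log
hazard ratios, the Weibull baseline and the 5%/10% event rates. It does
not model the real joint dependence among phase-I covariates, competing
risks, left truncation or time-varying effects. Operating characteristics
that are driven by event counts and effect sizes (type-I error, power,
full-cohort SD, coverage) transfer well to this synthetic population;
quantities sensitive to covariate fine structure (e.g. the exact
efficiency of stratified variants) should be read qualitatively.

## Known limitations

- The IPW estimator under the GOF design shows a small positive bias and
  mild under-coverage for a strong biomarker (alpha = 0.5) at the 5%
  event rate — visible in the original design-comparison literature as
  well — because heavy weights on a few well-fitting controls inflate
  finite-sample variability of the weighted risk sets.
- The semiparametric maximum-likelihood (SMLE) comparator is out of
  scope; the case-cohort comparator is the weighted form only.
- The sandwich variance ignores weight-estimation variability by design;
  if weights were estimated from the analysed data a correction would be
  needed.
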