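# Methods

## Dose-toxicity model and escalation rule

All three designs share a logistic dose-toxicity model in the standardised
dose `z = log(x/d* + 1)` (reference dose `d*`, 200 mg/m² by default):

- two-parameter (homogeneous): `logit π = β₀ + β₁ z`;
- four-parameter (subgroup-aware): `logit π = β₀ + β₁ z + 𝟙⁺(β₂ + β₃ z)`,
  with `𝟙⁺ = 1` for biomarker-positive patients.

The standardisation keeps `z` positive and increasing, zero at dose zero.
Escalation advice is identical across designs once a model is fitted: among
grid doses whose estimated DLT probability is below the unacceptable level
δ (default 0.35), advise the dose maximising the patient gain
`1/(π̂(d) − θ)²` with target θ (default 0.16).  Gain maximisation is
implemented as `argmin |π̂(d) − θ|` over the safe doses — the identical
ordering without a division by zero at an exact hit — with ties broken to
the lower dose (conservative and deterministic).

## Pseudo-data prior

Prior opinion is encoded as fractional pseudo-patients: per subgroup, two
prior doses with an assumed DLT proportion and a patient weight (default:
2 patients at 100 mg/m² with proportion 1/6, 1 patient at 260 mg/m² with
proportion 1/2 — 3 pseudo-patients per subgroup, a tenth of the planned 30).
The homogeneous baseline uses the pooled rows (4 and 2 patients at the same
proportions).  Pseudo-data are fitted exactly like trial data, so the MAP
estimate equals the weighted MLE and no MCMC is needed outside the
variable-selection step.  Under this prior the advised starting dose is
100 mg/m², and a DLT-free path escalates one grid level at a time.

## Model fitting

Weighted-binomial logistic fits use Newton's method with step-halving on the
log-likelihood.  Convergence is declared when the relative log-likelihood
change falls below 1e-8 — the standard GLM deviance criterion.  This choice
is substantive on quasi-separated data (e.g. a subgroup with no DLTs below
the penultimate dose): the MLE then lies at infinity and the *reported*
coefficients are wherever the stopping rule lands, although derived
quantities such as the TD100θ stabilise quickly.  The packaged
biomarker-negative data are exactly such a case; the GLM-equivalent
tolerance reproduces the conventional estimate (TD16 = 244 mg/m²).
Quasi-separation is noted on the fit object.  Rank-deficient designs (fewer
distinct dose/subgroup support points than free parameters) and fits whose
observed information cannot be inverted are flagged `converged=False`.
The coefficient covariance is the inverse observed information at the
optimum.  A statsmodels GLM serves as an independent cross-check in the test
suite; it is not used by the implementation.

## Spike-and-slab variable selection (method2)

The subgroup terms carry Dirac-spike / normal-slab priors

    βⱼ | γⱼ ~ γⱼ N(mⱼ, σⱼ²) + (1 − γⱼ) δ₀,  P(γⱼ = 1) = wⱼ  (j = 2, 3),

with independent Bernoulli indicators and prior inclusion probabilities
w₂ = w₃ = 0.5 by default.  The slab is derived by fitting the four-parameter
model to the pseudo-data alone: slab means are the coefficient estimates
(zero for β₂, β₃ under the symmetric default prior) and slab variances are
the diagonal of `slab_scale ×` the inverse observed information
(`slab_scale` defaults to 1, keeping prior strength equal to pseudo-data
strength; results are sensitive to this knob and it is exposed in the
configuration).  The full covariance is retained on the prior object, but
the sampler uses the independent components, matching the independent
mixture form above.

Sampling is Metropolis-within-Gibbs, JIT-compiled with numba:

1. each active coefficient gets a Gaussian random-walk update against the
   likelihood × its slab prior; step sizes adapt towards 44% acceptance
   during burn-in only, so retained draws come from a fixed-kernel chain;
2. each indicator gets a birth/death move: births draw the coefficient from
   its slab, so the prior density cancels against the proposal and the
   acceptance ratio reduces to the likelihood ratio times the prior odds
   wⱼ/(1 − wⱼ); deaths are the reverse move.  Boundary priors (wⱼ = 0 or 1)
   pin the indicator.

Draws with γⱼ = 0 have βⱼ exactly zero (Dirac spike), so the posterior
inclusion probability ŵⱼ is the fraction of retained draws with γⱼ = 1.
Chains start at the slab mean with both terms included.  Fractional binomial
weights enter the likelihood directly.  Defaults are 20 000 iterations with
5 000 burn-in; a "fast" profile (5 000 / 1 000) exists for large simulation
studies and is flagged in study output.  The sampler is validated against
exact model enumeration (tensor-product Gauss-Hermite quadrature of the
marginal likelihood of all four models) on small datasets, against the prior
on empty data, and for bit-identical seeded reproducibility.

A term enters the escalation model when ŵⱼ exceeds the inclusion bound
(default 0.25, strict inequality as the bound is phrased; a tie excludes).
The chosen model is then refitted by MAP on pseudo + trial data and dosing
proceeds as in the other designs.

## Trial conduct

Cohorts have size 2: one patient per subgroup while both are active, both
from the survivor after a one-sided stop.  Per-subgroup cap is half the
trial cap (30 of 60 by default).  A subgroup stops for safety when its
advised dose set is empty; the surviving subgroup immediately switches to
the two-parameter model fitted to its own pseudo + trial data.  Safety
stops are evaluated at each advisory step before the cohort is treated.

Final recommendations are frequentist — fitted to trial data only, never the
pseudo-data — and restricted to grid doses at or below the maximum dose
administered in the relevant subgroup (the smaller subgroup maximum when a
pooled recommendation covers both).  The subgroup-effect verdict is coded
0 (none), 1 (effect), 2 (defaulted after a one-sided safety stop):

- baseline always reports 0;
- method1 reports 1 unless a one-sided safety stop occurred (then 2);
  simultaneous safety stops in both subgroups also code 1, since the
  four-parameter model was in use and no pooling decision was ever made;
- method2 runs a final variable-selection step on the complete data: both
  terms out → pooled recommendation, verdict 0; otherwise four-parameter
  recommendations, verdict 1; a one-sided stop forces 2, and a simultaneous
  both-subgroup stop codes 0 (no dose anywhere and no evidence of a
  *differential* effect).

When the final fit is rank deficient — all relevant patients treated at a
single dose, common in the no-tolerated-dose scenario — the recommendation
falls back to an intercept-only model: the estimated DLT probability is the
pooled observed fraction, every allowed dose ties in gain, and the tie
breaks to the lowest dose (no recommendation when the fraction is not below
δ).  This mirrors how standard GLM software drops aliased columns, keeps
operating characteristics comparable, and is counted per trial.

### Accuracy stopping (optional)

A subgroup may additionally stop when at least 5 of its patients have been
treated at the currently advised dose and the 95% interval for its TD100θ
estimate is narrower than a configured bound.  The interval is a
delta-method normal interval on the dose scale from the fit's
observed-information covariance.  The conventional bound of 5 mg/m² is far
narrower than a delta-method interval can reach at 30 patients per subgroup
(typical widths are 60–150 mg/m²), so under that default the rule never
fires; the bound, level, minimum count and the rule itself are
configuration knobs, and tests exercise the rule with attainable bounds.
This is a known limitation: the interval construction that would make a
5 mg/m² bound operative is not determined here.

## Simulation scenarios

Six scenario truths are generated from the four-parameter model, not from
rounded probability tables.  The negative-subgroup curve is the pooled
two-parameter fit to the packaged trial data (β₀ = −7.098, β₁ = 7.680).
Scenario 1 uses it for both subgroups; scenarios 2–5 solve (β₂, β₃) by
nonlinear least squares on the probability scale so the positive-subgroup
curve reproduces its target per-dose probabilities to 2 decimal places
(cells printed as 1.00 contribute a one-sided hinge at 0.995); scenario 6
fits a fresh shared curve with no tolerated dose anywhere.  Construction
fails loudly, listing offending cells, if any dose misses its target by
more than 0.005.  Logit-scale least squares was rejected because it
over-weights extreme cells and misses the 2-dp targets.

## Replicated studies

`run_study` repeats `run_trial` with replicate-indexed seeds
(replicate r uses root_seed + r; each trial splits its seed into independent
outcome and MCMC streams), so studies can be split across sessions or
workers and pooled without changing any number.  Summaries report average
sample sizes and DLT proportions (averaged over trials, including
early-stopped ones), verdict counts, per-subgroup recommended-dose
distributions over {no dose} ∪ grid (proportions of all trials, summing
to 1), stop-reason proportions, and the joint no-dose-anywhere rate.

## Problem sizes and numerical choices

Default studies use 1 000 replicates with the full MCMC profile, matching
the published setup.  The packaged acceptance script uses 1 000 replicates
for the deterministic-design averages and 500 per design (full MCMC) for
the no-tolerated-dose scenario; the test suite uses 200–400 replicates with
the fast MCMC profile for the method2 checks.  These sizes put Monte-Carlo
standard errors well inside the tolerances asserted.  All randomness flows
from explicit integer seeds; no wall-clock entropy enters results.

## What the simulations do and do not show

The generator draws binary DLT outcomes from fixed per-dose, per-subgroup
probabilities under perfect biomarker classification, instant outcome
observation, and full cohort compliance.  Real trials feature misclassified
biomarkers, staggered enrolment and late toxicities, clinical overrides of
model advice, and doses off the planned grid — none of which are modelled.
Passing operating-characteristics checks therefore validates the design
logic under the stated generative model, not trial performance in the
field.  Known residual differences from the published operating
characteristics are small and documented in the test tolerances: the
no-tolerated-dose scenario averages ~19.6–20.6 patients here against a
published 18.9 (about one patient, within combined Monte-Carlo error), with
the same stop-speed and recommendation pattern.
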