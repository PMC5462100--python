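# Methods

## Model and assumptions

A patient's dose-limiting toxicity (DLT) is a single binary outcome observed
immediately after dosing. The true dose–toxicity relationship is the
two-parameter logistic π(x) = expit(β0 + β1 x) with β1 > 0, so toxicity is
strictly increasing in dose. The maximum tolerated dose (MTD) γ is defined
by π(γ) = θ, with target toxicity level θ = 1/3 in the bundled study setup.
The model is reparameterized through (γ, ρ0), with ρ0 = π(xmin) the DLT
probability at the lowest dose: given (γ, ρ0, θ, xmin),

    β1 = (logit θ − logit ρ0) / (γ − xmin),    β0 = logit ρ0 − β1 xmin,

which requires 0 < ρ0 < θ and γ > xmin; anything else is rejected as a
degenerate scenario (the implied slope would be non-positive or infinite).
logit/expit are clamped 10⁻¹⁵ away from {0, 1} so curve construction never
produces infinities for near-degenerate baseline probabilities such as
ρ0 = 0.001.

Scenario tables always carry exact solved parameters; printed values are
rounded only for display. The per-level probabilities of the bundled
discrete scenarios are consistent with the exact, not the rounded,
parameters.

## Priors

* **Uniform** (the classical overdose-control choice): γ ~ U(xmin, xmax)
  independent of ρ0 ~ U(0, θ). A consequence worth knowing: observations
  taken exactly at xmin satisfy π(xmin) = ρ0 identically, so they update ρ0
  only and leave the γ-marginal untouched.
* **Bivariate normal on (β0, log β1)** (the simulation-study prior):
  means (−2.56, −5.32), SDs (1.24, 0.91), correlation −0.90. Monte-Carlo
  summaries in the clinical parameterization give a prior mean (SD) for ρ0
  of 0.203 (0.139). The prior mean of γ has the lognormal closed form
  e^{−μ1+σ1²/2}(logit θ − μ0 + ρσ0σ1) ≈ 263 mg/m², but γ is extremely
  heavy-tailed under this prior (its MC standard deviation is several
  hundred mg/m² and unstable), so only ρ0's summary should be quoted.

## Posterior backend

The marginal posterior CDF of the MTD, H_n, is computed by deterministic
tensor-product grid quadrature:

* uniform prior — cell-midpoint grid over (γ, ρ0) ∈ [xmin, xmax] × [0, θ],
  with the CDF tabulated at the right-hand cell edges so the no-data
  posterior is *exactly* the uniform CDF;
* bivariate normal prior — an equally spaced grid over (β0, log β1)
  spanning μ ± 6σ with bivariate-normal weights; γ is computed per node and
  H_n assembled by accumulating node masses in γ-order (precomputed sort).

The default resolution is 400 × 400 nodes; posterior quantiles move by less
than 0.5 mg/m² when the grid is doubled to 800 × 800, and they agree with a
10⁶-draw importance-sampling oracle to well under 2 mg/m² on small
datasets. Batch simulations use 201 × 201 (quantile granularity well below
the 1 mg/m² dose rounding); a single quadrature engine is shared across a
batch so node construction and per-dose likelihood terms are computed once.

Under the bivariate normal prior γ's support extends beyond the dose range;
H_n is tabulated on the extended support and quantiles are clipped to
[xmin, xmax] only when converted to doses. Quantile inversion is
piecewise-linear in the tabulated CDF, returning the smallest dose whose
CDF reaches α (ties resolve to the smaller dose). A numerically zero
normalizing constant raises a diagnostic error naming the offending data.

The optional MCMC backend (`compute_posterior_mcmc`, affine-invariant
ensemble sampler via `emcee`) exposes chains/burn-in/thinning settings and
tabulates H_n from the empirical CDF of the γ draws. It exists for
cross-validation and for studying sampling-noise effects; everything that
must be reproducible bit-for-bit uses the grid.

## Feasibility-bound schedules

All schedules produce α ∈ [αmin, 0.50]; (1 − α)/α is the implied
overdose:underdose loss ratio (3 at the classical α = 0.25, 1 at the
posterior median).

| schedule | parameters (defaults) | notes |
|---|---|---|
| fixed  | α = 0.25 | constant |
| tr     | — | 0.25 for patients 2–9, +0.05 per patient for 10–14, then 0.50 |
| hybrid | αmin (0.25), N | α_n = αmin + (0.50 − αmin)(n − 2)/(N/2 − 1), capped; 19 increments for N = 40, i.e. steps of 0.40/19 ≈ 0.021 (αmin = 0.10) or 0.25/19 ≈ 0.013 (αmin = 0.25) |
| eat    | αmin (0.10), increment (0.05), cap (0.50) | one increment per non-DLT among patients 2..n−1 |
| tdfb   | αmin (0.25), S | α_{n+1} = min(0.50, αmin + (0.50 − αmin)(n − 1 − Σyᵢ)/S) |

Choices embedded here that a reimplementer should know:

* The hybrid ramp is anchored at α₂ = αmin and α_{N/2+1} = 0.50, giving
  N/2 − 1 equal increments. Its per-trial count of α-increase opportunities
  (the violation-rate denominator) is therefore N/2 − 1 = 19 for N = 40;
  the alternative convention counting ramp dose decisions (20) is available
  via the `opportunities` field.
* The EAT cap at 0.50 is not intrinsic to the rule but is imposed for
  parity with every other schedule; it is configurable.
* TDFB's numerator is exactly n − 1 − Σᵢ yᵢ: patient 1 is excluded even
  though y₁ = 0 by construction (a trial with y₁ = 1 stops).
* S = (N/2 − 1)(1 − θ) (= 38/3 for N = 40, θ = 1/3) makes the *expected*
  bound reach 0.50 when half the patients have been dosed. The realized
  first passage is slightly later: an integer count ⌈S⌉ = 13 of non-DLTs is
  needed, so the mean first capped patient index is 2 + ⌈S⌉/(1 − θ) = 21.5
  rather than N/2 + 1 = 21 (negative-binomial closed form; verified by
  simulation in the test suite). With no DLTs at all, TDFB dominates the
  hybrid ramp sharing its αmin at every patient.

## Trial engine

Cohort size is one. Patient 1 receives the lowest administrable dose —
xmin on a continuous range, the lowest level of a discrete set (150 when
the set starts above xmin = 140). If patient 1 has a DLT the trial stops
for safety re-evaluation: such trials are flagged, carry no MTD estimate,
and are counted separately rather than redrawn (batch summaries report the
count; recommendation metrics average over completed trials only).

For each subsequent patient, α_{n+1} is computed from the outcomes of
patients 1..n *before* y_{n+1} is observed; the posterior uses all accrued
data; and the assigned dose is the administrable dose nearest the
α-quantile — continuous doses are rounded half-up to the nearest integer
mg/m² and clipped to the range, discrete ties at equidistant levels break
to the lower (safer) level.

Two end-of-trial MTD estimators are reported: the posterior median
γ̂ = H_N⁻¹(0.50) and the next-dose estimate γ̃ = H_N⁻¹(α_{N+1}), both
projected onto the dose space. They coincide whenever the schedule has
reached its 0.50 cap, so they differ materially only for the fixed-α
design (γ̃ ≤ γ̂ by quantile monotonicity).

A *coherence violation* is recorded whenever x(n+1) > x(n) and y_n = 1.
Schedules whose bound never rises after a DLT (fixed, eat, tdfb) cannot
violate: adding a DLT observation shifts every posterior quantile weakly
downward (likelihood-ratio ordering, checked empirically in the tests), and
the dose projection is monotone. A test-backed empirical finding for the
deterministic backend: replaying trials under the stepwise `tr` ramp, the
dose that would follow a DLT at a ramp patient never exceeds the dose at
which the DLT occurred — the 0.05 α-jump never outweighs the one-DLT
posterior downshift, with a large share of exact ties. Escalations after a
DLT under such ramps therefore require posterior-quantile noise (e.g.
finite MCMC samples) to break those ties upward; a deterministic posterior
eliminates the mechanism. Batch summaries still report violation rates with
binomial standard errors per α-increase opportunity (tr: 5/trial; hybrid:
19/trial) so sampled backends can be compared on the same footing.

Randomness: each trial draws outcomes from its own `numpy` generator keyed
by (base seed, scenario index, design index, trial index), so batches are
reproducible, order-independent and embarrassingly parallel. Seeded runs
are bit-reproducible.

## Simulated data: what it does and does not emulate

The generator produces exactly the data the designs assume: instantaneous
binary DLT outcomes drawn from a smooth monotone true curve (logistic, or
power/hyperbolic-tangent curves on the standardised dose
x* = (x − xmin)/(xmax − xmin) for misspecification studies — those
generators are never fitted; the working model is always the logistic).
Defaults mirror the bundled study setup: N = 40 patients, θ = 1/3,
continuous range [140, 425] mg/m² or levels {150, …, 400}, ten scenarios
spanning steep, shallow and plateauing curves with MTDs from 165 to 400
and baseline toxicity ρ0 from 0.001 to 0.30. Not represented: late-onset
or cumulative toxicity, patient heterogeneity or covariates, accrual
timing/pipeline patients, dose modifications within a patient, or
misreported outcomes. Passing simulations therefore validate the decision
logic and estimator behavior under the stated model, not robustness to
those clinical realities.

## Operating characteristics

For recommendations γ̄_k over K completed trials against true MTD γ:
bias = mean(γ̄_k − γ); RMSE = sqrt(mean((γ̄_k − γ)²)) ≥ |bias|. The
accuracy index over J dose labels with true toxicities π(d_j) and
recommendation frequencies p_j is

    A = 1 − J · Σ (π(d_j) − θ)² p_j / Σ (π(d_j) − θ)²,

equal to 1 when all mass sits at labels with π = θ, 0 for a uniform
recommendation distribution, and undefined (rejected) if every label sits
exactly at θ. Experimentation is summarised as the fraction of dosed
patients per true-toxicity band; the default band edges
{0, .20, .25, .30, .35, .40, 1} include the conventional [0.30, 0.35)
on-target band. For continuous dose ranges the accuracy index has no
canonical discretization; here recommendations are assigned to their
true-toxicity band and A is computed over bands with band-midpoint
probabilities standing in for π(d_j) — a documented package choice, and the
reason continuous and discrete accuracy values should not be compared
numerically with each other.

## Known limitations

* No stopping rules beyond the first-patient DLT rule; no safety-suspension
  logic, no covariate adjustment, no cohorts larger than one.
* The continuous-accuracy banding (above) is a convention, not a canonical
  definition.
* The MCMC backend is validated only to Monte-Carlo-error agreement with
  the quadrature on small datasets; it is not tuned for production use.
* γ's prior moments under the default bivariate normal prior are heavy
  tailed; Monte-Carlo summaries of γ (unlike ρ0) are unstable and reported
  for orientation only.
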