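# Methods

This note documents the model, the algorithms and the numerical choices
behind `pedpk`, and what the synthetic-data studies do and do not
demonstrate.

## Structural model

Both drugs are described by a two-compartment disposition model with
first-order elimination, parameterised as apparent oral clearance CL/F,
central volume Vc/F, inter-compartmental clearance Q/F and peripheral
volume Vp/F, with transit-compartment absorption.  The transit chain has a
continuous number of compartments NN and mean transit time MTT; its input
rate into the first-order depot (rate constant ka) is the gamma density
with shape NN+1 and rate ktr = (NN+1)/MTT scaled by F·dose.  Because the
whole system is linear in the administered amounts, multiple doses
superpose, and each dose's contribution at lag τ is the convolution of
that gamma density with the tri-exponential impulse response of the
depot + two-compartment chain.  The convolution is evaluated in closed
form through the regularised lower incomplete gamma function,

    I(τ; a, ktr, λ) = e^(−λτ) (ktr/(ktr−λ))^a P(a, (ktr−λ)τ),  a = NN+1,

with two numerical fallbacks keyed on z = (ktr−λ)τ: a power series for
|z| < 8 (all-positive for z ≤ 0, mildly alternating otherwise) and a
24-node Gauss–Legendre rule concentrated at the upper endpoint for
z ≤ −8, where the convolution mass sits near the observation time.  An
explicit-chain ODE oracle (integer NN, stiff solver) agrees with the
closed form to <1e-6 relative; direct quadrature of the kernel agrees to
~1e-7 across the parameter ranges the models visit.

Covariates: allometric scaling to the 15 kg reference child (fixed
exponents 0.75 for CL and Q, 1.0 for Vc and Vp), sigmoidal maturation of
CL in postmenstrual age (Hill coefficient γ, half-maturation age PMAGE50),
a proportional formulation effect of suspension on MTT (crushed tablets
pooled with whole tablets), and an optional proportional MDR-TB group
effect on one of CL, F, MTT or ka.  Ages convert at 1 month =
365.25/12 days; gestational age defaults to 9 months where unrecorded.

Pre-dose (trough) concentrations are generated and fitted from an explicit
history of 10 prior doses at the nominal interval.  For abacavir
(terminal half-life ≈ 6.5 h) this is at steady state to well below 0.1%;
for lamivudine the deep peripheral compartment (terminal half-life ≈ 26 h)
still accumulates by ~2% per additional 2 doses.  Because the same
convention is used for simulation and estimation this residual
non-stationarity cancels from the recovery and power studies.

## Stochastic model and censored data

Between-subject variability acts on CL (SD ω on the log scale) and
between-occasion variability on ka, MTT and F (SDs π, lognormal;
F is fixed at 1 for the typical subject).  The pre-dose samples form
occasion 1 — the tie at the dose time counts as pre-dose — and the
observed-dose profile occasion 2; all history doses share the occasion-1
absorption draws, the observed dose uses occasion 2.  Subjects with only
post-dose samples (the once-daily subset) have a single occasion.

Residual error is combined additive + proportional,
sd² = pred²·σ_prop² + σ_add², with σ_add bounded below by 20% of the
assay LLOQ (enforced as a hard constraint).  The LLOQ is 0.024 mg/L for
both assays, back-derived from the fixed additive error of 0.0048 mg/L
being 20% of it.  Below-LLOQ handling follows the M6 rule: censored
observations are imputed at LLOQ/2 with the additive SD inflated by
LLOQ/2 (an SD increment, not a variance increment); within the trailing
run of censored observations at the end of a profile only the first is
imputed and the rest are excluded from the likelihood but kept for
diagnostics.  Simulated concentrations are truncated at zero for output
while the likelihood uses the untruncated Gaussian.

## Estimation

The marginal likelihood integrates the per-subject random effects (up to
seven: one CL effect plus one absorption triple per occasion) by the
Laplace approximation around the conditional mode.  The inner problem is
solved by a damped Gauss–Newton iteration using the *analytic* Jacobian of
the predictions with respect to the random effects (closed-form
derivatives of the convolution kernel in each branch), with a ridge
escalation and step clamp at ±6 SD; convergence is declared on the Newton
decrement (< 1e-12), which is scale-free where raw gradient norms are not.
The mode search always starts from a fixed reference (the conditional
modes at the fit's starting values, re-centred between optimizer rounds),
which makes the marginal a deterministic function of the parameters —
warm starts carried over from other parameter vectors were observed to
strand the search in poor local modes of the absorption parameters.

Two flavours of the log-determinant term are available:

* `method="foce"` (default): the expected-information (Gauss–Newton)
  Hessian.  Robust and fast; this is the FOCE-I-style choice and the one
  used for the replicate studies.
* `method="laplace"`: the observed Hessian by central differences of the
  analytic gradient.  Closer to the true integral on well-behaved data
  (within ~0.03 of a 64-node adaptive Gauss–Hermite oracle on toy sets,
  versus ~0.1–0.3 per subject for the expected-information variant), but
  the observed conditional Hessian can approach singularity in the weakly
  informed occasion-1 absorption directions (two trough samples versus
  three occasion-level effects), where the log-determinant is unbounded
  below; its eigenvalues are floored at 2% of the smallest prior curvature
  to keep the objective bounded.

The outer problem maximises over the free parameters on a log scale
(log(1+x) for the signed proportional effects), inside a ±2.5 log-unit box
around the starting values, by a damped Newton iteration with central
finite-difference gradients and a periodically refreshed finite-difference
Hessian; per-direction step sizes come from the diagonal curvature.
Convergence is again decrement-based (< 1e-3 of a −2LL point).  Jittered
multi-starts are available (`restarts=`, seeded) but off by default: the
search from the model's initial estimates is deterministic and, in
simulation studies, reached the same optima as jittered restarts at a
third of the cost.  The default free set comprises the ten structural
fixed effects (F fixed at 1), the four random-effect SDs and the
proportional error; the formulation effect and the occasion SDs are
dropped automatically when the data cannot inform them.  Typical
bioavailability freed together with CL or Vc triggers an identifiability
warning (oral data only determine their ratios).

Priors: lognormal penalties with 20% CV on γ and PMAGE50 stabilise the
maturation parameters, which a cohort of mostly mature children hardly
informs; for recovery testing they are centred at the final estimates.
The compiled (numba) engine is mirrored by a pure-python reference
implementation and the two are kept in lockstep by parity tests; a
Gauss–Hermite quadrature oracle guards the approximation itself.

## Covariate search, uncertainty, diagnostics, power

The stepwise search tests proportional MDR-TB effects one parameter at a
time (CL, F, MTT or ka), forward inclusion at p < 0.05 and backward
elimination at p < 0.01 on the drop in −2LL against χ²(1) quantiles
(6.63 at p = 0.01, computed from the distribution function, not
hard-coded).  The model carries one group effect at a time, so the
forward pass includes the single best significant candidate — sufficient
for the null-calibration and single-effect power questions this package
addresses.

Parameter uncertainty uses sampling importance resampling: multivariate
normal proposals on the estimation scale around the estimate (covariance
from the outer Hessian, inflated 1.5-fold), likelihood-ratio weights, and
resampling without replacement; the effective sample size is checked and
the resample count should stay well below the proposal count.

The visual predictive check bins observations at the protocol's nominal
times after the observed dose (−1, 0, 1, 3, 5, 7, 10 h, ±0.5 h tolerance;
bins with fewer than 3 observations merge into their neighbour; the
once-daily subjects' late samples fall outside every bin and are dropped
from display, as are excluded trailing-censored points from the
percentiles).  Simulated replicates of the design give a 95% confidence
band for each observed percentile.

Power follows the stochastic simulation-and-estimation recipe: simulate
the trial with a postulated multiplicative clearance (or bioavailability)
change in the MDR-TB group, fit with and without the group effect, and
compare the drop in −2LL to χ²(1) at α = 0.01.  During SSE refits the
maturation parameters stay at their final values (the original analysis
needed informative priors for them) and the refit iteration count is
capped; the reduced fit starts from the generating values and the full
fit from the reduced optimum, a warm-start chain that changes individual
Δ−2LL values by well under the significance threshold.

## Synthetic cohorts

`generate_cohort` draws weights and ages per group from lognormal
distributions matched to the reported medians and quartile ratios
(σ = ln(Q3/Q1)/(2·0.6745)); a lognormal cannot also match an asymmetric
IQR exactly, so the quartiles land at median·e^(∓0.6745σ).  Draws are
clipped to 2.5–70 kg and 0.25–14.9 years (clipping, unlike rejection,
preserves the median and quartiles), and weight is coupled to age by rank
within each group.  Formulation, nasogastric and ART-regimen indicators
follow the reported group fractions; dose amounts are exactly mg/kg
(4 mg/kg twice daily for lamivudine, 8 for abacavir; doubled for the
once-daily subset) with no tablet-strength rounding.  Each child receives
10 steady-state doses before the observed dose; 7.4% of children (the
observed fraction) miss the evening dose before sampling, which is
removed from both the simulated history and the fitted one (the original
analysis likewise assumed the missed dose).  Sampling follows the
protocol; the 5 h vs 10 h final sample alternates by subject index; two
control children remain on once-daily dosing and are sampled at 10–17 h
after an unobserved evening dose.  The lamivudine design yields exactly
322 observations, the study's count.

What these cohorts do not emulate: real covariate vectors (the per-child
weights and ages of the trial are unavailable, so power and recovery
results on the matched synthetic design are approximate by construction),
assay batch effects, time-varying weight, adherence patterns beyond the
single missed-dose scenario, and any true MDR-TB effect — the generator
imposes none unless asked.  Passing recovery and power checks therefore
demonstrate internal consistency of model, simulator and estimator at the
study's design and reported parameter values, not properties of the real
data.

## Problem sizes used by the test suite

The full replicate studies (hundreds of fits) are a research-scale
computation; the package's own checks use these sizes, chosen to keep the
suite comfortably on one CPU:

* parameter recovery: 20 replicate simulation–estimation runs per drug at
  the full study design (54 and 50 children);
* power: 12 SSE replicates per drug at the postulated detectable effect
  (binomial 95% bounds at that count are the assertion band), with the
  library defaulting to the publication-scale 200 replicates;
* covariate-search type-I error: 24 null searches on an 8-child design
  (the null retention rate does not depend on the design size);
* VPC self-coverage: 8 seeds × 150 simulations on a 12-child design;
* quadrature oracles: 4-subject datasets, 64 nodes.

## Known limitations

* Single-analyte, oral-dosing datasets only; no infusions, no
  time-varying covariates within a sampling day.
* One multiplicative group effect at a time in the covariate machinery.
* The expected-information default slightly biases the absolute −2LL
  relative to the exact integral (bounded by the oracle tests); model
  comparisons use differences of the same flavour, where the bias largely
  cancels.
* IIV–IOV correlations are representable in the specification but the
  final models carry none, and the estimator treats the random effects as
  independent.
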