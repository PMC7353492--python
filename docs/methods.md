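# Methods

This note documents the models, estimators and numerical choices behind
`frostkin`, and what the packaged synthetic data do and do not
demonstrate.

## Kinetic model

Quality loss is modelled with a primary reaction-order law and an
Arrhenius secondary model. The case study (vitamin C in frozen green
peas) is first order; zero order is also implemented as the other
common frozen-food primary model, but the general fractional order is
deliberately not solved. All equations operate in Kelvin and J/mol;
every user interface takes °C and reports E_a in kJ/mol. The gas
constant is fixed at 8.314 J/(mol·K) and the reference temperature
defaults to 253.15 K (−20 °C), the frozen-food convention: `k_ref` is
then directly the rate at the temperature labels are written for.

Dynamic histories are stepwise: the quality function is
`Q = Σ k(T_i)·t_i` over constant-temperature steps. Continuous T(t)
beyond this discretization is out of scope; cold-chain records are
effectively stepwise anyway. The effective temperature is obtained by
inverting the Arrhenius law at `k_eff = Q/t_tot`, which is undefined
for `E_a = 0` (an explicit error). Remaining shelf life may be
negative — a pack already past the limit — and is reported unclamped so
that expired-fraction statistics are well defined downstream.

## Estimation

**One-step** fitting minimizes the sum of squared *retention* residuals
of the integrated model over all observations jointly, via
Levenberg–Marquardt (`scipy.optimize.least_squares`, `method="lm"`)
with the analytic Jacobian
(`∂Y/∂k_ref = −A·t·Y`, `∂Y/∂E_a = k_ref·t·A·Y·(1/T − 1/T_ref)/R`,
`A = exp(−(E_a/R)(1/T − 1/T_ref))`). Convergence tolerances default to
1e−10 on the relative SSE/step change. Initialization uses the
two-step estimates, falling back to a crude log-linear start when the
two-step design requirements are not met. Fitting on the retention
scale (not log-retention) matches the residual definition used for the
confidence machinery.

The asymptotic covariance is `(JᵀJ)⁻¹·SSE/(n−p)`. Because k_ref
(~10⁻³) and E_a (~10⁵) differ by eight orders of magnitude, the rank
test and inversion are performed after column equilibration of J; true
rank deficiency (all data at one temperature, or a vanishing column)
raises a dedicated error rather than returning garbage intervals.
Confidence intervals are `estimate ± SE·t(1−α/2, n−p)`; n−p degrees of
freedom are used consistently with the SSE/(n−p) variance estimate.

**Two-step** fitting regresses ln(retention) on time per temperature —
through the origin by default, since retention is normalized to 1 at
t = 0 (a free intercept is an option) — then ln k on `(1/T − 1/T_ref)`
by OLS (statsmodels). `(k_ref, E_a)` uncertainties follow from the
second regression's covariance by the delta method, with t quantiles
on (number of temperatures − 2) degrees of freedom. Temperatures whose
step-1 slope is nonpositive are excluded with a recorded warning; fewer
than three usable rate constants is an error. Weighted least squares
and bootstrap intervals are out of scope.

## Joint confidence region

The joint (1−α) region is `SSE ≤ SSE_min·(1 + p/(n−p)·F(p, n−p, 1−α))`.
Membership for Monte Carlo filtering always uses exact SSE evaluation,
never a discretized polygon, so no contour error leaks into the
simulation. The boundary (for inspection and export) is extracted by
marching squares (`skimage.measure.find_contours`) on a 201×201 SSE
grid spanning the estimate ± 5 asymptotic SEs, with the box doubled up
to four times if the contour touches an edge; beyond that the result is
flagged "unbounded within search box" rather than raised, because
likelihood regions of nonlinear models can genuinely be unbounded. In
the near-linear regime (small noise, many observations) the polygon
area agrees with the asymptotic covariance ellipse to well under 10%,
which is the regression test for the construction.

## Cold-chain scenarios

A scenario is an ordered list of stages, each with a fixed duration and
a temperature distribution (truncated normal via inverse-CDF on
`scipy.stats.truncnorm`, or a histogram sampled bin-by-probability and
uniformly within the bin). By default one temperature is drawn per
stage per iteration; a `resample_interval` splits a stage into chunks
with independent redraws for finer within-stage dynamics. Stage
durations are fixed — duration randomness, door-opening microdynamics
and defrost cycles are not modelled.

The packaged 130-day case study (60 d warehouse, 40 d retail, 30 d
domestic) uses **synthetic** stage distributions: truncated normals at
−22 ± 2 °C [−30, −12], −18 ± 3.5 °C [−30, −5] and −15 ± 4.5 °C
[−30, −2]. They emulate the qualitative shape of cold-chain survey
data — progressively warmer and broader toward the domestic freezer,
the chain's weakest link — but are not fitted to any real survey, so
every conclusion drawn from them is a property of the *method*
(orderings, variance decompositions, what-if directions), not a
prediction for any real product.

## Monte Carlo

Parameters are sampled independently per component from normal laws,
k_ref truncated to positive values by rejection; standard deviations
derive from 95% CI half-widths as half-width/1.96 (the large-sample
normal pairing, under which ±11.34 kJ/mol corresponds to
σ = 5.8 kJ/mol). Continuous inverse-CDF sampling is the default; a
discretized-normal option (default 101 bins over ±4σ) reproduces
binned-frequency sampling for comparison. Zero standard deviations are
accepted and mean point masses — the degenerate limit used to decompose
uncertainty sources and to verify collapse to the deterministic
calculation (relative error ~1e−14 in the packaged check).

Joint-region filtering uses rejection-with-redraw so the output sample
size stays fixed; the acceptance rate is reported, and an acceptance
below 1% raises a diagnostic error (the parameter law and the fitted
region disagree). Each run derives two independent substreams from its
seed — one for parameter draws, one for temperature draws — so paired
what-if comparisons (CI-width scaling, stage replacement) reuse
identical temperature histories across arms and differences are due to
the intervention alone. Runs are bit-reproducible for a fixed
configuration.

The default iteration count is 10⁴. Summary intervals are empirical
2.5–97.5 percentile bands; for the strongly right-skewed shelf-life
distributions a symmetric mean ± half-width summary would be
misleading. The single-temperature engine is validated against a
semi-analytic oracle: `E[SL] = −ln(limit)·E[1/k_ref]·exp(−c·μ_Ea +
c²σ²_Ea/2)` with `c = (1/T_ref − 1/T)/R` and `E[1/k_ref]` by numerical
quadrature over the truncated normal; the Monte Carlo mean at −18 °C
(~271 d) agrees within Monte Carlo standard error. Note this mean
exceeds the plug-in value (265.6 d) — the Jensen direction for a mean
of 1/k.

## Synthetic isothermal data

The generator emulates an accelerated-type isothermal study: five
temperatures (−5, −8, −12, −16, −20 °C), eight sampling times spaced to
two half-lives at each temperature, and additive Gaussian noise
(default sd 0.02) on retention, redrawn when a draw would make
retention nonpositive (a multiplicative-noise option exists). Additive
retention noise matches the residual scale the estimators minimize.
The temperature ladder and design are invented, configurable defaults —
real studies' designs are rarely published in full — so estimator
calibration results (≥93/100 runs with E_a within 2 SEs of truth;
95% CI coverage within [90%, 98%] over 200 replicates) certify the
estimator under this design, not under any particular laboratory's.

What the synthetic data do not emulate: inter-lot variability of the
initial vitamin C content, non-Arrhenius behaviour near the glass
transition (WLF-type kinetics are out of scope), autocorrelated
measurement error, and real survey temperature histograms. Passing
tests therefore demonstrate correctness of the estimation and
propagation machinery, not validation against a physical product.

## Problem sizes

Calibration checks use 100–200 synthetic replicates of 40 observations
each; Monte Carlo checks use 4,000–10,000 iterations; the 1/√n scaling
check compares 60 independent run means at n = 10² vs n = 10⁴. These
sizes give stable verdicts for every property tested while keeping the
full suite and the acceptance script fast (seconds each).

## Known limitations

* Deterministic shelf lives recomputed from the case-study parameter
  values (e.g. 265.6 d at −18 °C, 353.7 d at −20 °C from the two-step
  values) are taken as authoritative outputs of the stated equations;
  no external constants are introduced to force agreement with any
  previously quoted rounded figures.
* The joint region is limited to the two Arrhenius parameters;
  profile-likelihood per-parameter intervals and >2-parameter regions
  are not provided.
* Histogram distributions assume within-bin uniformity; truncation
  bounds are hard limits, not soft tails.
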