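# Methods

## Setting and model

A two-arm group-sequential trial monitors an original primary endpoint
(endpoint A) at looks `k = 1..K` through its efficient score statistic
`S_k^A` and Fisher information `I_k^A`, with the canonical asymptotic
model

    (S_1^A, ..., S_K^A) ~ N(theta_A * I^A, Sigma),   Cov(S_j, S_k) = I_min(j,k).

This holds exactly for normal data with known variance and asymptotically
for the binary, normal, and time-to-event statistics implemented in
`gsswitch.whitehead` (log-odds ratio, standardized mean difference, and
log hazard ratio scales respectively; the binary information uses the
`n_C n_T s f / N^3` form, which is the variant consistent with the
package's reference dataset).

Efficacy stopping uses an alpha-spending boundary: a nondecreasing
function `alpha*(t)` on information time `t_k = min(I_k / Imax, 1)` fixes
the cumulative null crossing probability at every look, and the critical
values `u_k` are found recursively by Brent root-finding on
multivariate-normal rectangle probabilities (`gsswitch.spending`).  Only
upper (efficacy) boundaries are constructed; futility rules are treated as
non-binding and ignored, which cannot inflate the type I error for
nonnegative endpoint correlations.

## Endpoint switch and the corrected boundary

At look `k_switch` (chosen on grounds external to the trial data) the
primary endpoint changes to endpoint B, which has been collected all
along.  Monitoring before `k_switch` is on A; from `k_switch` on, it is on
B; if the trial already stopped with an A-rejection at look
`k < k_switch`, a single test of `S_k^B` is performed.  The joint model
extends to both endpoints with cross-covariance
`Cov(S_j^A, S_k^B) = rho * sqrt(I_min^A I_min^B)`, where `rho` is the
correlation between same-look score statistics.

The probability of rejecting the endpoint-B null depends on the nuisance
effect `theta_A`, so the corrected critical values `u_k^B` are defined by
a worst-case spending condition: at every look the *supremum over
theta_A* of the cumulative probability of stopping and rejecting H0(B)
equals the spent alpha `alpha*(t_k^B)`.  This controls the type I error
for the new endpoint whatever the true effect on the abandoned one.  The
same spending function as for endpoint A is used; `Imax^B` is the
expected endpoint-B information at the sample size that yields `Imax^A`.

### Numerical construction

Rejection events are conjunctions of one-sided threshold conditions on
the per-look statistics and are evaluated as rectangle probabilities of
the standardized joint normal (`gsswitch.joint` / `gsswitch.mvnorm`):
exact closed forms in dimensions 1-2 (Owen's T function), and a Genz
separation-of-variables transform over a scrambled Sobol set in higher
dimensions.  The Sobol seed is fixed, so all solves are deterministic;
typical absolute accuracy is ~1e-5 at the default 2^14 points and ~3e-7
at the 2^16 points used for the reference boundary computations.

The supremum over `theta_A` combines three pieces:

* the limits `theta_A -> +-inf`, evaluated analytically (threshold
  conditions on A become almost sure or impossible);
* a dense grid over `|theta_A| <= (z_1^A + 8) / sqrt(I_1^A)`, outside
  which the objective has flattened onto the limit plateaus;
* a local refinement of the interior peak (a fine sub-grid inside the
  root-finder; a bounded scalar minimization for the reported maximizer),
  with tolerance 1e-6 on `theta_A`.

The boundary value at each look is then the Brent root of
`sup_value(u) = alpha*(t_k^B)`; the supremum is nonincreasing in `u`
(every event either contains `{S_k^B >= u}` or is free of `u`), so the
crossing is unique.  If a look adds no incremental alpha the boundary is
`+inf`.  When `rho` is re-estimated at successive looks, the current
estimate enters every cross-term of that look's construction while
earlier boundary values stay frozen as first computed; when the trial has
already stopped before the switch, the whole chain is built
retrospectively with the single estimate from the stop look.

The interior maximizer can lie at `+inf` (always at look 1), at interior
points of either sign, or effectively on a limit plateau; the search is
global over all three.  On one reference configuration the cumulative
rejection probability has a flat negative-theta plateau whose value lies
within ~2e-4 of a small interior bump — a purely local 1-D optimizer can
return the plateau and a boundary a few hundredths lower, which is the
scale of the remaining discrepancy between this implementation and some
published values of that configuration.

## Correlation estimation

For normal endpoints `rho` equals the within-group correlation of the
endpoints and is estimated by pooled within-arm Pearson correlation.
Otherwise a within-arm bootstrap resamples subjects with replacement
(original arm sizes preserved, paired observations kept together),
recomputes `(S^A, S^B)` per replicate, and takes the Pearson correlation
across replicates (default 1000; degenerate resamples are redrawn up to a
retry cap).  Estimates are clipped to `[-0.999, 0.999]`.  An optional
Fisher-z upper confidence limit across replicates supports deliberately
conservative boundary construction, since overstating `rho` makes the
corrected test conservative.

## Synthetic data and the scenario driver

`generate_normal_trial` emulates the canonical study conditions: five
stages of 19/19/19/19/20 subjects per arm (96 per arm total), bivariate
normal endpoints with unit variances, correlation `rho_true`, and
standardized treated-arm effects `(theta_A, theta_B)`; the per-look
information is `n_cum / 2` for both endpoints (`Imax = 47.75`, i.e.,
one-sided alpha 0.025 and 90% power at a standardized difference of 0.5
with linear spending).  `generate_binary_tte_trial` provides a
latent-variable stand-in for ordinal disease-progression generators: one
latent bivariate normal per subject is thresholded for a binary day-15
response and mapped through its probability transform to an exponential
recovery time censored at day 28 (calibrated to a 40% control recovery
rate by default).

`run_scenario` compares three tests of H0(B): the corrected boundary
(built per replicate with the pooled within-arm correlation estimate at
the current look), the naive fixed `1.96 sqrt(I_k^B)` rule, and an
uncorrected group-sequential boundary on endpoint B.  Score statistics in
the scenario driver use the generator's known unit variance by default,
matching the exact joint normal model that the boundaries are built on
(`known_variance=False` switches to pooled-SD estimation, which adds
small-sample tail inflation of the naive and group-sequential rates on
the order of +0.004 at the stage sizes above).  Correlation estimates are
always taken from the simulated subject-level data; negative estimates
are mapped to zero before boundary lookup, consistent with the
nonnegative-correlation designs studied.

Because the information schedule is deterministic given the stage sizes,
corrected boundary chains depend on the data only through the correlation
estimate; `BoundaryCache` precomputes chains on a `rho` grid (default
step 0.01 on [0, 0.95]) and interpolates linearly, with interpolation
error below 0.01 in the boundary value (verified against direct solves).
Cache chains use 2^11 integration points and a root tolerance of 1e-3 —
a boundary jitter of ~2e-3, i.e., ~3e-4 on the z-scale, which is
negligible against Monte-Carlo noise at the replicate counts used.

What these simulations do not emulate: staggered entry or information
drift (information is exactly `n/2` per arm), covariate structure,
non-normal endpoint distributions for the operating-characteristics
tables, and over-running after a stopping decision.  Passing tests
therefore certify the boundary construction and its error control under
the canonical joint model, not robustness to those features of real
trials.

## Problem sizes used in the checks

The packaged test-suite runs the deterministic reproductions at full
precision and the Monte-Carlo comparisons at 4000-5000 replicates per
cell with a 0.05-step boundary cache; the acceptance script uses 10^4
replicates (the study's own size) and the default 0.01-step cache.  These
sizes put every Monte-Carlo tolerance at 3 standard errors or the
documented absolute band, whichever is larger.

## Known limitations

* The supremum search certifies global optimality only through the dense
  grid plus limit evaluation; pathologically narrow interior maxima
  (width well below the grid step over `theta_A`) could in principle be
  missed, though none arise in the configurations studied.
* Boundary construction assumes `rho` known (or plugged in); estimation
  error in `rho` is addressed empirically and by the upper-confidence
  option, not analytically.
* No point or interval estimation for the endpoint-B effect after
  stopping; no futility boundaries; no familywise control across both
  endpoints as co-primaries; at most two endpoint processes.
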