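# Methods

## The model

Each patient's total ALSFRS-R score is modelled as a logistic decay in time
since symptom onset:

    y(x) = Ymax / (1 + exp((x − D50)/dx)),    Ymax = 48.

`D50` (months, > 0) locates the inflection, where the modelled score equals
half the instrument maximum (24 points); `dx` (months, > 0) is the shape
denominator. The tangent slope at the inflection is `−Ymax/(4·dx)`
points/month. The literature sometimes calls `dx` itself "the slope at a
score of 24"; the two quantities differ by the factor `Ymax/4`, so the
package exposes both (`LogisticParams.dx` and `midpoint_slope`) instead of
conflating them. The exponential base is Euler's e, and the sign convention
is fixed to decay: `dx > 0` always, and growth-shaped solutions are treated
as fit failures, not valid parameters.

Model assumptions worth stating plainly: monotone decline (the curve cannot
follow transient functional gains, which real patients show after e.g.
therapeutic interventions); a common theoretical baseline of 48 rather than
the patient's own first score; no covariates; independent homoscedastic
score noise around the curve.

Display values are truncated toward zero (`truncate_display`), never
rounded — 31.88 displays as 31, 0.0931 as 0.0 — and internal computation
always keeps full precision. Evaluation uses `scipy.special.expit`, so
extreme times saturate gracefully to the asymptotes instead of overflowing.
A precision note: for a near-vertical curve (`dx = 0.4`, `D50 = 119`) the
pre-midpoint plateau equals 48.0 exactly in double precision only up to
roughly month 102; beyond that `48·(1 − ε)` truncates to 47. Plateau checks
therefore probe months ≤ 100.

## Initialization

Starting values come from the conventional linear decline rate
(points/month). Two slope estimators are provided: `two_point`,
`(y_first − y_last)/(x_last − x_first)` over the first and last visits (the
default; which visit pair to use when more exist is genuinely open, and
first/last uses the longest lever arm), and `onset_anchored`,
`(48 − y_first)/x_first`, the field-standard ΔFRS. Flat or improving
trajectories have no positive decline rate; they are flagged
(`ZeroSlopeError` → fit status `failed`), never silently fitted.

`D50` is initialized by extending the conventional line to score 24:
interpolated between the bracketing visits if the observations cross 24,
otherwise extrapolated forward (last score above 24) or backward (below)
from the last visit.

`dx` initialization has two deliberate modes:

- `converted` (default): `48/(4·slope)` — the shape value whose midpoint
  tangent equals the conventional slope. Correct units, sensible starting
  curve.
- `paper`: the slope is passed through verbatim as `dx`. This mimics an
  analysis pipeline in which the points/month rate was used directly as the
  shape parameter. For fast progressors (slope ≈ 1–3) the initial curve is
  steep but close enough to the data for the optimizer to recover. For slow
  progressors (slope < 0.365, hence `dx` ≈ 0.1–0.4 months) the initial
  curve is an almost-vertical cliff at the extrapolated `D50`: every
  observed visit sits on the flat plateau at 48, the residual gradient is
  numerically zero, and the optimizer terminates at the initial point. The
  package keeps this mode because reproducing that failure mechanism — and
  detecting it honestly — is part of its purpose.

## Fitting

Per-patient sum-of-squared-error minimization with
`scipy.optimize.least_squares` (trust-region reflective, analytic Jacobian),
bounds `D50 ∈ (0.001, 600]` months, `dx ∈ (0.001, 200]` months. `Ymax` is
fixed at 48 by default; a free-but-bounded mode (`(0, 48]`) and a fully
unconstrained mode exist for the diagnostic below. Eligibility requires at
least three observations. Tolerances (`xtol = ftol = gtol = 1e-10`) are
tight enough that noise-free synthetic trajectories refit to their true
parameters at better than 1e-6 relative error.

Fit status is a partition:

- `degenerate_initial` — final parameters within 1e-7 relative distance of
  the initials with no SSE improvement: the optimizer never left the
  starting point (checked before the boundary test, since a cliff initial
  may also sit near a bound);
- `boundary` — some parameter pinned at a bound (1e-8 relative);
- `converged` — optimizer success with SSE no worse than the initials';
- `failed` — everything else, including no-positive-slope trajectories.

`converged` therefore implies `sse ≤ sse_initial` by construction.

### Bootstrap confidence intervals

Case-resampling over visits: resample the (time, score) pairs with
replacement, redraw any resample with fewer than three distinct times,
refit (starting from the base estimate — replicate initialization was
checked to be immaterial: per-replicate conventional initials give
identical intervals), and take percentile intervals at the configured
level. Case resampling was chosen over residual resampling because the
model is knowingly misspecified for trajectories with transient gains;
percentile over bias-corrected because it is the simplest interval
consistent with a preset confidence level. Everything is driven by the
config seed and is exactly reproducible. If more than half the replicate
fits fail, the result carries a wide-interval warning rather than raising.

A calibration property of this estimator worth knowing: with very few
visits per patient (around 9), percentile case-resampling intervals are
slightly anticonservative — Monte-Carlo experiments in the test suite
measure empirical coverage of the nominal 95% interval in the high
0.80s/low 0.90s. This is the textbook small-n behaviour of the percentile
bootstrap, not an implementation artifact.

### Unconstrained-asymptote diagnostic

`diagnose_unconstrained` refits with `Ymax` free and unbounded and scans
the fitted curve on a dense grid from symptom onset through the last visit.
The curve — including its early-disease asymptote `Ymax` itself, which is
the model's predicted score near onset — is flagged `out_of_range` if it
exceeds 48 or goes below 0. The asymptote is included deliberately: a
bounded trust-region optimizer frequently fits mildly-declining
slow-progressor data with `Ymax ≈ 60–90` while parking `D50` near zero, so
the within-window predictions stay inside the instrument range even though
the model claims a better-than-maximal functional baseline. Roughly a third
of simulated slow progressors trigger the flag; well-behaved fast
progressors do not.

## Cohort analysis

- **Classification**: slow iff conventional slope < 0.365 points/month
  (strict inequality; the boundary value is fast). The threshold applies to
  the linear points/month rate, never to the fitted shape parameter `dx` —
  the only reading under which slow-progressor slopes (≈ 0.08–0.40) and
  fast-progressor fitted `dx` values (≈ 1–17 months) are commensurable with
  their published ranges.
- **Summaries**: n / min / max / mean / sample SD (n−1 denominator) of
  initial and optimal `dx` and `D50`, grouped by fit outcome (converged vs
  not). SD for a single value is reported as undefined (NaN), not 0.
- **Agreement**: R² is the squared Pearson correlation;
  the ICC is the two-way random-effects, absolute-agreement,
  single-measures form (pingouin's ICC(A,1)) with its confidence interval;
  Cronbach's alpha treats observed and predicted as two items. Identical
  inputs short-circuit to exactly 1.0 (the ANOVA ratio is 0/0-adjacent
  there); zero variance in either column sets a degenerate flag.
- **Regressions**: ordinary least squares via `scipy.stats.linregress`;
  R² equals the squared Pearson correlation by construction.

The reliability/regression statistics are data-dependent descriptions of
whatever cohort they are run on; the tests verify them against long-hand
transcriptions of the defining formulas, not against any published value.

## Synthetic cohorts

The generator emulates a small population-register ALS cohort, with all
defaults chosen from that register's published descriptive statistics and
fixed in `SimulationConfig`:

- 20 patients, 35% slow progressors;
- visit counts ~ Normal(4.5, 2.2), clipped to [3, 11] and rounded;
- onset age ~ Normal(59.3, 13.49), sex ≈ 45/55 male/female, onset site ≈
  30/35/25/10 bulbar/lower-limb/upper-limb/unknown (generated for I/O
  realism; the model never uses demographics);
- fast progressors: `D50 ~ U(14, 52)`, `dx ~ U(2, 12)` months — the range
  of published fitted values; slow progressors: `D50 ~ U(59, 282)` months
  (the published slow-group range) and `dx ~ U(30, 150)` months, the shape
  values whose midpoint tangents correspond to slopes of 0.08–0.40
  points/month;
- visit schedules anchored to each patient's own curve: the first visit
  where the curve crosses a draw from Normal(40.8, 4.7) (the first-score
  distribution), the last where it crosses a draw from Normal(25.15, 7.9),
  capped at a 60-month maximum follow-up (so slow progressors are observed
  only on their plateau — the mechanism behind their degenerate fits);
  visits evenly spaced in between with ±30% jitter, spacing distribution
  being unreported anywhere and chosen here as the simplest defensible
  scheme;
- scores = curve + Normal(0, 2) noise, clamped to [0, 48], rounded to
  integers (the instrument is integer-valued; Gaussian-then-clamp is the
  simplest noise model consistent with that); with probability 0.10 one
  mid-course visit gains +5 points above trend, emulating observed
  transient functional improvements.

What the generator does **not** emulate: informative dropout near death,
measurement error correlated across visits, rater effects, sub-score
dynamics, and any covariate influence on progression. Passing tests on
these cohorts therefore demonstrate correctness of the pipeline's
mechanics and its behaviour under the stated noise model — not clinical
validity on register data.

Problem sizes used in the test suite (chosen to keep Monte-Carlo error
small at interactive runtimes): 200 replicate datasets for recovery and
coverage experiments, 1000 bootstrap replicates per dataset in the coverage
experiment, cohorts of 120–500 patients for share/statistics checks.

## Known limitations

- The logistic form cannot represent transient gains; fits through such
  visits are systematically biased around them.
- Slow progressors observed only pre-midpoint are fundamentally
  unidentifiable under this model (the data contain almost no information
  about `D50` or `dx`); the package surfaces this as degenerate/boundary
  statuses rather than extrapolating.
- Bootstrap intervals are anticonservative at very small visit counts (see
  above).
- No pooling across patients: every fit is per-subject, so a hierarchical
  model would be needed to borrow strength for sparse trajectories.
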