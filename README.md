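# alsprog — logistic (D50/dx) modelling of ALS functional decline

Amyotrophic lateral sclerosis (ALS) is monitored clinically with the revised
ALS Functional Rating Scale (ALSFRS-R): 12 items scored 0–4, summing to a
total from 48 (normal function) down to 0 (maximum disability). Decline is
not linear — patients plateau near baseline, pass through a phase of steady
deterioration and flatten again late in disease. `alsprog` models each
patient's trajectory with a sigmoidal logistic decay,

    y(x) = Ymax / (1 + exp((x − D50) / dx)),    Ymax = 48,

where `x` is months since symptom onset, `D50` is the month at which the
modelled score reaches half the maximum (24 points, the inflection) and
`dx` (months) sets the steepness of the transition; the tangent slope at
the midpoint is `−Ymax/(4·dx)` points/month.

The package is for biostatisticians and clinical researchers working with
longitudinal ALSFRS-R data. It provides:

- **trajectory I/O** — long-format CSV in/out, 12-item sub-score summation,
  chronological reordering, strict validation (`alsprog.trajectory_io`);
- **initialization** — conventional linear slope (two-point or
  onset-anchored) and its translation into starting values for `dx` and
  `D50`, in two modes: `converted` (`48/(4·slope)`, the numerically sound
  default) and `paper` (the slope passed verbatim as `dx`, which reproduces
  a historically important failure mode — see below)
  (`alsprog.initial_estimation`);
- **fitting** — per-patient bounded nonlinear least squares with explicit
  statuses (`converged`, `degenerate_initial`, `boundary`, `failed`),
  case-resampling bootstrap percentile confidence intervals, and an
  unconstrained-asymptote diagnostic (`alsprog.model_fitting`);
- **cohort analysis** — slow/fast progressor classification at 0.365
  points/month, descriptive summaries of initial vs optimal parameters,
  observed-vs-predicted reliability (R², two-way absolute-agreement ICC,
  Cronbach's alpha) and parameter regressions (`alsprog.cohort_analysis`);
- **synthetic cohorts** — a register-like generator with known ground truth
  (slow/fast mixture, realistic visit counts and score ranges, transient
  score gains) so the whole pipeline is testable without patient data
  (`alsprog.synthetic_cohort`);
- **a CLI** — `alsprog simulate | fit | classify | summarize | agreement |
  report`, each writing a JSON run manifest.

A methodological point the package makes explicit: when the points/month
slope is fed in directly as the shape parameter `dx` (the `paper` init
mode), slow progressors (slope < 0.365) get a near-vertical initial curve
— flat at 48, then a cliff — far from their data. The optimizer sees a
numerically zero gradient and stops at the initial values; `alsprog`
reports this as `degenerate_initial` rather than pretending convergence.
With the `converted` mode the same patients usually fit.

## Worked example

```python
from alsprog import (LogisticParams, predict_score, time_at_score,
                     midpoint_slope, truncate_display)

p = LogisticParams(d50=51.724, dx=17.184)   # a representative fitted patient
for x in (40, 48, 118, 159):
    print(f"month {x:>3}: model {predict_score(p, x):7.3f}  "
          f"display {truncate_display(predict_score(p, x), 1)}")
print("midpoint slope:", round(midpoint_slope(p), 4), "points/month")
print("months to score 12:", round(time_at_score(p, 12.0), 1))
```

prints

```
month  40: model  31.884  display 31.8
month  48: model  26.590  display 26.5
month 118: model   0.993  display 0.9
month 159: model   0.093  display 0.0
midpoint slope: -0.6983 points/month
months to score 12: 70.6
```

This patient crosses the scale midpoint (24 points) at 51.7 months,
declining about 0.7 points/month there; the model's displayed scores at 40
and 48 months (31 and 26 after integer truncation) sit above the observed
dip this patient actually had — the logistic cannot follow a transient
functional gain. The late tail (0.9 points at 118 months, 0.0 at 159) shows
the saturating approach to complete loss of function.

The full pipeline on a synthetic cohort:

```bash
alsprog report --seed 1 --n-patients 20 --out-dir run
# ...
# R2=0.965 ICC=0.982 alpha=0.991 over 87 pairs
```

which leaves `cohort.csv`, `ground_truth.csv`, `fits.csv`, `fits.json`,
`classification.csv`, `summary.csv` and `agreement.json` in `run/`. The
agreement line says model predictions track observed scores closely for the
converged patients (R² of 0.965 over 87 visit pairs); `summary.csv` holds
the per-group (converged vs not) descriptive statistics of initial and
optimal `dx`/`D50`.

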