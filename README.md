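# mcgurksim

Monte-Carlo simulation of what a significance-filtered literature reports
about group differences in McGurk susceptibility.

## The problem

The McGurk effect — an illusion in which incongruent auditory and visual
speech fuse into a new percept — is a standard assay of multisensory
integration, and group differences in susceptibility (clinical vs control,
across cultures, genders, ages) are widely reported. But susceptibility
varies enormously *within* groups: in large samples of healthy young adults
the between-subject SD is close to 37 percentage points and the
distribution is strongly bimodal (many people essentially never fuse, many
almost always do). When small studies of such a population are run through
a two-sample *t*-test and only `p < 0.05` results are published, the
published effect sizes are systematically inflated and occasionally have
the wrong sign.

`mcgurksim` is a library for quantifying that distortion. It provides:

* **`cohort`** — a calibrated generator of synthetic populations of
  per-subject, per-stimulus susceptibilities (bounded bimodal mixture,
  positive within-subject correlation across stimuli, between-stimulus
  variation in efficacy);
* **`engine`** — the simulated experiment: bootstrap resampling, balanced
  group assignment, a calibrated group shift with [5, 95] truncation,
  binomial trial noise, and a pooled-variance *t*-test, replicated to
  long-run scale with per-replication random substreams;
* **`metrics`** — statistical power, effect inflation (Type M /
  exaggeration ratio), sign-error rate (Type S), published/discarded
  estimate means, and a closed-form normal-theory oracle;
* **`explorer`** — factorial sweeps over sample size `N`, true difference
  `E`, stimulus count `S` and trials `T`, plus power-curve inversion
  ("how many subjects for 80% power?");
* **`meta`** — loading and summarizing study-comparison tables (e.g.
  ASD-vs-TD reviews) and linking them to simulation predictions.

The key quantities, for a design with true difference `E`:

* power = P(p < 0.05),
* Type M (inflation) = E[ |Ê| / |E| given p < 0.05 ],
* Type S (sign error) = P( sign(Ê) ≠ sign(E) given p < 0.05 ),

and the decomposition `power · E[Ê | published] + (1 − power) ·
E[Ê | discarded] = E[Ê]`, which equals the true realized difference: the
significance filter redistributes estimates, it does not create bias in the
unfiltered mean.

## Worked example

```python
from mcgurksim import (StudyDesign, calibrate_shift, default_cohort_params,
                       run_replications, summarize_longrun)

params = default_cohort_params()           # bimodal, mean 45%, SD 36.7%
shift = calibrate_shift(10.0, params, seed=0)  # ~15 points for a realized 10

for n_total in (300, 30):
    design = StudyDesign(n_total=n_total, true_diff=10.0, shift=shift,
                         n_stimuli=8, n_trials=100)
    s = summarize_longrun(run_replications(design, params, 4000, seed=11))
    print(n_total, s.power, s.published_mean, s.inflation, s.sign_error_rate)
```

This (the bundled `examples/03_significance_filter.py`) prints:

```
N = 300: power 67%  published mean +12.4%  discarded mean +5.4%  inflation x1.2  sign errors 0.0%  unfiltered mean +10.1%
N = 30:  power 11%  published mean +31.2%  discarded mean +7.4%  inflation x3.3  sign errors 2.8%  unfiltered mean +10.0%
```

Read it as: with a true 10-point group difference, an N = 300 study is
published two times in three and the published literature overstates the
difference only mildly (12.4 vs 10). At the field-typical N = 30, barely
one study in nine is published, the published mean difference is three
times the truth, and ~3% of published studies get the direction wrong —
while the *unfiltered* mean is accurate at both sample sizes.

The other example scripts cover cohort generation (`01`), a single
simulated experiment (`02`), design planning and power-curve inversion
(`04`), and connecting a literature table of small studies to the
simulation's predicted published estimate (`05`). Each runs in roughly a
minute or less.

A thin CLI wraps the same functions:

```bash
mcgurksim simulate --n 30 --diff 10 --reps 5000 --seed 1 --out run/
mcgurksim sweep --n 30,100,300 --diff 5,10,20 --out sweep/
mcgurksim calibrate --targets 5,10,20,30 --out cal/
mcgurksim power --target-power 0.8 --diff 20 --n-grid 60,100,140,180 --out pow/
mcgurksim meta --table comparisons.csv --predict 3,36 --out meta/
```

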