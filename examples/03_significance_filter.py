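"""The significance filter in the long run: power, Type M and Type S errors.

Repeats the same 10-point-difference experiment thousands of times at
N=300 and N=30 and compares what 'the published literature' (significant
studies only) would report at each sample size.
"""

from mcgurksim import (
    StudyDesign,
    calibrate_shift,
    default_cohort_params,
    run_replications,
    summarize_longrun,
)

params = default_cohort_params()
shift = calibrate_shift(10.0, params, seed=0)

for n_total in (300, 30):
    design = StudyDesign(n_total=n_total, true_diff=10.0, shift=shift,
                         n_stimuli=8, n_trials=100)
    reps = run_replications(design, params, n_reps=4000, seed=11)
    s = summarize_longrun(reps)
    print(f"N = {n_total}: power {100 * s.power:.0f}%  "
          f"published mean {s.published_mean:+.1f}%  "
          f"discarded mean {s.discarded_mean:+.1f}%  "
          f"inflation x{s.inflation:.1f}  "
          f"sign errors {100 * s.sign_error_rate:.1f}%  "
          f"unfiltered mean {s.weighted_recovery:+.1f}%")

print("-> the unfiltered mean recovers the true 10% at every N; "
      "the published-only mean is accurate at N=300 but roughly "
      "threefold inflated at N=30.")
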