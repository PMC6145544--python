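"""Connect the simulation to a literature of small studies.

Loads a synthetic 13-comparison ASD-vs-TD table (the shape real review
tables take), summarizes it, and asks: if the true difference were the
3 points reported by the largest study, what would significance-filtered
studies at the literature's typical sample size report on average?
"""

from mcgurksim import (
    default_cohort_params,
    load_comparison_table,
    make_example_table,
    predict_published_estimate,
    summarize_comparisons,
)

path = "scratch_example_table.csv"
make_example_table(path)
records = load_comparison_table(path)
summary = summarize_comparisons(records)
print(f"{summary['n_total']} comparisons, median TD-ASD difference "
      f"{summary['median_diff']:.0f}%, range [{summary['min_diff']:.0f}, "
      f"{summary['max_diff']:.0f}]%, mean total sample size "
      f"{summary['mean_sample_size']:.0f}")

params = default_cohort_params()
pred = predict_published_estimate(
    anchor_true_diff=3.0, typical_n=36, cohort=params, n_reps=6000, seed=5,
)
print(f"if the true difference is 3%: power {100 * pred['power']:.0f}%, "
      f"published magnitude ~{pred['inflation'] * 3:.0f}% "
      f"(x{pred['inflation']:.1f} inflation)")
print("-> a 3-point truth plus a significance filter reproduces the large "
      "median difference the small-study literature reports.")
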