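"""Detect disease-linked age acceleration with matched cohorts.

Participants with an isolated serious condition are compared to healthy
test-set controls matched on age, sex and living area (nearest
neighbour, sampled with replacement). The delta column is the mean
difference in clock error — the extra biological years attributed to the
condition. The generator injects +2.2 y for lung disease, +1.49 y for
stroke, −1.07 y for cancer, etc., so the measured deltas should track
those values within sampling noise.
"""

import pandas as pd

from bloodclock import (
    SyntheticConfig,
    assign_sets,
    exclude_invalid,
    generate_cohort,
    predict_age,
    run_disease_association,
    train_clock,
)

config = SyntheticConfig(n_participants=8_000, seed=21)
cohort, _ = generate_cohort(config)
clean, _ = exclude_invalid(cohort)
splits = assign_sets(clean, seed=22)
train = splits.subset(clean, "train")
test = splits.subset(clean, "test")
discovery = splits.subset(clean, "discovery")

model, _ = train_clock(train, seed=23)
predictions = predict_age(model, pd.concat([test, discovery], ignore_index=True))

report = run_disease_association(discovery, test, predictions, seed=24)
cols = ["condition", "delta_years", "p_value", "n_afflicted", "mean_age_diff_years"]
print(report[cols].round(3).to_string(index=False))
print(
    "\ndelta_years > 0 with a small two-sided Mann-Whitney p-value means the"
    "\ncondition's carriers are predicted biologically older than matched"
    "\nhealthy controls; mean_age_diff_years near 0 confirms the matching."
)
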