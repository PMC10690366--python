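"""The statistical battery on a synthetic cohort: two-rater ICC per
structure, height/weight vs score correlations, the sex difference, and
the age-month ANOVA, plus the month-wise share of non-measurable images.
"""

import numpy as np

from hipscore import (
    CohortConfig,
    anova_oneway,
    below_threshold_by_month,
    composite_scores,
    generate_cohort,
    generate_scores,
    icc,
    pearson_r,
    ttest_independent,
)
from hipscore.scoring import STRUCTURES

config = CohortConfig(seed=1)
cohort = generate_cohort(config)
scores = generate_scores(cohort, config)

for s in STRUCTURES:
    wide = scores.pivot(index="image_id", columns="rater_id", values=s)
    print(f"two-rater ICC(A,1) for {s}: {icc(wide.to_numpy(float)).icc:.2f}")

merged = cohort.merge(composite_scores(cohort, config), left_on="id", right_on="image_id")
for cov in ("height_cm", "weight_kg"):
    r, p = pearson_r(merged[cov], merged["q"])
    print(f"Pearson r({cov}, q) = {r:+.2f} (p = {p:.3g})")

t, p = ttest_independent(
    merged.loc[merged.sex == "male", "q"], merged.loc[merged.sex == "female", "q"]
)
print(f"sex difference: t = {t:.2f} (p = {p:.3g}); "
      f"means m/f = {merged.groupby('sex')['q'].mean().round(2).to_dict()}")

f, p = anova_oneway([g["q"].to_numpy() for _, g in merged.groupby("age_months")])
print(f"age-month ANOVA: F = {f:.2f} (p = {p:.3g})")

print("share of non-measurable images by month:",
      below_threshold_by_month(merged["age_months"], merged["q"]))

# Heavier (hence older/bigger) infants tend to produce poorer images, so the
# weight correlation is strongly negative and the below-threshold share rises
# with age — the pattern that motivates an individualized suitability model.
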