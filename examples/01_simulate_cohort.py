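"""Simulate a study-shaped infant cohort with two-rater rubric scores.

Draws the default 290-infant cohort (50 each at months 5-8, 30 each at
months 9-11), simulates both raters' integer scores for the three
anatomical structures, and prints summaries.
"""

from hipscore import CohortConfig, generate_cohort, generate_scores

config = CohortConfig(seed=1)
cohort = generate_cohort(config)
scores = generate_scores(cohort, config)

print("cohort size:", len(cohort))
print("per-month counts:", cohort["age_months"].value_counts().sort_index().to_dict())
print(cohort.head(3).to_string(index=False))
print("\nfirst image's two-rater scores:")
print(scores.head(2).to_string(index=False))

# Heights/weights rise ~1.4 cm and ~0.3 kg per month; each rater's brp/lil/gl
# scores are the infant's latent image quality plus structure and rater noise,
# rounded to the 1-5 rubric.
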