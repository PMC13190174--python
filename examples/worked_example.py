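"""Aggregate a hand-specified score profile into an overall suitability.

Feeds a hypothetical trial cohort's per-feature coverage and completeness
percentages through the clinical weighting scheme and the 60/40 combination.
"""

from trialfit import Feature, aggregate, suitability

coverage = {
    Feature.GENDER: 98.0,
    Feature.AGE_GROUP: 91.0,
    Feature.ETHNICITY: 89.0,
    Feature.WEIGHT_GROUP: 86.0,
    Feature.RELIGION: 82.5,
    Feature.LANGUAGE: 79.0,
    Feature.MARITAL_STATUS: 85.0,
}
completeness = {
    Feature.AGE_GROUP: 89.0,
    Feature.ETHNICITY: 95.0,
    Feature.GENDER: 100.0,
    Feature.WEIGHT_GROUP: 62.0,
    Feature.RELIGION: 80.0,
    Feature.LANGUAGE: 56.0,
    Feature.MARITAL_STATUS: 88.0,
}

cov = aggregate(coverage)
comp = aggregate(completeness)
print(f"overall coverage:     {cov:.3f}%")
print(f"overall completeness: {comp:.1f}%")
print(f"suitability (full-precision coverage): {suitability(cov, comp):.1f}%")
print(f"suitability (coverage rounded to 90):  {suitability(90.0, comp):.1f}%")
# Coverage is the weighted demographic similarity to the target, completeness
# the weighted share of valid data; suitability blends them 60/40 into one
# fitness-for-purpose score.  Scores are carried at full precision and
# rounded only for display, so the two suitability lines differ when the
# overall coverage is rounded before the final combination.
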