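"""Simulate a synthetic adolescent cohort and inspect its composition.

Generates questionnaire-level records from the second-order well-being
factor model (default: the published standardized loadings), injects the
three exclusion mechanisms stochastically, and writes a cohort CSV.
"""

import pwbi

params = pwbi.PopulationParams()
cohort = pwbi.generate_cohort(params, n=1659, seed=42)
cohort = pwbi.inject_exclusions(cohort, params, seed=43)
pwbi.write_cohort(cohort, "cohort.csv")

n = len(cohort)
print(f"students generated      : {n}")
print(f"proportion male         : {(cohort['sex'] == 'M').mean():.3f}")
print(f"mean age (years)        : {cohort['age'].mean():.2f} "
      f"(SD {cohort['age'].std(ddof=1):.2f})")
print(f"without consent         : {(~cohort['consent']).sum()}")
print(f"diagnosed condition     : {cohort['diagnosed_condition'].sum()}")
missing = cohort.isna().any(axis=1).sum()
print(f"incomplete questionnaire: {missing}")

# The flags mimic a school enrolment: most students are eligible, a
# minority carries one (occasionally several) of the three disqualifiers.
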