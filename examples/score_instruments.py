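"""Score raw questionnaire responses into the 14 model indicators.

Each student's KIDSCREEN-52, KIDMED, PAQ-C, Stroop and school-grade
responses collapse into the observed variables of the well-being model:
ten 0-100 quality-of-life dimensions, a 0-12 diet index, a 1-5 activity
score, a Stroop interference score and a 1-10 school-performance mean.
"""

import pwbi

params = pwbi.PopulationParams()
cohort = pwbi.generate_cohort(params, n=5, seed=7)

vec = pwbi.score_all(cohort.iloc[0])
print(f"student {cohort.iloc[0]['student_id']}:")
for name, value in vec.as_dict().items():
    print(f"  {name:24s} {value:8.2f}")

table = pwbi.score_cohort(cohort)
print("\ncohort indicator table (first rows):")
print(table.head(3).round(2).to_string(index=False))

# Higher is better on every indicator (bullying is keyed so that a high
# score means little bullying; Stroop interference so that a high score
# means stronger executive function).
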