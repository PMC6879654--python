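"""Table-style cohort characterization with exact categorical tests.

Continuous variables are mean +/- SEM, categorical ones n (%); a 2x2
Fisher's exact test (full hypergeometric enumeration) compares outcome
rates between cohorts.
"""

import traumanet as tn
from traumanet.cohort import ContingencyTable2x2

patients, _ = tn.generate_cohort(tn.SyntheticConfig(n_day=40, n_night=40, seed=7))
day = [p for p in patients if p.group == "Day"]
night = [p for p in patients if p.group == "Night"]

summary = tn.summarize_cohort(day)
age = summary[summary.variable == "age"].iloc[0]
print(f"day cohort age: {age['mean']:.1f} +/- {age['sem']:.1f} years (n={len(day)})")

ni_day = sum(p.nosocomial_infection for p in day)
ni_night = sum(p.nosocomial_infection for p in night)
print(f"nosocomial infection: day {ni_day}/{len(day)} "
      f"({tn.percent(ni_day, len(day))}%), night {ni_night}/{len(night)} "
      f"({tn.percent(ni_night, len(night))}%)")

table = ContingencyTable2x2(ni_day, len(day) - ni_day,
                            ni_night, len(night) - ni_night)
p = tn.fisher_exact_2x2(table)
print(f"Fisher's exact two-sided p = {p:.3f}")
print("p is the exact probability, under fixed margins, of a table at "
      "least as unlikely as the observed infection split.")
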