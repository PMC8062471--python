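"""Group analysis on a synthetic sex x stress cohort.

Generates the default 64-subject cohort (high-stress females get a higher
mean probability-weighting slope than high-stress males), scores
performance, runs the two-way ANOVA on fitted weighting slopes, and the
covariate-adjusted sex-difference GLM under high stress.
"""

import pandas as pd

from stressrl import default_cohort_spec, fit_map, generate_cohort
from stressrl.analysis import performance_table, sex_difference_glm, two_way_anova

subjects = generate_cohort(default_cohort_spec(n_per_group=16, seed=0))
perf = performance_table(subjects)

print("mean proportion correct by cell:")
print(perf.groupby(["stress_group", "sex"]).prop_correct.mean().round(3))

rows = []
for i, s in enumerate(subjects):
    fit = fit_map("s1w", s.trials, n_restarts=30, seed=100 + i)
    rows.append({"subject_id": s.subject_id, "alpha": fit.params.alpha,
                 "gamma": fit.params.gamma})
params = pd.DataFrame(rows)

fitted = perf.merge(params, on="subject_id")
print("\nmean fitted weighting slope (gamma) by cell:")
print(fitted.groupby(["stress_group", "sex"]).gamma.mean().round(3))

anova = two_way_anova(fitted, dv="gamma")
print("\ntwo-way ANOVA on fitted gamma:")
print(anova[["F", "PR(>F)"]].round(4))

glm = sex_difference_glm(perf, params)
print("\nhigh-stress sex-difference GLM (male = 1), all trials:")
print(glm[glm.scope == "all"].to_string(index=False))
print("\nThe sex:stress interaction on gamma shows the generator's effect")
print("structure is recovered from fits; in the GLM, the 'attenuation'")
print("column says how much of the sex coefficient each fitted-parameter")
print("covariate absorbs.")
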