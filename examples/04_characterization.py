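"""Post-hoc characterization: which feature groups define each cluster?

For each (cluster, feature group) pair a one-sample t-test compares the
cluster's mean composite against the all-participant mean, Bonferroni
corrected over the whole K x G family at family-wise alpha 0.05.  Cells
show the direction and strength of the deviation (+ / ++ / +++ elevated,
minus signs depressed, N.S. not significant); the direction pattern maps to
a clinical-style interpretation.
"""

import delirclust as dc

cohort = dc.simulate(dc.default_design(), seed=17)
X = dc.to_wide(cohort.scores)
grouping = dc.group_features(X, restarts=200, master_seed=1)
Xr = dc.reduce(X, grouping)
pc = dc.cluster_participants(Xr, restarts=200, master_seed=2)

profile = dc.posthoc_profile(Xr, pc.solution)
roles = dc.infer_roles({grouping.name_of(g): grouping.members(g)
                        for g in range(grouping.G)})
dc.interpret_labels(profile, roles)

print(f"family size m = {profile.m_tests} tests, "
      f"per-test threshold {profile.config.alpha_fwer / profile.m_tests:.2e}")
table = profile.sign_table()
table["interpretation"] = profile.labels
print(table.to_string())

# covariate screen: the simulated age/MMSE carry no cluster signal, so the
# ANOVA p-values should look uniform
from delirclust.posthoc import anova_table  # noqa: E402

anova = anova_table(cohort.meta.table[["age", "mmse"]], pc.solution)
print(anova.to_string(index=False))
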