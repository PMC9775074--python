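"""Group comparisons on a synthetic cohort.

One-way ANOVA on the ALPS index across the four diagnostic groups, a
covariate-adjusted general linear model, chi-square on a categorical
marker, and the partial correlation between white-matter-hyperintensity
burden and the ALPS index controlling for demographics.
"""

import numpy as np

import alps_glymph as ag
from alps_glymph import cohort_scoring as sc
from alps_glymph import group_stats as gs
from alps_glymph.synthetic_data import GROUPS

df = sc.transform_markers(ag.generate_cohort(ag.CohortSpec(seed=7)))

# unadjusted ANOVA on the ALPS index
groups = [df.loc[df["group"] == g, "alps_index"].to_numpy() for g in GROUPS]
res = gs.anova_oneway(groups)
print(f"ALPS one-way ANOVA: F = {res.statistic:.2f}, p = {res.p_value:.2e}")

# adjusted for gender, age, hypertension and education
cov = np.column_stack([
    (df["gender"] == "F").astype(float),
    df["age"],
    df["hypertension"].astype(float),
    df["education"],
])
adj = gs.glm_adjusted(df["alps_index"], df["group"], cov,
                      covariate_names=["gender", "age", "hypertension", "education"])
print(f"adjusted group effect: F = {adj.statistic:.2f}, p = {adj.p_value:.2e}")
print(adj.posthoc[["contrast", "estimate", "p_bonferroni"]].round(4).to_string(index=False))

# chi-square on basal-ganglia enlarged perivascular spaces
table = np.array([
    [(df[df["group"] == g]["epvs"] == v).sum() for g in GROUPS] for v in (1, 0)
])
chi = gs.chi_square_test(table)
print(f"\nEPVS chi-square: chi2 = {chi.statistic:.3f}, p = {chi.p_value:.3g}")

# partial correlation within the CSVD subsample
csvd = df[df["group"] != "NC"]
z = np.column_stack([(csvd["gender"] == "F").astype(float), csvd["age"], csvd["education"]])
pc = gs.partial_corr(csvd["log_wmh"], csvd["alps_index"], z)
print(f"WMH-ALPS partial r = {pc.statistic:.3f}, p = {pc.p_value:.2e}")
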