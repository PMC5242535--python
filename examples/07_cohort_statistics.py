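"""The cohort statistics layer: Grubbs screen, three-way ANOVA,
Bonferroni-corrected correlations.

Screens a generated behavioural table for outliers cell by cell, fits the
between-subject Genotype x Sex x Age ANOVA on locomotor activity, and
builds the Bonferroni-gated Pearson correlation matrix across measures at
the final age.
"""
from neuropheno.cohort_stats import (
    bonferroni_correlations,
    factorial_anova,
    screen_cohort,
)
from neuropheno.synthetic import default_trajectory_config, generate_cohort

traj = default_trajectory_config(missing_rate=0.05, outlier_rate=0.03)
table = generate_cohort(traj, n_per_cell=10, ages=[16, 36, 70, 94], seed=4)

screened = screen_cohort(table)
print(f"Grubbs screen flagged {screened['outlier'].sum()} of "
      f"{screened['value'].notna().sum()} observations "
      f"(injected outlier rate 3%)")

loco = screened[screened["measure"] == "locomotor_distance"]
res = factorial_anova(loco, ["genotype", "sex", "age_weeks"])
for term in ("genotype", "sex", "age_weeks", "genotype:sex"):
    df1, df2 = res.dof(term)
    print(f"F({term})_{df1:.0f};{df2:.0f} = {res.f(term):8.3f}, p = {res.p(term):.4g}")

final = screened[(screened["age_weeks"] == 94) & ~screened["outlier"]]
wide = final.pivot_table(index="subject", columns="measure", values="value")
plan = bonferroni_correlations(wide)
print(f"\n{plan.n_comparisons} pairwise correlations, "
      f"Bonferroni-adjusted alpha = {plan.adjusted_alpha:.4f}")
print("significant pairs after correction:")
for a in plan.measures:
    for b in plan.measures:
        if a < b and plan.significant.loc[a, b]:
            print(f"  {a} ~ {b}: r = {plan.r.loc[a, b]:.2f}")
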