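"""Three-group differential expression with BH-FDR control.

Fits the one-way ANOVA + pairwise-contrast model on a simulated cohort
and prints the DEG tallies and the Venn partition of DEGs across the
three contrasts.
"""

from granulosig.dge import deg_summary, fit_dge, venn_partition
from granulosig.simulate import study_config, simulate_cohort

cohort = simulate_cohort(study_config(n_genes=4000, seed=0))
table = fit_dge(cohort.expr, cohort.samples)

s = deg_summary(table)
print(f"{s['n_deg']} of {s['n_genes']} genes differentially expressed "
      f"({s['deg_fraction_pct']:.1f}%) in at least one contrast")
for c in ("sepsis_vs_presurgical", "SIRS_vs_presurgical", "sepsis_vs_SIRS"):
    print(f"  {c:24s} {s[f'{c}_pct_of_degs']:5.1f}% of DEGs "
          f"({s[f'{c}_unique_pct_of_degs']:.1f}% unique)")

part = venn_partition(table)
print("\nVenn regions (top rows):")
print(part.updown.head(7))
print(
    "\nPlanted sepsis-specific effects concentrate in the regions that "
    "contain both sepsis contrasts; with this generator SIRS and "
    "presurgical controls differ only mildly, so most DEGs involve sepsis."
)
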