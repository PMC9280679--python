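"""Score the six granule-compartment signatures per patient group.

"Targeting by timing": each granule compartment's genes are transcribed
in a specific maturation window, so their bulk CD15+ levels report the
abundance of the matching precursor stages.
"""

from granulosig.dge import fit_dge
from granulosig.signatures import (
    global_compartment_expression,
    summarize_compartment,
)
from granulosig.simulate import study_config, program_gene_sets, simulate_cohort

cohort = simulate_cohort(study_config(n_genes=4000, seed=0))
table = fit_dge(cohort.expr, cohort.samples)
sets = program_gene_sets(cohort.truth.profiles, ["AG", "SG", "GG", "FG", "SV", "CM"])
summ = summarize_compartment(cohort.expr, cohort.samples, sets, deg_filter=table)

tab = global_compartment_expression(summ)
cols = ["n_genes", "global_presurgical", "global_SIRS", "global_sepsis",
        "fold_sepsis_vs_SIRS", "fold_SIRS_vs_presurgical"]
print(tab[cols].round(2))
for comp in summ:
    if comp.n_deg is not None:
        print(f"{comp.name}: {comp.n_deg}/{comp.n_in_universe} signature genes "
              "differentially expressed")
print(
    "\nAzurophilic (AG) granule genes are elevated in sepsis only; "
    "specific (SG) granule genes rise stepwise presurgical -> SIRS -> "
    "sepsis; late compartments (FG/SV/CM) barely move — the transcriptional "
    "fingerprint of sepsis-accelerated granulopoiesis."
)
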