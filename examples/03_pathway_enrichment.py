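"""Gene-set enrichment of stage-restricted programs, sepsis vs. SIRS.

Ranks genes by the signed contrast t statistic and scores the
generator's program gene sets with the weighted running-sum enrichment
statistic, normalized against a sample-permutation null.
"""

from granulosig.config import AnalysisConfig
from granulosig.enrichment import rank_genes, run_enrichment
from granulosig.simulate import study_config, program_gene_sets, simulate_cohort

cohort = simulate_cohort(study_config(n_genes=4000, seed=0))
sets = program_gene_sets(
    cohort.truth.profiles,
    ["lysosome", "cellcycle", "mito", "proteasome", "ribosome", "FG", "SV", "CM"],
)
ranked = rank_genes(cohort.expr, cohort.samples, ("sepsis", "SIRS"))
table = run_enrichment(
    ranked,
    sets,
    AnalysisConfig(n_permutations=100, seed=0),
    expr=cohort.expr,
    samples=cohort.samples,
    contrast=("sepsis", "SIRS"),
)
print(table[["size", "es", "nes", "p", "fdr_q", "enriched_group"]].round(3))
print(
    "\nPrograms expressed by immature precursors (lysosome, cell cycle, "
    "mitochondrial, proteasome, ribosome) score positive NES in sepsis; "
    "late-stage compartments (FG/SV/CM) do not — the hallmark of an "
    "expanded immature compartment rather than per-cell regulation."
)
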