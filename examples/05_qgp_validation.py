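"""Bead-array validation of a candidate shortlist.

Simulates a QuantiGene-Plex-style plate for 20 planted (4-fold in
sepsis) and 20 null genes, normalizes it against a reference gene with
background masking, and runs the confirmation + Mann-Whitney +
Bonferroni validation scheme.
"""

from granulosig.config import AnalysisConfig
from granulosig.qgp import normalize_qgp, validate_degs
from granulosig.selection import merge_selection
from granulosig.simulate import CohortConfig, simulate_cohort

planted = [(f"HK{i + 1:05d}", "sepsis", 4.0) for i in range(20)]
cfg = CohortConfig(
    n_genes=200,
    n_per_group={"presurgical": 0, "SIRS": 22, "sepsis": 18},
    sigma_tech=0.35,
    qgp_duplicate_cv=0.1,
    qgp_reference_gene="HK00100",
    planted_genes=planted,
    seed=0,
)
genes = [f"HK{i + 1:05d}" for i in range(40)]
cohort = simulate_cohort(cfg, qgp_genes=genes)

norm = normalize_qgp(cohort.plate)
n_missing = int(norm.values.isna().to_numpy().sum())
print(f"plate: {len(genes)} genes x {len(cohort.samples)} samples, "
      f"{n_missing} signals at/below background -> treated as missing")

out = validate_degs(norm, cohort.samples, merge_selection([], genes, []),
                    AnalysisConfig())
tp = int(out.loc[genes[:20], "validated"].sum())
fp = int(out.loc[genes[20:], "validated"].sum())
print(f"confirmed in both groups: {int(out['confirmed_both'].sum())}/40")
print(f"validated: {tp}/20 planted genes, {fp}/20 null genes")
print("\nexample rows:")
print(out.loc[[genes[0], genes[39]],
              ["n_sepsis", "n_SIRS", "fold", "mwu_p", "p_bonf_global",
               "validated"]].round(5))
print(
    "\nA planted gene shows a ~4-fold normalized-signal ratio and a tiny "
    "Bonferroni-adjusted p; null genes stay unvalidated."
)
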