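# granulosig

Analysis pipeline for bulk CD15⁺ granulocyte transcriptomes that asks a
clinically loaded question: can the blood granulocyte compartment
distinguish **sepsis** from sterile **SIRS** (systemic inflammatory
response syndrome) on ICU admission?

CD15⁺ cells span all stages of terminal granulocytic differentiation —
(late) promyelocyte (LPM) → myelocyte (MY) → metamyelocyte (MM) → band
cell (BC) → mature neutrophil (PMN). Under emergency granulopoiesis,
immature precursors spill into blood. Because granule biogenesis follows
the "targeting by timing" rule — azurophilic (AG) granule genes are
transcribed at the promyelocyte stage, specific (SG) granule genes at
the myelocyte/metamyelocyte stages, later compartments (gelatinase GG,
ficolin FG, secretory vesicles SV, cell membrane CM) afterwards — the
bulk expression of each compartment's signature genes reports the
abundance of the matching precursor stage. A sepsis-specific left shift
therefore leaves a readable transcriptional fingerprint.

## What the package does

For a gene × sample expression matrix (linear-scale normalized
intensities) with three patient groups (presurgical, SIRS, sepsis):

* **`granulosig.dge`** — per-gene one-way ANOVA on log₂ values with the
  three pairwise contrasts tested by pooled-variance t; per-contrast
  Benjamini–Hochberg FDR (gene *g* is a DEG in contrast *c* iff
  *q(g,c)* ≤ α, default 0.05); linear fold changes
  FC = max(x̄₁/x̄₂, x̄₂/x̄₁) with a direction sign; Venn partition of the
  DEG universe.
* **`granulosig.enrichment`** — weighted Kolmogorov–Smirnov running-sum
  enrichment score on the signed-t ranking (weight |t|, exponent 1),
  sample-label permutation null, NES = ES / mean |null ES of matching
  sign|, FDR-q by the pooled positive/negative null convention.
* **`granulosig.selection`** — the three shortlisting strategies:
  (1) top-q genes of the joined high-expression DEG pools plus a
  quartile range-separation rule, (2) >2-fold sepsis/SIRS with <1.1-fold
  SIRS/presurgical, (3) lysosomal genes in the high-expression pool.
* **`granulosig.qgp`** — bead-array (QuantiGene-Plex-style) processing:
  duplicate averaging, at-or-below-background → missing, reference-gene
  normalization; "confirmed" = ≥4 above-background samples per group;
  two-sided Mann–Whitney U (exact by enumeration for small samples) with
  Bonferroni adjustment per strategy list and globally; validated =
  any adjusted p < α.
* **`granulosig.signatures`** — per-compartment group means and the
  global compartment expression (unweighted mean over signature genes of
  per-gene group means) with pairwise fold ratios.
* **`granulosig.counts`** — precursor blood-count comparison (fold of
  group means + Mann–Whitney), a probability-mass two-sided Fisher exact
  test for clinical 2×2 tables, and PCA (centering + unit-variance
  scaling, SVD, optional zero-fill of missing bead-array values).
* **`granulosig.simulate`** — a synthetic-cohort generator encoding the
  cell-mixture mechanism: per sample, a stage composition π ~
  Dirichlet(α_group); expression x = (Profiles · π) · planted effects ·
  e^ε with ε ~ N(0, σ²); blood counts = round(total · π) from the *same*
  π, coupling signatures and counts; a bead-array observation layer with
  gain, duplicate CV and a background floor.

## Worked example

```python
from granulosig.simulate import study_config, simulate_cohort, program_gene_sets
from granulosig.signatures import summarize_compartment, global_compartment_expression

cohort = simulate_cohort(study_config(n_genes=4000, seed=0))
sets = program_gene_sets(cohort.truth.profiles, ["AG", "SG", "GG", "FG", "SV", "CM"])
summ = summarize_compartment(cohort.expr, cohort.samples, sets)
print(global_compartment_expression(summ).round(2))
```

prints

```
             n_genes  global_presurgical  global_SIRS  global_sepsis  fold_sepsis_vs_SIRS  fold_SIRS_vs_presurgical
compartment
AG                30              131.20       132.70         220.83                 1.66                      1.01
SG                30              258.46       300.91         811.74                 2.70                      1.16
GG                12              329.87       512.31        2433.21                 4.75                      1.55
FG                15            19104.93     20471.89       19847.20                 0.97                      1.07
SV                20            16749.82     16783.60       16206.32                 0.97                      1.00
CM                30            16126.49     15971.60       15901.01                 1.00                      0.99
```

Azurophilic (AG) granule genes are elevated in sepsis only (1.66× vs
SIRS, flat SIRS vs presurgical), specific (SG) granule genes rise
stepwise across the groups, and the late compartments barely move —
exactly the pattern an expanded immature compartment produces. The
matching blood counts from the same cohort show ~7–25× higher precursor
counts in sepsis with a non-significant ~20% PMN difference
(`examples/07_precursor_counts.py`).

The `examples/` directory holds one short script per capability
(simulation, differential expression, enrichment, selection, bead-array
validation, signatures, counts); each prints the numbers it computes
and a line on what they mean.

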