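# Methods

## The model behind the pipeline

The package treats a bulk CD15⁺ transcriptome as a composition-weighted
mixture over the five stages of terminal granulocytic differentiation.
For sample *j* with stage composition πⱼ (a 5-simplex point over LPM,
MY, MM, BC, PMN) and a gene × stage profile matrix **P**,

    E[x·ⱼ] = P πⱼ ,    xᵢⱼ = (P πⱼ)ᵢ · eᵢⱼ · exp(εᵢⱼ),  ε ~ N(0, σ²)

where eᵢⱼ is an optional planted group-specific multiplicative effect.
Blood counts of the five stages are `round(Tⱼ · πⱼ)` with Tⱼ a
log-normal total CD15 count — counts and expression share one latent
composition, so the claim "granule-signature shifts reflect precursor
expansion" is a *construction* of the generator and a *recoverable
property* for the analysis side. The analysis modules never see π; they
must recover its consequences from the observed matrices.

## Statistical procedures

**Differential expression.** Log₂ is applied internally (inputs stay on
the linear scale because fold changes are linear ratios). Per gene: a
one-way fixed-effects ANOVA F p-value across the three groups, and per
contrast a pooled-variance two-sample t-test. FDR control is
Benjamini–Hochberg step-up, applied per contrast across all genes (the
source analysis names only "FDR correction"; BH is the standard choice
and recorded here as ours). Degenerate genes: all values identical →
p = 1 by convention; non-identical groups with zero within-group
variance → a log₂-scale variance floor of 1e-8 keeps statistics finite.
Whether per-contrast significance should derive from the global F or
from per-contrast tests is not specified by the source; per-contrast
BH-adjusted t tests are our design decision.

**Enrichment.** The weighted KS running-sum statistic with weight
|t|¹; with this convention a single member at the very top of the list
attains ES = 1 (the running sum is evaluated after each gene). The null
re-permutes *sample labels* (preserving inter-gene correlation) and
recomputes the ranking per permutation; gene-label permutation is
available for tiny cohorts. NES divides ES by the mean |null ES| of
matching sign; FDR-q follows the pooled two-sided null convention.
Default 200 permutations; the acceptance script uses 100 (resolution
0.01 on permutation p, sufficient for sign/threshold calls made there).

**Candidate selection.** Strategy 1 joins two top-100 lists (DEGs of
the sepsis-vs-SIRS contrast ranked by mean linear expression in sepsis
and in SIRS respectively — "mean expression" read on the linear scale),
ranks the union by ascending FDR-q and keeps the top 50; an explicit
exclusion list removes genes *without replacement* (modelling assay
dropouts; no promotion of the next-ranked gene). Range-rule additions
come from the same joined pool (not all DEGs — "this list" is read as
the pool): the rule passes iff min(high) > Q75(low) **and**
max(low) < Q25(high), with type-7 (linear-interpolation) quantiles and
strict inequalities, so boundary ties conservatively fail. Strategy 2
gates on linear fold changes (>2.0 sepsis/SIRS, <1.1 SIRS/presurgical)
among DEGs of any contrast. Strategy 3 intersects the strategy-1 pool
with a lysosomal gene catalogue.

**Bead-array validation.** Duplicates are averaged first; an entry is
missing iff its duplicate mean is at or below the per-plate background
constant (masking happens on raw duplicate means, before reference
normalization). Missingness reduces n rather than imputing background —
the conservative choice, since absence concentrates in the
lower-expressing group. "Confirmed" needs ≥4 above-background samples
per group. The Mann–Whitney U test is exact by full enumeration of the
pooled-midrank permutation null (valid under ties) when min(n,m) ≤ 8
and n+m ≤ 20, otherwise normal approximation with tie and continuity
corrections. Bonferroni universes are the *confirmed* genes within each
strategy list and all confirmed selected genes together; a gene is
validated when any adjusted p < 0.05 — a smaller strategy list can
therefore validate a gene the global adjustment misses.

**Counts and PCA.** Count comparisons use fold ratios of arithmetic
group means plus two-sided Mann–Whitney p-values, uncorrected across
the five populations (matching the source analysis). The 2×2 Fisher
test is two-sided by the probability-mass rule (sum of hypergeometric
probabilities ≤ that of the observed table). PCA centers and
unit-variance-scales features of the *untransformed* data and uses SVD;
missing bead-array values can be zero-filled (nominal background)
before scaling; constant features are dropped with a warning. An
unscaled (center-only) variant exists for methodological checks.

## Generator calibration (the study conditions)

`study_config()` fixes the synthetic study conditions; they were
calibrated once, against the source's printed count folds, and are not
tuning knobs:

| parameter | value | rationale |
|---|---|---|
| groups (presurgical/SIRS/sepsis) | 11 / 14 / 20 | discovery-control and count-cohort sizes |
| genes | 20,000 | whole-genome array scale |
| mean stage fractions, sepsis | 0.007 / 0.0115 / 0.019 / 0.095 / 0.8675 | left shift sized to give ~16.9× LPM, ~11× MY/BC, ~6.5× MM, ~23% PMN vs SIRS |
| mean stage fractions, SIRS | 6e-4 / 1.5e-3 / 4e-3 / 0.012 / 0.982 | mild trauma-induced shift |
| mean stage fractions, presurgical | 2e-4 / 5e-4 / 1.5e-3 / 5e-3 / 0.993 | near-normal blood |
| Dirichlet concentration | 2500 | order-of-magnitude patient scatter in rare stages without destabilising group means |
| total CD15 cells/µL | log-normal, means ≈ 4.5k / 7.5k / 10.4k, log-SD 0.4–0.6 | ICU-range neutrophil counts; ratio sized to the PMN target |
| peak/off profile ratio | 100 | granule genes are effectively off outside their stage window; 10× (the generic default of `build_stage_profiles`) cannot move bulk expression at realistic precursor fractions |
| baseline log-SD | 1.0 | genes span a realistic dynamic range |
| σ (tech/biol. noise, log scale) | 0.35 | microarray-like combined variability |
| planted effects | 60 genes, 2–8× in sepsis only | recoverable sepsis responders for the selection/validation chain |
| bead array | gain 5, background 30, background noise SD 5, duplicate CV 0.05 | produces the at-/below-background missingness the validation rule exists for |

Program gene counts (AG 30, SG 30, GG 12, FG 15, SV 20, CM 30, cell
cycle 120, mitochondrial 150, proteasome 45, ribosome 80, lysosome 150)
are plausible signature-list sizes; absolute expression units are
arbitrary (the source reports none), chosen only so planted effects are
recoverable.

**What the generator does and does not emulate.** It reproduces the
mixture mechanism, group-specific precursor expansion, log-normal
expression noise, bead-array duplicates with a background floor, and
count/expression coupling. It does **not** emulate probe-level array
artifacts, batch effects, activation states of mature neutrophils
(low-density granulocytes, MDSC), per-cell regulation within a stage,
or correlated gene modules beyond the stage programs. Passing recovery
tests therefore shows the *pipeline* is correct and well-calibrated
under the mixture mechanism — not that real cohorts satisfy that
mechanism.

## Numerical choices and degenerate inputs

* Expression must be finite and strictly positive; readers reject (and
  name) offending records rather than coercing.
* Gene identity is the case-sensitive symbol string; multi-row genes
  are treated as distinct rows (no probe collapsing, no alias maps).
* Ranking ties (equal t) break by gene id; all selection outputs are
  deterministic functions of their inputs.
* Exact-test switchovers: Mann–Whitney exact for min(n,m) ≤ 8 and
  n+m ≤ 20; Fisher p snaps to 1 when the whole support is included
  (guards pmf round-off).
* One `numpy` Generator per simulation, seeded from the config, drawing
  in a documented order (profiles → per-sample composition and total →
  expression noise → plate noise), so outputs are byte-identical per
  seed.

## Problem sizes used by the test and acceptance runs

The acceptance script runs the full cohort at 20,000 genes. The test
suite exercises recovery properties at reduced gene universes (700 for
count-only checks, where the gene dimension is irrelevant; 1,000–4,000
where expression matters) and 10-seed grids — sizes chosen to keep the
suite quick while leaving every assertion's expected effect an order of
magnitude above its Monte-Carlo error.

## Known limitations

* The enrichment NES/FDR conventions are the standard open ones; the
  commercial implementation the source used is unspecified, so absolute
  NES values are not comparable — only patterns and signs. The
  significance level for *calling* a pathway enriched is a knob
  (`alpha_fdr`, default 0.05); figure-style reporting sometimes marks a
  much looser FDR-q < 0.5, which callers can apply to the returned
  table themselves.
* The bead-array recovery experiment's "zero false validations"
  expectation is probabilistic: with 200 null tests at an adjusted
  threshold of 1.25e-3, occasional legitimate extreme null draws occur
  (observed rate 0.1% over 100 seeds, below the nominal 0.125%).
* Strategy 1's reading of "top 100 … each" (two lists, then joined) and
  the range rule's strict-inequality treatment of boundary ties are
  interpretations, recorded here as design decisions.
* Whether global compartment expression averages per-gene group means
  (implemented) or pools all sample values is ambiguous in the source
  description; the alternative is a one-line change via `statistic=`.
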