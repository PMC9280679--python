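"""Synthetic CD15+ cohort generator.

The generator encodes the cell-mixture mechanism the analysis pipeline
is designed to detect. Each sample's bulk expression is a
composition-weighted mixture of maturation-stage programs:

* every gene has an expected intensity per stage (LPM, MY, MM, BC, PMN);
  granule-program genes (AG, SG, GG, FG, SV, CM) peak at the stage
  window where the corresponding compartment is formed ("targeting by
  timing"), proliferation/metabolism programs (cell cycle,
  mitochondrial, proteasome, ribosome, lysosome) peak in the immature
  stages and decline at the metamyelocyte transition, and housekeeping
  genes are constant across stages;
* each sample draws a stage composition pi from a group-specific
  Dirichlet — the sepsis group's concentration is shifted toward
  LPM/MY, emulating emergency granulopoiesis;
* bulk expression is Profiles @ pi times multiplicative log-normal
  noise, optionally times planted group-specific effects;
* blood counts are the same pi scaled by a log-normal total CD15 count,
  coupling expression signatures and precursor counts through one
  latent composition;
* a bead-array observation layer adds gain, duplicate noise and a
  background floor.

All draws flow from a single seeded generator in a documented order
(stage profiles, then per sample in group order: composition, total
count; then the expression noise matrix; plate noise last), so outputs
are byte-identical across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from granulosig.io import ExpressionMatrix, GROUPS
from granulosig.qgp import QGPPlate

#: Maturation stages from most immature to mature.
STAGES = ("LPM", "MY", "MM", "BC", "PMN")

#: Stage window in which each labelled program peaks.
PROGRAM_PEAKS: dict[str, tuple[str, ...]] = {
    "AG": ("LPM",),
    "SG": ("MY", "MM"),
    "GG": ("MM", "BC"),
    "FG": ("BC", "PMN"),
    "SV": ("BC", "PMN"),
    "CM": ("BC", "PMN"),
    "cellcycle": ("LPM", "MY"),
    "mito": ("LPM", "MY"),
    "proteasome": ("LPM", "MY"),
    "ribosome": ("LPM", "MY"),
    "lysosome": ("LPM", "MY"),
}

_PREFIX = {
    "AG": "AG", "SG": "SG", "GG": "GG", "FG": "FG", "SV": "SV", "CM": "CM",
    "cellcycle": "CC", "mito": "MT", "proteasome": "PS", "ribosome": "RB",
    "lysosome": "LY", "housekeeping": "HK",
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    The dataclass defaults describe a small neutral cohort (equal
    compositions, no planted effects); :func:`study_config` returns
    the calibrated study conditions.
    """

    n_genes: int = 2000
    n_per_group: dict = field(
        default_factory=lambda: {"presurgical": 10, "SIRS": 10, "sepsis": 10}
    )
    dirichlet_alpha: dict = field(
        default_factory=lambda: {
            g: np.full(5, 20.0) for g in GROUPS
        }
    )
    #: per-program gene counts; the remainder is housekeeping
    program_sizes: dict = field(default_factory=dict)
    peak_ratio: float = 10.0
    baseline: float = 100.0
    baseline_log_sd: float = 0.0
    sigma_tech: float = 0.2
    total_count_logmean: dict = field(
        default_factory=lambda: {g: 8.9 for g in GROUPS}
    )
    total_count_logsd: dict = field(
        default_factory=lambda: {g: 0.5 for g in GROUPS}
    )
    qgp_gain: float = 5.0
    qgp_background: float = 30.0
    qgp_background_noise_sd: float = 5.0
    qgp_duplicate_cv: float = 0.05
    qgp_reference_gene: str | None = None
    #: (gene_id, group, multiplicative effect) applied to expected expression
    planted_genes: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            alpha = np.asarray(self.dirichlet_alpha[g], dtype=float)
            if alpha.shape != (5,) or (alpha <= 0).any():
                raise ValueError(
                    f"dirichlet_alpha[{g!r}] must be 5 positive values"
                )
            self.dirichlet_alpha[g] = alpha
        if self.sigma_tech < 0:
            raise ValueError("sigma_tech must be >= 0")
        for gene, group, effect in self.planted_genes:
            if group not in GROUPS:
                raise ValueError(f"planted gene {gene!r}: unknown group {group!r}")
            if effect <= 0:
                raise ValueError(f"planted gene {gene!r}: effect must be > 0")
        n_labelled = sum(self.program_sizes.values())
        if n_labelled > self.n_genes:
            raise ValueError(
                f"{n_labelled} labelled program genes exceed n_genes={self.n_genes}"
            )
        unknown = set(self.program_sizes) - set(PROGRAM_PEAKS)
        if unknown:
            raise ValueError(f"unknown program label(s): {sorted(unknown)}")


# Calibrated study conditions: mean stage fractions of the whole-blood
# CD15 compartment per group. The sepsis group shows the emergency-
# granulopoiesis left shift (expanded LPM/MY/MM/BC), SIRS a mild one,
# presurgical controls almost none.
STUDY_STAGE_FRACTIONS: dict[str, np.ndarray] = {
    "presurgical": np.array([2.0e-4, 5.0e-4, 1.5e-3, 5.0e-3, 0.9928]),
    "SIRS": np.array([6.0e-4, 1.5e-3, 4.0e-3, 1.2e-2, 0.9819]),
    "sepsis": np.array([7.0e-3, 1.15e-2, 1.9e-2, 9.5e-2, 0.8675]),
}

_STUDY_CONCENTRATION = 2500.0

# Total CD15 cells/uL: log-normal parameters per group (mean counts about
# 4.5e3 presurgical, 7.5e3 SIRS, 1.04e4 sepsis).
STUDY_TOTALS_LOGMEAN = {"presurgical": 8.2318, "SIRS": 8.7427, "sepsis": 9.0734}
STUDY_TOTALS_LOGSD = {"presurgical": 0.4, "SIRS": 0.6, "sepsis": 0.6}

STUDY_PROGRAM_SIZES = {
    "AG": 30, "SG": 30, "GG": 12, "FG": 15, "SV": 20, "CM": 30,
    "cellcycle": 120, "mito": 150, "proteasome": 45, "ribosome": 80,
    "lysosome": 150,
}


def study_config(
    n_genes: int = 20000,
    n_planted: int = 60,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Study conditions: three groups, ~20k genes, sepsis composition
    shifted toward LPM/MY, planted sepsis-specific effects.

    Planted genes are housekeeping genes given multiplicative effects
    2-8x in the sepsis group only (log-spaced, deterministic), emulating
    genes that respond to sepsis rather than SIRS.
    """
    planted = [
        (f"HK{i + 1:05d}", "sepsis", float(e))
        for i, e in enumerate(np.geomspace(2.0, 8.0, n_planted))
    ]
    cfg = CohortConfig(
        n_genes=n_genes,
        n_per_group={"presurgical": 11, "SIRS": 14, "sepsis": 20},
        dirichlet_alpha={
            g: _STUDY_CONCENTRATION * STUDY_STAGE_FRACTIONS[g] for g in GROUPS
        },
        program_sizes=dict(STUDY_PROGRAM_SIZES),
        peak_ratio=100.0,
        baseline=100.0,
        baseline_log_sd=1.0,
        sigma_tech=0.35,
        total_count_logmean=dict(STUDY_TOTALS_LOGMEAN),
        total_count_logsd=dict(STUDY_TOTALS_LOGSD),
        planted_genes=planted,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class StageProfileMatrix:
    """Expected per-stage intensity per gene, with program labels."""

    profiles: pd.DataFrame  # genes x stages
    program_labels: pd.Series  # gene -> program label ("housekeeping" if none)

    @property
    def genes_of(self) -> dict[str, list[str]]:
        return {
            label: self.program_labels.index[self.program_labels == label].tolist()
            for label in self.program_labels.unique()
        }


def build_stage_profiles(config: CohortConfig) -> StageProfileMatrix:
    """Assign every gene a per-stage expected intensity.

    Labelled genes peak (baseline x ``peak_ratio``) in their program's
    stage window and sit at baseline elsewhere; housekeeping genes are
    constant. Per-gene baselines are log-normal around ``baseline`` with
    log-SD ``baseline_log_sd`` (0 makes them all equal). Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    names: list[str] = []
    labels: list[str] = []
    for program in PROGRAM_PEAKS:  # fixed insertion order
        k = config.program_sizes.get(program, 0)
        names += [f"{_PREFIX[program]}{i + 1:03d}" for i in range(k)]
        labels += [program] * k
    n_hk = config.n_genes - len(names)
    names += [f"HK{i + 1:05d}" for i in range(n_hk)]
    labels += ["housekeeping"] * n_hk

    baselines = config.baseline * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=config.n_genes)
    )
    profiles = np.tile(baselines[:, None], (1, len(STAGES)))
    stage_index = {s: i for i, s in enumerate(STAGES)}
    for row, label in enumerate(labels):
        if label == "housekeeping":
            continue
        for stage in PROGRAM_PEAKS[label]:
            profiles[row, stage_index[stage]] = baselines[row] * config.peak_ratio
    return StageProfileMatrix(
        profiles=pd.DataFrame(profiles, index=names, columns=list(STAGES)),
        program_labels=pd.Series(labels, index=names, name="program"),
    )


def program_gene_sets(
    stage_profiles: StageProfileMatrix, labels: list[str] | None = None
) -> "GeneSetCollection":
    """Bundle the generator's program labels into a gene-set collection
    (e.g. the six granule compartments for signature scoring, or the
    early-stage programs for enrichment)."""
    from granulosig.io import GeneSet, GeneSetCollection

    wanted = labels or [l for l in PROGRAM_PEAKS]
    coll = GeneSetCollection()
    by_label = stage_profiles.genes_of
    for label in wanted:
        members = by_label.get(label, [])
        if members:
            coll.add(GeneSet(label, class_label=label, members=frozenset(members)))
    return coll


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    composition: pd.DataFrame  # samples x stages, rows sum to 1
    profiles: StageProfileMatrix
    planted_genes: list
    total_counts: pd.Series


@dataclass
class SimulatedCohort:
    expr: ExpressionMatrix
    samples: pd.Series
    counts: pd.DataFrame  # sample_id, group, LPM..PMN (cells/uL)
    plate: QGPPlate | None
    truth: CohortTruth


def simulate_cohort(
    config: CohortConfig, qgp_genes: list[str] | None = None
) -> SimulatedCohort:
    """Draw a full cohort: expression, sample table, blood counts,
    optional bead-array plate, and ground truth.

    ``qgp_genes`` selects the genes put on the plate; by default the
    planted genes (if any) plus the reference gene. Same config (and
    seed) gives byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    stage_profiles = build_stage_profiles(config)
    profile_values = stage_profiles.profiles.to_numpy()
    gene_ids = stage_profiles.profiles.index

    planted_by_group: dict[str, dict[str, float]] = {g: {} for g in GROUPS}
    for gene, group, effect in config.planted_genes:
        if gene not in stage_profiles.profiles.index:
            raise ValueError(f"planted gene {gene!r} not among simulated genes")
        planted_by_group[group][gene] = (
            planted_by_group[group].get(gene, 1.0) * effect
        )

    sample_ids: list[str] = []
    group_labels: list[str] = []
    compositions: list[np.ndarray] = []
    totals: list[float] = []
    expected_cols: list[np.ndarray] = []
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for group in GROUPS:
        alpha = config.dirichlet_alpha[group]
        for j in range(int(config.n_per_group.get(group, 0))):
            sample_ids.append(f"{group[:3]}_{j + 1:02d}")
            group_labels.append(group)
            pi = rng.dirichlet(alpha)
            compositions.append(pi)
            totals.append(
                float(
                    rng.lognormal(
                        config.total_count_logmean[group],
                        config.total_count_logsd[group],
                    )
                )
            )
            mu = profile_values @ pi
            if planted_by_group[group]:
                mu = mu.copy()
                for gene, effect in planted_by_group[group].items():
                    mu[gene_pos[gene]] *= effect
            expected_cols.append(mu)

    expected = np.column_stack(expected_cols)
    noise = rng.normal(0.0, config.sigma_tech, size=expected.shape)
    observed = expected * np.exp(noise)

    expr = ExpressionMatrix(
        pd.DataFrame(observed, index=gene_ids, columns=sample_ids)
    )
    samples = pd.Series(group_labels, index=sample_ids, name="group")

    comp = np.vstack(compositions)
    counts = pd.DataFrame(
        np.rint(comp * np.asarray(totals)[:, None]),
        index=sample_ids,
        columns=list(STAGES),
    )
    counts.insert(0, "group", group_labels)
    counts.index.name = "sample_id"

    truth = CohortTruth(
        composition=pd.DataFrame(comp, index=sample_ids, columns=list(STAGES)),
        profiles=stage_profiles,
        planted_genes=list(config.planted_genes),
        total_counts=pd.Series(totals, index=sample_ids, name="total_cd15"),
    )

    reference = config.qgp_reference_gene
    if reference is None:
        hk = stage_profiles.program_labels.index[
            stage_profiles.program_labels == "housekeeping"
        ]
        unplanted = [g for g in hk if all(g not in planted_by_group[gr] for gr in GROUPS)]
        if unplanted:
            # highest-baseline unplanted housekeeping gene: reliably above
            # the plate background in every sample
            base = stage_profiles.profiles.loc[unplanted, STAGES[0]]
            reference = str(base.idxmax())
        else:
            reference = None

    plate = None
    if reference is not None:
        if qgp_genes is None:
            qgp_genes = sorted({g for g, _, _ in config.planted_genes})
        assay = [g for g in qgp_genes if g != reference] + [reference]
        if assay:
            plate = simulate_qgp(
                expr.subset_genes(assay),
                config,
                rng=rng,
                reference_gene=reference,
            )
    return SimulatedCohort(
        expr=expr, samples=samples, counts=counts, plate=plate, truth=truth
    )


def simulate_qgp(
    expr: ExpressionMatrix,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    reference_gene: str | None = None,
) -> QGPPlate:
    """Bead-array observation layer on an expression matrix.

    Each duplicate signal is ``gain * x * (1 + cv * z) + e`` with
    ``z, e`` standard-normal draws (``e`` scaled by the background noise
    SD), floored at the plate background. The reference gene must be one
    of the matrix's genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reference = reference_gene or config.qgp_reference_gene
    if reference is None:
        raise ValueError("a reference gene is required to build a plate")
    if reference not in expr.data.index:
        raise ValueError(f"reference gene {reference!r} not in expression subset")
    x = expr.data.to_numpy()
    n_genes, n_samples = x.shape
    records = []
    for r in range(2):
        z = rng.normal(0.0, 1.0, size=x.shape)
        e = rng.normal(0.0, config.qgp_background_noise_sd, size=x.shape)
        y = config.qgp_gain * x * (1.0 + config.qgp_duplicate_cv * z) + e
        records.append(np.maximum(y, config.qgp_background))
    rep1, rep2 = records
    long = pd.DataFrame(
        {
            "gene": np.repeat(expr.gene_ids, n_samples),
            "sample": np.tile(expr.sample_ids, n_genes),
            "rep1": rep1.ravel(),
            "rep2": rep2.ravel(),
        }
    )
    return QGPPlate(
        data=long, background=config.qgp_background, reference_gene=reference
    )
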