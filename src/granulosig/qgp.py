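"""Bead-array (QuantiGene-Plex-style) processing and validation statistics.

Raw plates carry technical duplicate fluorescence signals per gene and
sample, a plate background value and a reference gene. Duplicates are
averaged; entries whose duplicate mean is at or below the plate
background are treated as MISSING (not as zero), which conservatively
reduces the sample size for the group with the lower expression. Values
are normalized to the reference gene's duplicate mean per sample.

A gene counts as "expression confirmed" in a patient group when at
least ``confirm_min_n`` samples of that group are above background.
Genes confirmed in both compared groups are tested with the two-sided
Mann-Whitney U test; Bonferroni adjustment is applied within each
selection strategy's confirmed list and globally across all confirmed
selected genes, and a gene is validated when any adjusted p-value falls
below ``alpha_validation``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from granulosig.config import AnalysisConfig
from granulosig.io import FormatError
from granulosig.selection import SelectionTable
from granulosig.stats import mann_whitney_exact

logger = logging.getLogger(__name__)


@dataclass
class QGPPlate:
    """Raw duplicate signals: DataFrame with columns ``gene``, ``sample``,
    ``rep1``, ``rep2``; a plate background value; a reference gene id."""

    data: pd.DataFrame
    background: float
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "rep1", "rep2"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"plate table needs columns {sorted(required)}")
        if self.background <= 0:
            raise FormatError("plate background must be > 0")
        if (self.data[["rep1", "rep2"]].to_numpy(dtype=float) < 0).any():
            raise FormatError("negative raw signals in plate")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        missing = samples - ref_samples
        if missing:
            raise FormatError(
                f"reference gene {self.reference_gene!r} missing for "
                f"samples {sorted(missing)[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.data["sample"]))


def read_qgp_plate(path, background: float, reference_gene: str) -> QGPPlate:
    """Read a plate TSV (gene, sample, rep1, rep2)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    return QGPPlate(df, background=background, reference_gene=reference_gene)


def write_qgp_plate(plate: QGPPlate, path) -> None:
    plate.data.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedQGP:
    """Reference-normalized signals (genes x samples); NaN marks values
    whose duplicate mean was at or below background."""

    values: pd.DataFrame
    missing_reason: pd.DataFrame  # "" or "at_or_below_background"


def normalize_qgp(plate: QGPPlate) -> NormalizedQGP:
    """Average duplicates, mask at-or-below-background entries as
    missing, and divide by the reference gene's duplicate mean."""
    df = plate.data.copy()
    df["mean"] = df[["rep1", "rep2"]].astype(float).mean(axis=1)
    wide = df.pivot_table(index="gene", columns="sample", values="mean", aggfunc="first")
    ref = wide.loc[plate.reference_gene]
    bad = ref[ref <= plate.background]
    if not bad.empty:
        raise FormatError(
            f"reference gene {plate.reference_gene!r} at or below background "
            f"in sample(s) {bad.index.tolist()[:5]}"
        )
    assay = wide.drop(index=plate.reference_gene)
    missing = assay <= plate.background
    values = assay.where(~missing) / ref
    reason = pd.DataFrame(
        np.where(missing, "at_or_below_background", ""),
        index=assay.index,
        columns=assay.columns,
    )
    return NormalizedQGP(values=values, missing_reason=reason)


def confirm_expression(
    norm: NormalizedQGP, samples: pd.Series, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-gene, per-group flag: >= ``confirm_min_n`` above-background samples."""
    config = config or AnalysisConfig()
    groups = sorted(samples.unique())
    out = {}
    for g in groups:
        ids = [s for s in norm.values.columns if samples.get(s) == g]
        present = norm.values[ids].notna().sum(axis=1) if ids else 0
        out[g] = present >= config.confirm_min_n if ids else pd.Series(
            False, index=norm.values.index
        )
    return pd.DataFrame(out)


def validate_degs(
    norm: NormalizedQGP,
    samples: pd.Series,
    selection: SelectionTable,
    config: AnalysisConfig | None = None,
    groups: tuple[str, str] = ("sepsis", "SIRS"),
) -> pd.DataFrame:
    """Run the confirmation + Mann-Whitney + Bonferroni validation scheme.

    Returns a DataFrame indexed by selected gene with confirmation flags,
    per-group n used, linear fold change of group means, raw Mann-Whitney
    p, per-strategy and global Bonferroni-adjusted p-values, and the
    final ``validated`` flag.
    """
    config = config or AnalysisConfig()
    g_hi, g_lo = groups
    confirmed = confirm_expression(norm, samples, config)

    rows = []
    for gene in selection.union:
        row = {
            "gene_id": gene,
            "on_plate": gene in norm.values.index,
            f"confirmed_{g_hi}": False,
            f"confirmed_{g_lo}": False,
        }
        if not row["on_plate"]:
            logger.warning("selected gene %r absent from plate; unconfirmed", gene)
            rows.append(row)
            continue
        row[f"confirmed_{g_hi}"] = bool(confirmed.loc[gene].get(g_hi, False))
        row[f"confirmed_{g_lo}"] = bool(confirmed.loc[gene].get(g_lo, False))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    table["confirmed_both"] = table[f"confirmed_{g_hi}"] & table[f"confirmed_{g_lo}"]

    # Bonferroni universes: genes selected by a strategy AND confirmed in
    # both groups; plus all confirmed selected genes together.
    strat_members = {
        k: set(selection.genes_by_strategy(k)) for k in (1, 2, 3)
    }
    confirmed_genes = set(table.index[table["confirmed_both"]])
    m_strategy = {
        k: len(strat_members[k] & confirmed_genes) for k in (1, 2, 3)
    }
    m_global = len(confirmed_genes)

    ids_hi = [s for s in norm.values.columns if samples.get(s) == g_hi]
    ids_lo = [s for s in norm.values.columns if samples.get(s) == g_lo]

    for col in ("n_" + g_hi, "n_" + g_lo):
        table[col] = 0
    table["fold"] = np.nan
    table["mwu_p"] = np.nan
    for k in (1, 2, 3):
        table[f"p_bonf_strategy{k}"] = np.nan
    table["p_bonf_global"] = np.nan
    table["validated"] = False

    for gene in table.index[table["confirmed_both"]]:
        a = norm.values.loc[gene, ids_hi].dropna().to_numpy(dtype=float)
        b = norm.values.loc[gene, ids_lo].dropna().to_numpy(dtype=float)
        _, p = mann_whitney_exact(a, b)
        table.loc[gene, "n_" + g_hi] = a.size
        table.loc[gene, "n_" + g_lo] = b.size
        table.loc[gene, "fold"] = a.mean() / b.mean()
        table.loc[gene, "mwu_p"] = p
        adjusted = []
        for k in (1, 2, 3):
            if gene in strat_members[k] and m_strategy[k] > 0:
                p_adj = min(1.0, m_strategy[k] * p)
                table.loc[gene, f"p_bonf_strategy{k}"] = p_adj
                adjusted.append(p_adj)
        p_glob = min(1.0, m_global * p)
        table.loc[gene, "p_bonf_global"] = p_glob
        adjusted.append(p_glob)
        table.loc[gene, "validated"] = any(
            p_adj < config.alpha_validation for p_adj in adjusted
        )
    return table
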