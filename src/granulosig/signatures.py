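"""Granule-compartment signature scoring.

Neutrophil granule proteins are sorted by "targeting by timing":
azurophilic (AG) granule genes are transcribed at the promyelocyte
stage, specific (SG) granule genes at the myelocyte/metamyelocyte
stages, and gelatinase (GG), ficolin (FG), secretory-vesicle (SV) and
cell-membrane (CM) programs later. Bulk CD15+ expression of each
compartment's signature therefore tracks the abundance of the
corresponding maturation stages, making compartment summaries a proxy
for emergency granulopoiesis.

The module computes, per compartment: per-gene group means, pairwise
mean differences (heat-map panels, optionally restricted to DEGs), and
the global compartment expression level — the unweighted mean over
signature genes of the per-gene group means — with fold ratios between
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from granulosig.io import (
    ExpressionMatrix,
    GeneSetCollection,
    GROUPS,
    check_samples_match,
)

logger = logging.getLogger(__name__)

#: Canonical compartment order: azurophilic, specific, gelatinase,
#: ficolin, secretory vesicles, cell membrane.
COMPARTMENTS = ("AG", "SG", "GG", "FG", "SV", "CM")

_PAIRS = (
    ("sepsis", "presurgical"),
    ("SIRS", "presurgical"),
    ("sepsis", "SIRS"),
)


@dataclass
class CompartmentSummary:
    name: str
    n_total: int  # full signature size (in the collection)
    n_in_universe: int
    n_deg: int | None  # DEG-restricted count, when a DGE filter was given
    gene_means: pd.DataFrame  # genes x groups (full signature in universe)
    gene_diffs: pd.DataFrame  # genes x pairwise mean differences
    heatmap_genes: list[str]  # DEG-restricted when filter given
    global_means: pd.Series  # per-group scalar
    fold_matrix: pd.DataFrame  # groups x groups ratio of global means

    @property
    def absent(self) -> bool:
        return self.n_in_universe == 0


@dataclass
class SignatureSummary:
    compartments: dict[str, CompartmentSummary] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CompartmentSummary:
        return self.compartments[name]

    def __iter__(self):
        return iter(self.compartments.values())


def summarize_compartment(
    expr: ExpressionMatrix,
    samples: pd.Series,
    sigs: GeneSetCollection,
    deg_filter: pd.DataFrame | None = None,
    statistic: str = "mean",
) -> SignatureSummary:
    """Score every compartment signature against the expression matrix.

    ``deg_filter`` (a DGE table) restricts the heat-map gene lists to
    genes flagged DEG in at least one contrast, while global summaries
    always use the complete signature sets found in the universe.
    ``statistic`` selects the per-gene group summary ("mean" or
    "median").
    """
    aligned = check_samples_match(expr, samples)
    masks = {g: (aligned == g).to_numpy() for g in GROUPS}
    values = expr.data

    deg_genes: set[str] | None = None
    if deg_filter is not None:
        deg_cols = [c for c in deg_filter.columns if c.endswith("_deg")]
        deg_genes = set(deg_filter.index[deg_filter[deg_cols].any(axis=1)])

    summary = SignatureSummary()
    for name in sigs.names:
        gs = sigs[name]
        in_universe = sorted(gs.members & set(values.index))
        if not in_universe:
            logger.warning("compartment %r has no genes in the universe", name)
            summary.compartments[name] = CompartmentSummary(
                name=name,
                n_total=len(gs),
                n_in_universe=0,
                n_deg=None if deg_genes is None else 0,
                gene_means=pd.DataFrame(columns=list(GROUPS)),
                gene_diffs=pd.DataFrame(),
                heatmap_genes=[],
                global_means=pd.Series(np.nan, index=list(GROUPS)),
                fold_matrix=pd.DataFrame(
                    np.nan, index=list(GROUPS), columns=list(GROUPS)
                ),
            )
            continue
        sub = values.loc[in_universe]
        if statistic == "mean":
            means = pd.DataFrame(
                {g: sub.loc[:, masks[g]].mean(axis=1) for g in GROUPS}
            )
        elif statistic == "median":
            means = pd.DataFrame(
                {g: sub.loc[:, masks[g]].median(axis=1) for g in GROUPS}
            )
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        diffs = pd.DataFrame(
            {f"{a}_minus_{b}": means[a] - means[b] for a, b in _PAIRS}
        )
        heat = (
            [g for g in in_universe if g in deg_genes]
            if deg_genes is not None
            else list(in_universe)
        )
        global_means = means.mean(axis=0)
        fold = pd.DataFrame(
            np.outer(global_means, 1.0 / global_means),
            index=list(GROUPS),
            columns=list(GROUPS),
        )
        summary.compartments[name] = CompartmentSummary(
            name=name,
            n_total=len(gs),
            n_in_universe=len(in_universe),
            n_deg=None if deg_genes is None else len(heat),
            gene_means=means,
            gene_diffs=diffs,
            heatmap_genes=heat,
            global_means=global_means,
            fold_matrix=fold,
        )
    return summary


def global_compartment_expression(summary: SignatureSummary) -> pd.DataFrame:
    """Tabulate global per-group compartment expression with the three
    pairwise fold ratios."""
    rows = []
    for comp in summary:
        row = {"compartment": comp.name, "n_genes": comp.n_in_universe}
        for g in GROUPS:
            row[f"global_{g}"] = comp.global_means.get(g, np.nan)
        for a, b in _PAIRS:
            row[f"fold_{a}_vs_{b}"] = (
                comp.fold_matrix.loc[a, b] if not comp.absent else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("compartment")
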