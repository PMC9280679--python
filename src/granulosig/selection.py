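"""Shortlisting of differentially expressed genes for bead-array validation.

Three complementary strategies target genes that change in sepsis rather
than SIRS:

1. From the sepsis-vs-SIRS DEGs, the top ``strategy1_pool_size`` genes
   by mean expression in sepsis and the top ``strategy1_pool_size`` by
   mean expression in SIRS are joined, ranked by ascending FDR-q, and
   the top ``strategy1_top_k`` taken (minus an explicit exclusion list,
   without replacement). Pool genes whose sepsis/SIRS signal ranges are
   separated by the opposing group's quartile (the range-percentile
   rule) are added.
2. Genes with a >``strategy2_fc_high``-fold sepsis-vs-SIRS mean
   difference and concomitantly a <``strategy2_fc_low``-fold
   SIRS-vs-presurgical difference.
3. Members of a lysosomal gene catalogue found in strategy 1's joined
   high-expression pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from granulosig.config import AnalysisConfig
from granulosig.io import ExpressionMatrix, GeneSetCollection, check_samples_match


def range_percentile_rule(high_values, low_values) -> bool:
    """True when two expression ranges are quartile-separated.

    ``high_values`` is the sample vector of the group with the larger
    mean. The rule holds iff the high group's range lies strictly above
    the low group's 75th percentile AND the low group's range lies
    strictly below the high group's 25th percentile. Quantiles use
    linear interpolation; boundary ties fail the rule (conservative).
    """
    high = np.asarray(high_values, dtype=float)
    low = np.asarray(low_values, dtype=float)
    if high.size < 3 or low.size < 3:
        raise ValueError("range_percentile_rule requires >= 3 values per group")
    return bool(
        high.min() > np.quantile(low, 0.75) and low.max() < np.quantile(high, 0.25)
    )


def strategy1_pool(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Joined high-expression pool feeding strategies 1 and 3.

    Union of the top ``strategy1_pool_size`` sepsis-vs-SIRS DEGs by mean
    linear expression in sepsis with the same by mean expression in SIRS.
    """
    config = config or AnalysisConfig()
    degs = table[table["sepsis_vs_SIRS_deg"]]
    pool: set[str] = set()
    for group in ("sepsis", "SIRS"):
        top = degs.sort_values(
            [f"mean_{group}"], ascending=False, kind="mergesort"
        ).head(config.strategy1_pool_size)
        pool |= set(top.index)
    return sorted(pool)


def select_strategy1(
    table: pd.DataFrame,
    expr: ExpressionMatrix,
    samples: pd.Series,
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Strategy 1: top-q genes from the joined high-expression pool plus
    range-rule additions. Returns genes in selection order."""
    config = config or AnalysisConfig()
    pool = strategy1_pool(table, config)
    if not pool:
        return []
    ranked = (
        table.loc[pool]
        .sort_values(["sepsis_vs_SIRS_q", "sepsis_vs_SIRS_p"], kind="mergesort")
        .index.tolist()
    )
    top = ranked[: config.strategy1_top_k]
    selected = [g for g in top if g not in set(config.exclusion_list)]

    aligned = check_samples_match(expr, samples)
    sep = (aligned == "sepsis").to_numpy()
    sirs = (aligned == "SIRS").to_numpy()
    taken = set(selected)
    for gene in ranked:
        if gene in taken or gene in set(config.exclusion_list):
            continue
        x = expr.data.loc[gene].to_numpy(dtype=float)
        a, b = x[sep], x[sirs]
        high, low = (a, b) if a.mean() >= b.mean() else (b, a)
        if range_percentile_rule(high, low):
            selected.append(gene)
            taken.add(gene)
    return selected


def select_strategy2(
    table: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[str]:
    """Strategy 2: large sepsis-vs-SIRS fold with near-flat
    SIRS-vs-presurgical fold, among DEGs of any contrast."""
    config = config or AnalysisConfig()
    deg_any = (
        table["sepsis_vs_presurgical_deg"]
        | table["SIRS_vs_presurgical_deg"]
        | table["sepsis_vs_SIRS_deg"]
    )
    hit = (
        deg_any
        & (table["sepsis_vs_SIRS_fold"] > config.strategy2_fc_high)
        & (table["SIRS_vs_presurgical_fold"] < config.strategy2_fc_low)
    )
    return table.index[hit].tolist()


def select_strategy3(
    pool: list[str],
    lysosome_set: GeneSetCollection,
    already_selected: list[str],
) -> tuple[list[str], list[str]]:
    """Strategy 3: lysosomal genes in the joined high-expression pool.

    Returns ``(selected, new)`` where ``new`` are the members not already
    covered by earlier strategies.
    """
    members: set[str] = set()
    for gs in lysosome_set:
        members |= gs.members
    if not members:
        raise ValueError("lysosome gene set is empty")
    selected = [g for g in pool if g in members]
    prior = set(already_selected)
    new = [g for g in selected if g not in prior]
    return selected, new


@dataclass
class SelectionTable:
    """Per-gene strategy flags with provenance for the merged shortlist."""

    table: pd.DataFrame

    @property
    def union(self) -> list[str]:
        return self.table.index.tolist()

    def genes_by_strategy(self, strategy: int) -> list[str]:
        return self.table.index[self.table[f"strategy{strategy}"]].tolist()


def merge_selection(s1: list[str], s2: list[str], s3: list[str]) -> SelectionTable:
    """Merge the three strategy lists into a nonredundant shortlist with
    per-strategy membership flags."""
    order: list[str] = []
    for lst in (s1, s2, s3):
        for g in lst:
            if g not in order:
                order.append(g)
    df = pd.DataFrame(
        {
            "strategy1": [g in set(s1) for g in order],
            "strategy2": [g in set(s2) for g in order],
            "strategy3": [g in set(s3) for g in order],
        },
        index=pd.Index(order, name="gene_id"),
    )
    return SelectionTable(df)
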