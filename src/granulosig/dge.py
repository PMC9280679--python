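"""Three-group differential expression with FDR control.

Expression values arrive on the linear scale and are log2-transformed
internally. Per gene, a one-way fixed-effects ANOVA across the three
patient groups yields a global F p-value, and each of the three pairwise
contrasts (sepsis vs. presurgical, SIRS vs. presurgical, sepsis vs.
SIRS) is tested with a pooled-variance two-sample t-test on the log2
values. Benjamini-Hochberg FDR adjustment is applied per contrast across
all genes; a gene is a DEG in a contrast when its adjusted q is at or
below ``alpha_fdr``. Fold changes are ratios of linear-scale group means,
reported as a magnitude >= 1 with a direction sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from granulosig.config import AnalysisConfig
from granulosig.io import ExpressionMatrix, GROUPS, check_samples_match

#: Pairwise contrasts in the order they are reported, as (numerator, denominator).
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("sepsis", "presurgical"),
    ("SIRS", "presurgical"),
    ("sepsis", "SIRS"),
)


def contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


CONTRAST_NAMES = tuple(contrast_name(c) for c in CONTRASTS)

# log2-scale variance floor for genes whose within-group variance is zero
# while group means differ; keeps the F and t statistics finite.
_VAR_FLOOR = 1e-8


def _group_arrays(expr: ExpressionMatrix, samples: pd.Series):
    aligned = check_samples_match(expr, samples)
    present = [g for g in GROUPS if (aligned == g).any()]
    if set(present) != set(GROUPS):
        missing = sorted(set(GROUPS) - set(present))
        raise ValueError(f"missing patient group(s): {missing}")
    values = expr.data.to_numpy(dtype=float)
    masks = {g: (aligned == g).to_numpy() for g in GROUPS}
    return values, masks


def fit_dge(
    expr: ExpressionMatrix, samples: pd.Series, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Fit the three-group differential expression model.

    Returns a DataFrame indexed by gene id with linear-scale group means,
    the ANOVA F p-value and, per contrast, the fold change magnitude,
    direction sign, raw p, BH-adjusted q and DEG flag.
    """
    config = config or AnalysisConfig()
    values, masks = _group_arrays(expr, samples)
    logx = np.log2(values)

    n = {g: int(m.sum()) for g, m in masks.items()}
    lin_mean = {g: values[:, m].mean(axis=1) for g, m in masks.items()}
    log_mean = {g: logx[:, m].mean(axis=1) for g, m in masks.items()}
    log_var = {g: logx[:, m].var(axis=1, ddof=1) for g, m in masks.items()}

    total_n = sum(n.values())
    grand = sum(n[g] * log_mean[g] for g in GROUPS) / total_n
    ssb = sum(n[g] * (log_mean[g] - grand) ** 2 for g in GROUPS)
    ssw = sum((n[g] - 1) * log_var[g] for g in GROUPS)
    df1, df2 = len(GROUPS) - 1, total_n - len(GROUPS)
    msw = np.maximum(ssw / df2, _VAR_FLOOR)
    f_stat = (ssb / df1) / msw
    f_p = sps.f.sf(f_stat, df1, df2)

    # genes identical everywhere: no signal, p fixed at 1 by convention
    flat = np.ptp(logx, axis=1) == 0
    f_p[flat] = 1.0

    out = pd.DataFrame(index=expr.data.index)
    out.index.name = "gene_id"
    for g in GROUPS:
        out[f"mean_{g}"] = lin_mean[g]
    out["F_p"] = f_p

    for pair in CONTRASTS:
        name = contrast_name(pair)
        g1, g2 = pair
        pooled = (
            (n[g1] - 1) * log_var[g1] + (n[g2] - 1) * log_var[g2]
        ) / (n[g1] + n[g2] - 2)
        pooled = np.maximum(pooled, _VAR_FLOOR)
        se = np.sqrt(pooled * (1.0 / n[g1] + 1.0 / n[g2]))
        t = (log_mean[g1] - log_mean[g2]) / se
        p = 2.0 * sps.t.sf(np.abs(t), n[g1] + n[g2] - 2)
        same = log_mean[g1] == log_mean[g2]
        p[same] = 1.0
        ratio = lin_mean[g1] / lin_mean[g2]
        fold = np.maximum(ratio, 1.0 / ratio)
        direction = np.where(ratio >= 1.0, 1, -1)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        out[f"{name}_t"] = t
        out[f"{name}_fold"] = fold
        out[f"{name}_direction"] = direction
        out[f"{name}_p"] = p
        out[f"{name}_q"] = q
        out[f"{name}_deg"] = q <= config.alpha_fdr
    return out


@dataclass
class VennPartition:
    """Partition of DEGs by the subset of contrasts they are significant in.

    ``regions`` maps a frozenset of contrast names to the genes whose set
    of significant contrasts is exactly that subset. ``updown`` counts,
    per region and contrast, how many of the region's genes are up- or
    down-regulated in that contrast. Because a gene can be up in one
    contrast and down in another, the per-contrast tallies need not sum
    to the region size.
    """

    regions: dict[frozenset, list[str]]
    updown: pd.DataFrame

    @property
    def n_deg(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region(self, *contrasts: str) -> list[str]:
        return self.regions.get(frozenset(contrasts), [])


def venn_partition(
    table: pd.DataFrame, config: AnalysisConfig | None = None
) -> VennPartition:
    """Assign every DEG to the Venn region of its significant contrasts."""
    deg_cols = {c: table[f"{c}_deg"].to_numpy(bool) for c in CONTRAST_NAMES}
    any_deg = np.logical_or.reduce(list(deg_cols.values()))
    genes = table.index.to_numpy()
    regions: dict[frozenset, list[str]] = {}
    rows = []
    membership = np.vstack([deg_cols[c] for c in CONTRAST_NAMES]).T
    for key in map(
        frozenset,
        [
            (a,)
            for a in CONTRAST_NAMES
        ]
        + [
            (a, b)
            for i, a in enumerate(CONTRAST_NAMES)
            for b in CONTRAST_NAMES[i + 1 :]
        ]
        + [CONTRAST_NAMES],
    ):
        mask = any_deg.copy()
        for j, c in enumerate(CONTRAST_NAMES):
            if c in key:
                mask &= membership[:, j]
            else:
                mask &= ~membership[:, j]
        regions[key] = genes[mask].tolist()
        row = {"region": "&".join(sorted(key)), "n": int(mask.sum())}
        for c in key:
            up = int((table.loc[mask, f"{c}_direction"] > 0).sum())
            row[f"{c}_up"] = up
            row[f"{c}_down"] = int(mask.sum()) - up
        rows.append(row)
    updown = pd.DataFrame(rows).set_index("region")
    return VennPartition(regions=regions, updown=updown)


def deg_summary(table: pd.DataFrame) -> dict:
    """Headline DEG tallies: total fraction, per-contrast percentages of
    the DEG universe, and percentage unique to each contrast."""
    part = venn_partition(table)
    n_genes = len(table)
    n_deg = part.n_deg
    summary = {
        "n_genes": n_genes,
        "n_deg": n_deg,
        "deg_fraction_pct": 100.0 * n_deg / n_genes if n_genes else 0.0,
    }
    for c in CONTRAST_NAMES:
        n_c = int(table[f"{c}_deg"].sum())
        summary[f"{c}_pct_of_degs"] = 100.0 * n_c / n_deg if n_deg else 0.0
        n_unique = len(part.region(c))
        summary[f"{c}_unique_pct_of_degs"] = (
            100.0 * n_unique / n_deg if n_deg else 0.0
        )
    return summary
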