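"""Granulocyte-precursor blood-count comparison and PCA utilities.

Blood counts (cells/uL) of the five CD15+ maturation stages — late
promyelocytes (LPM), myelocytes (MY), metamyelocytes (MM), band cells
(BC) and mature polymorphonuclear neutrophils (PMN) — are compared
between sepsis and SIRS with fold ratios of group means and two-sided
Mann-Whitney tests. PCA follows the convention used for the count and
bead-array data: untransformed values, per-feature centering and unit
variance scaling, components by SVD; in the bead-array case missing
values may be zero-filled (nominal background) before scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from granulosig.io import FormatError
from granulosig.stats import fisher_exact_2x2, mann_whitney_exact  # noqa: F401

logger = logging.getLogger(__name__)

#: Maturation stages from most immature to mature.
STAGES = ("LPM", "MY", "MM", "BC", "PMN")


def read_cell_counts(path) -> pd.DataFrame:
    """Read a counts CSV with columns sample_id, group, LPM, MY, MM, BC, PMN."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", *STAGES}
    if not required.issubset(df.columns):
        raise FormatError(f"count table needs columns {sorted(required)}")
    counts = df[list(STAGES)].to_numpy(dtype=float)
    if (counts < 0).any():
        raise FormatError("negative cell counts")
    return df.set_index("sample_id")


def compare_counts(
    counts: pd.DataFrame, groups: tuple[str, str] = ("sepsis", "SIRS")
) -> pd.DataFrame:
    """Per-stage group means, fold ratio ``groups[0]/groups[1]`` and
    two-sided Mann-Whitney p-value."""
    g_hi, g_lo = groups
    hi = counts[counts["group"] == g_hi]
    lo = counts[counts["group"] == g_lo]
    if hi.empty or lo.empty:
        raise ValueError(f"both groups {groups} must be present in the count table")
    rows = []
    for stage in STAGES:
        a = hi[stage].to_numpy(dtype=float)
        b = lo[stage].to_numpy(dtype=float)
        u, p = mann_whitney_exact(a, b)
        rows.append(
            {
                "population": stage,
                f"mean_{g_hi}": a.mean(),
                f"mean_{g_lo}": b.mean(),
                "fold": a.mean() / b.mean() if b.mean() > 0 else np.inf,
                "mwu_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components
    dropped_features: list[str]


def run_pca(
    matrix: pd.DataFrame, missing_policy: str = "error", scale: bool = True
) -> PCAResult:
    """PCA of a samples-x-features table with centering and unit-variance
    scaling (the convention used for the count and bead-array data), via
    SVD. ``scale=False`` centers only.

    ``missing_policy="zero_fill"`` replaces missing values with 0 (the
    nominal background) before scaling; ``"error"`` rejects missing
    values. Constant features are dropped with a warning because their
    scale is undefined.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        if missing_policy == "zero_fill":
            x = np.where(np.isnan(x), 0.0, x)
        elif missing_policy == "error":
            rows, cols = np.argwhere(np.isnan(x))[0]
            raise ValueError(
                f"missing value at sample {matrix.index[rows]!r}, "
                f"feature {matrix.columns[cols]!r} (missing_policy='error')"
            )
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = matrix.columns[~keep].tolist()
    if dropped:
        logger.warning("dropping constant feature(s): %s", dropped[:10])
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant features")
    x = x[:, keep]
    z = x - x.mean(axis=0)
    if scale:
        z = z / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    var = s**2 / (z.shape[0] - 1)
    ratio = var / z.var(axis=0, ddof=1).sum()
    comp_names = [f"PC{i + 1}" for i in range(s.size)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(
            vt.T, index=matrix.columns[keep], columns=comp_names
        ),
        dropped_features=dropped,
    )


def pc1_group_separation(pca: PCAResult, groups: pd.Series) -> float:
    """Standardized distance between two group means on PC1: the absolute
    mean difference divided by the pooled within-group SD."""
    labels = groups.loc[pca.scores.index]
    uniq = labels.unique()
    if len(uniq) != 2:
        raise ValueError("separation is defined for exactly two groups")
    a = pca.scores.loc[labels == uniq[0], "PC1"].to_numpy()
    b = pca.scores.loc[labels == uniq[1], "PC1"].to_numpy()
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        return np.inf
    return float(abs(a.mean() - b.mean()) / pooled)
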