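"""Rank-based gene-set enrichment with a permutation null.

Genes are ranked by a signed two-group t statistic on log2 expression;
each gene set is scored with the weighted Kolmogorov-Smirnov running-sum
enrichment score (weight = |statistic|, exponent 1). The null
distribution comes from sample-label permutations by default (preserving
inter-gene correlation), with gene-label permutation available for tiny
cohorts. Normalized enrichment scores (NES) divide each ES by the mean
magnitude of same-sign null scores for that set, and FDR-q uses the
pooled positive/negative null convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from granulosig.config import AnalysisConfig
from granulosig.io import ExpressionMatrix, GeneSetCollection, check_samples_match

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


def _signed_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-group t per gene (rows), group1 minus group2."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    pooled = np.maximum(pooled, _VAR_FLOOR)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    t[m1 == m2] = 0.0
    return t


def rank_genes(
    expr: ExpressionMatrix, samples: pd.Series, contrast: tuple[str, str]
) -> pd.Series:
    """Rank genes by the signed t statistic for ``contrast[0]`` vs
    ``contrast[1]``, descending; ties broken by gene id."""
    aligned = check_samples_match(expr, samples)
    g1, g2 = contrast
    for g in contrast:
        if not (aligned == g).any():
            raise ValueError(f"group {g!r} absent from sample table")
    logx = np.log2(expr.data.to_numpy(dtype=float))
    t = _signed_t(logx[:, (aligned == g1).to_numpy()], logx[:, (aligned == g2).to_numpy()])
    order = np.lexsort((np.asarray(expr.gene_ids), -t))
    return pd.Series(t[order], index=np.asarray(expr.gene_ids)[order], name="stat")


def enrichment_score(stats: np.ndarray, member: np.ndarray) -> float:
    """Weighted KS running-sum ES for one set on one ranked list.

    ``stats`` are the ranking statistics in rank order (descending);
    ``member`` is the boolean membership vector in the same order.
    """
    stats = np.asarray(stats, dtype=float)
    member = np.asarray(member, dtype=bool)
    n = stats.size
    nh = int(member.sum())
    if nh == 0 or nh == n:
        return 0.0
    w = np.abs(stats) * member
    denom = w.sum()
    if denom == 0:  # all member stats are zero: spread hits uniformly
        w = member.astype(float)
        denom = float(nh)
    hit = np.cumsum(w) / denom
    miss = np.cumsum(~member) / (n - nh)
    dev = hit - miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def _es_many(stats_sorted: np.ndarray, member_sorted: np.ndarray) -> np.ndarray:
    """Vectorised ES over columns: inputs are (n_genes, n_cols)."""
    n, _ = stats_sorted.shape
    nh = member_sorted.sum(axis=0)
    w = np.abs(stats_sorted) * member_sorted
    denom = w.sum(axis=0)
    uniform = denom == 0
    if uniform.any():
        w[:, uniform] = member_sorted[:, uniform]
        denom = np.where(uniform, np.maximum(nh, 1), denom)
    hit = np.cumsum(w, axis=0) / denom
    miss = np.cumsum(~member_sorted, axis=0) / np.maximum(n - nh, 1)
    dev = hit - miss
    idx = np.abs(dev).argmax(axis=0)
    es = dev[idx, np.arange(dev.shape[1])]
    es[(nh == 0) | (nh == n)] = 0.0
    return es


def _null_es(
    expr: ExpressionMatrix,
    samples: pd.Series,
    contrast: tuple[str, str],
    memberships: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    gene_order: np.ndarray,
    block: int = 64,
) -> np.ndarray:
    """Sample-label permutation null: (n_sets, n_perm) array of ES."""
    aligned = check_samples_match(expr, samples)
    g1, g2 = contrast
    idx = np.flatnonzero((aligned == g1) | (aligned == g2))
    n1 = int((aligned == g1).sum())
    logx = np.log2(expr.data.to_numpy(dtype=float))[:, idx]
    out = np.empty((memberships.shape[0], n_perm))
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        for j in range(k):
            perm = rng.permutation(logx.shape[1])
            t = _signed_t(logx[:, perm[:n1]], logx[:, perm[n1:]])
            order = np.lexsort((gene_order, -t))
            s = t[order]
            for si in range(memberships.shape[0]):
                out[si, done + j] = enrichment_score(s, memberships[si, order])
        done += k
    return out


def _null_es_genes(
    stats_sorted: np.ndarray,
    set_sizes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-permutation null: random sets of matching size on the fixed ranking."""
    n = stats_sorted.size
    out = np.empty((set_sizes.size, n_perm))
    for si, size in enumerate(set_sizes):
        member = np.zeros((n, n_perm), dtype=bool)
        for j in range(n_perm):
            member[rng.choice(n, size=size, replace=False), j] = True
        out[si] = _es_many(np.broadcast_to(stats_sorted[:, None], (n, n_perm)), member)
    return out


def run_enrichment(
    ranked: pd.Series,
    sets: GeneSetCollection,
    config: AnalysisConfig | None = None,
    *,
    expr: ExpressionMatrix | None = None,
    samples: pd.Series | None = None,
    contrast: tuple[str, str] | None = None,
    permutation: str = "sample",
) -> pd.DataFrame:
    """Score every gene set against a ranked list.

    ``permutation="sample"`` (default) requires ``expr``, ``samples`` and
    ``contrast`` so group labels can be reshuffled; ``"gene"`` permutes
    gene membership on the fixed ranking instead.

    Returns a DataFrame indexed by set name with columns ``class_label``,
    ``size``, ``es``, ``nes``, ``p``, ``fdr_q`` and ``enriched_group``
    (the contrast side favoured by the sign of the score).
    """
    config = config or AnalysisConfig()
    universe = ranked.index.to_numpy()
    stats = ranked.to_numpy(dtype=float)

    kept, memberships = [], []
    for gs in sets:
        member = np.isin(universe, list(gs.members))
        if member.sum() < config.min_set_size:
            logger.warning(
                "gene set %r has %d genes in the universe (< %d); skipped",
                gs.name, int(member.sum()), config.min_set_size,
            )
            continue
        kept.append(gs)
        memberships.append(member)
    if not kept:
        raise ValueError("no gene set meets the minimum size in the universe")
    memberships = np.vstack(memberships)

    es_obs = np.array(
        [enrichment_score(stats, m) for m in memberships]
    )

    rng = np.random.default_rng(config.seed)
    if permutation == "sample":
        if expr is None or samples is None or contrast is None:
            raise ValueError(
                "sample-label permutation requires expr, samples and contrast"
            )
        # memberships above are in ranked order; rebuild in matrix gene order
        gene_ids = np.asarray(expr.gene_ids)
        memb_matrix = np.vstack(
            [np.isin(gene_ids, list(gs.members)) for gs in kept]
        )
        null = _null_es(
            expr, samples, contrast, memb_matrix, config.n_permutations, rng, gene_ids
        )
    elif permutation == "gene":
        null = _null_es_genes(
            stats, memberships.sum(axis=1), config.n_permutations, rng
        )
    else:
        raise ValueError(f"unknown permutation mode {permutation!r}")

    nes_obs, nes_null, p = _normalize(es_obs, null)
    q = _pooled_fdr(nes_obs, nes_null)

    if contrast is not None:
        hi, lo = contrast
    else:
        hi, lo = "positive", "negative"
    out = pd.DataFrame(
        {
            "class_label": [gs.class_label for gs in kept],
            "size": memberships.sum(axis=1),
            "es": es_obs,
            "nes": nes_obs,
            "p": p,
            "fdr_q": q,
            "enriched_group": np.where(nes_obs >= 0, hi, lo),
        },
        index=pd.Index([gs.name for gs in kept], name="set"),
    )
    return out


def _normalize(es_obs: np.ndarray, null: np.ndarray):
    """NES = ES / mean(|null ES| of matching sign), per set; permutation p
    from the matching-sign tail."""
    n_sets, n_perm = null.shape
    nes_obs = np.zeros(n_sets)
    nes_null = np.zeros_like(null)
    p = np.ones(n_sets)
    for i in range(n_sets):
        pos = null[i][null[i] >= 0]
        neg = null[i][null[i] < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        scale = np.where(null[i] >= 0, mean_pos, mean_neg)
        nes_null[i] = np.divide(
            null[i], scale, out=np.zeros_like(null[i]), where=~np.isnan(scale) & (scale != 0)
        )
        s = mean_pos if es_obs[i] >= 0 else mean_neg
        nes_obs[i] = es_obs[i] / s if (s and not np.isnan(s) and s > 0) else 0.0
        if es_obs[i] >= 0:
            tail = pos.size and (pos >= es_obs[i]).sum() / pos.size
        else:
            tail = neg.size and (neg <= es_obs[i]).sum() / neg.size
        p[i] = float(tail) if tail else (1.0 / (n_perm + 1))
    return nes_obs, nes_null, p


def _pooled_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """FDR-q by the pooled positive/negative null convention."""
    pooled = nes_null.ravel()
    q = np.ones_like(nes_obs)
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            num_pool = pooled[pooled >= 0]
            num = (num_pool >= nes).mean() if num_pool.size else 1.0
            obs_side = nes_obs[nes_obs >= 0]
            den = (obs_side >= nes).mean() if obs_side.size else 1.0
        else:
            num_pool = pooled[pooled < 0]
            num = (num_pool <= nes).mean() if num_pool.size else 1.0
            obs_side = nes_obs[nes_obs < 0]
            den = (obs_side <= nes).mean() if obs_side.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q
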