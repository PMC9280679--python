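"""Exact two-sample and 2x2 tests shared by the validation and count modules.

Both tests are implemented from first principles (enumeration of the
permutation / hypergeometric null) because the downstream decision rules
depend on exact small-sample behaviour: bead-array validation typically
tests n in the teens per group after missing-value removal, and clinical
tables are small 2x2 counts.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney_exact", "fisher_exact_2x2"]

# Exact enumeration limits: below these the full C(n+m, n) null is enumerated.
_EXACT_MIN_N = 8
_EXACT_TOTAL = 20


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


@lru_cache(maxsize=4096)
def _rank_sum_distribution(ranks: tuple[float, ...], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the sum of ``n`` midranks drawn without
    replacement from ``ranks``: (sorted unique sums, counts)."""
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks, n)),
        dtype=float,
        count=math.comb(len(ranks), n),
    )
    values, counts = np.unique(np.round(sums, 6), return_counts=True)
    return values, counts


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U`` is the statistic for sample ``a``.
    For min(len) <= 8 and total <= 20 the p-value is exact, by full
    enumeration of the permutation null on the pooled midranks (hence
    valid under ties); otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_exact requires non-empty samples")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    rank_sum_a = ranks[:n].sum()
    u = rank_sum_a - n * (n + 1) / 2.0

    if min(n, m) <= _EXACT_MIN_N and n + m <= _EXACT_TOTAL:
        values, counts = _rank_sum_distribution(
            tuple(np.sort(np.round(ranks, 6))), n
        )
        total = counts.sum()
        obs = round(rank_sum_a, 6)
        lower = counts[values <= obs + 1e-9].sum() / total
        upper = counts[values >= obs - 1e-9].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return float(u), float(p)

    # normal approximation with tie and continuity corrections
    big_n = n + m
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return float(u), float(min(1.0, p))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test on a 2x2 count table.

    Uses the probability-mass definition: the p-value sums the
    hypergeometric probabilities of all tables (with the same margins)
    that are no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 expects a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        raise ValueError("fisher_exact_2x2 requires positive margins")
    rv = sps.hypergeom(total, col1, row1)
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()
    if p >= 1.0 - 1e-9:  # whole support included; absorb pmf round-off
        return 1.0
    return float(p)
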