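"""Meta-analysis baselines: Fisher and Stouffer p-value combination, RankProd.

These are the fixed-rule combiners the copula model is benchmarked against.
Fisher refers -2 * sum(log p) to chi-square with 2m degrees of freedom
(m = 2 studies here, so df = 4); Stouffer averages probit-transformed
p-values; RankProd multiplies normalized ranks of the fold changes, small
products flagging genes consistently extreme in the same tail across
studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .copula import FoldChangeMatrix

logger = logging.getLogger(__name__)

#: Replacement for p = 0 in Fisher's method (keeps the log finite).
FISHER_P_FLOOR = 1e-300
#: Clamp interval for Stouffer's method; the probit diverges at both ends
#: and p-values of exactly 0 otherwise collapse many genes to one value.
STOUFFER_CLAMP = (1e-15, 1.0 - 1e-15)


@dataclass(frozen=True)
class RankProdResult:
    """Two-sided RankProd: per-gene min over the up and down tails.

    ``rp`` is the reported statistic (smaller = more consistently extreme),
    ``direction`` records which tail attained it ('up' or 'down'), ``r`` is
    the (n, 2) matrix of ascending average ranks, ``n_j`` the per-study gene
    counts.
    """

    rp: np.ndarray
    direction: np.ndarray
    r: np.ndarray
    n_j: tuple[int, int]


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pvals must be (n, 2)")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def fisher_combine(pvals: np.ndarray) -> np.ndarray:
    """Fisher's method: -2 sum log p ~ chi-square(4) under the null."""
    p = _check_pvals(pvals)
    n_zero = int(np.sum(p == 0))
    if n_zero:
        logger.warning("%d zero p-value(s) clamped to %.0e", n_zero, FISHER_P_FLOOR)
        p = np.maximum(p, FISHER_P_FLOOR)
    statistic = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(statistic, df=4)


def stouffer_combine(pvals: np.ndarray) -> np.ndarray:
    """Stouffer's method: z = sum Phi^{-1}(1 - p_j) / sqrt(2), p = 1 - Phi(z)."""
    p = _check_pvals(pvals)
    n_clamped = int(np.sum((p < STOUFFER_CLAMP[0]) | (p > STOUFFER_CLAMP[1])))
    if n_clamped:
        logger.warning("%d extreme p-value(s) clamped for Stouffer", n_clamped)
    p = np.clip(p, *STOUFFER_CLAMP)
    z = stats.norm.isf(p).sum(axis=1) / np.sqrt(2.0)
    return stats.norm.sf(z)


def rankprod(data: FoldChangeMatrix) -> RankProdResult:
    """Two-sided RankProd on the fold changes.

    The one-tail statistic is the product over studies of rank/n.  With DE
    genes in both tails we evaluate it on ascending ranks (flags the down
    tail) and on descending ranks (flags the up tail) and report the smaller
    product per gene, recording the winning direction; ties use average
    ranks, with the down tail winning exact ties.
    """
    n = data.n_genes
    r = np.column_stack(
        [stats.rankdata(data.values[:, j], method="average") for j in range(2)]
    )
    rp_down = np.prod(r / n, axis=1)
    rp_up = np.prod((n + 1 - r) / n, axis=1)
    down_wins = rp_down <= rp_up
    rp = np.where(down_wins, rp_down, rp_up)
    direction = np.where(down_wins, "down", "up")
    return RankProdResult(rp=rp, direction=direction, r=r, n_j=(n, n))
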