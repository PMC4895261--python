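"""Posterior classification and error-rate-controlled DEG selection.

Given fitted parameters, each gene gets posterior probabilities
(p0, p1, p2) of being non-DE, up-regulated or down-regulated, and a hard
label by highest posterior.  Selection ranks genes by p0 ascending and
thresholds the running mean of p0 — the expected proportion of non-DE genes
among the claimed DEGs — at a target level alpha, in the style of the
irreproducible-discovery-rate criterion: the per-gene p0 is the local
quantity, the running mean is the set-level error rate actually controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .copula import FoldChangeMatrix, ModelParams, pseudo_observations
from .estimation import e_step


@dataclass(frozen=True)
class PosteriorTable:
    """Per-gene posterior component probabilities and argmax labels."""

    gene_ids: np.ndarray
    probs: np.ndarray  # (n, 3) columns p0, p1, p2
    labels: np.ndarray  # argmax component, ties to the smaller index

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("probs must be (n, 3)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "gene_ids", np.asarray(self.gene_ids))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def p0(self) -> np.ndarray:
        return self.probs[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "p0": self.probs[:, 0],
                "p1": self.probs[:, 1],
                "p2": self.probs[:, 2],
                "label": self.labels,
            }
        )


@dataclass(frozen=True)
class SelectionTable:
    """Genes ranked by p0 with the running expected non-DE rate.

    ``order`` are indices into the original gene arrays, in rank order
    (p0 ascending, ties broken by gene id for determinism).  ``cum_error[i]``
    is the mean p0 of the first i+1 ranked genes; ``i_max`` is the largest
    rank (1-based) at which that running mean stays below alpha, and the
    selection is exactly the prefix of length ``i_max`` (0 = nothing
    selected).  ``selected`` is aligned with the original gene order.
    """

    order: np.ndarray
    cum_error: np.ndarray
    i_max: int
    selected: np.ndarray
    alpha: float

    def to_frame(self, gene_ids: np.ndarray | None = None) -> pd.DataFrame:
        n = self.order.size
        rank = np.empty(n, dtype=int)
        rank[self.order] = np.arange(1, n + 1)
        out = pd.DataFrame(
            {
                "rank": rank,
                "cum_error": self.cum_error[rank - 1],
                "selected": self.selected,
            }
        )
        if gene_ids is not None:
            out.insert(0, "gene_id", gene_ids)
        return out


def posterior_probs(data: FoldChangeMatrix, theta: ModelParams) -> PosteriorTable:
    """Posterior p_k = pi_k h_k(z_1, z_2) / sum_l pi_l h_l(z_1, z_2).

    z are the pseudo-latent values of the data under ``theta`` (ranks ->
    pseudo-uniform -> mixture quantile), so the posteriors depend on the data
    only through ranks.
    """
    pseudo = pseudo_observations(data.values, theta)
    probs = e_step(pseudo, theta)
    return PosteriorTable(
        gene_ids=data.gene_ids, probs=probs, labels=classify_probs(probs)
    )


def classify_probs(probs: np.ndarray) -> np.ndarray:
    """Argmax component per row; exact ties go to the smaller index."""
    return np.argmax(np.asarray(probs, dtype=float), axis=1)


def classify(posteriors: PosteriorTable) -> np.ndarray:
    return classify_probs(posteriors.probs)


def select_degs(posteriors: PosteriorTable, alpha: float) -> SelectionTable:
    """Select DEGs controlling the expected non-DE rate among selections.

    Rank genes by p0 ascending; the running mean of sorted p0 estimates the
    proportion of non-DE genes among the top-i calls; keep the longest
    prefix whose running mean stays below ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    p0 = posteriors.p0
    n = p0.size
    # stable: ties in p0 resolved by gene id so output is reproducible
    order = np.lexsort((posteriors.gene_ids, p0))
    cum_error = np.cumsum(p0[order]) / np.arange(1, n + 1)
    below = np.nonzero(cum_error < alpha)[0]
    i_max = int(below[-1] + 1) if below.size else 0
    selected = np.zeros(n, dtype=bool)
    selected[order[:i_max]] = True
    return SelectionTable(
        order=order, cum_error=cum_error, i_max=i_max, selected=selected, alpha=alpha
    )
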