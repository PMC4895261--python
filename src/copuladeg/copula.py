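"""Core data types and copula/mixture mathematics.

The model: each gene belongs to one of three latent components —
non-differentially-expressed (k=0), up-regulated (k=1) or down-regulated
(k=2) with proportions ``pi``.  Conditional on the component, a latent pair
(z_1, z_2) for the two studies is bivariate normal with common mean ``mu_k``,
common variance ``sigma_k**2`` and correlation ``rho_k``.  Component 0 is
anchored at mean 0, variance 1, correlation 0 for identifiability; the DE
components sit above (mu_1 > 0) and below (mu_2 < 0) it with positive
inter-study correlation.  The observed differential-expression scores are
monotone transforms of the latent scale, x_{ij} = F_j^{-1}(G(z_{ij})), where
G is the mixture CDF of the latent marginal and F_j is the (unknown) marginal
of study j — estimated by the empirical CDF, which makes the whole procedure
rank-based and scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Fixed parameters of the non-DE anchor component (never estimated).
MU0: float = 0.0
SIGMA0: float = 1.0
RHO0: float = 0.0

#: Floor applied to mixture densities before taking logs.
DENSITY_FLOOR: float = 1e-300

#: Absolute tolerance (in u) for the numerical inverse of the mixture CDF.
QUANTILE_TOL: float = 1e-9


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Per-gene differential-expression scores for the same genes in 2 studies.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, length n.
    values
        (n, 2) float array of scores (log2 fold changes or any monotone
        per-gene statistic; the model only uses their ranks).
    study_names
        Labels for the two studies/platforms.
    """

    gene_ids: np.ndarray
    values: np.ndarray
    study_names: tuple[str, str] = ("study1", "study2")

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ValueError(f"values must be (n, 2), got shape {values.shape}")
        n = values.shape[0]
        if n < 10:
            raise ValueError(f"need at least 10 genes, got {n}")
        if len(gene_ids) != n:
            raise ValueError("gene_ids length does not match values")
        if not np.all(np.isfinite(values)):
            bad = np.where(~np.isfinite(values).all(axis=1))[0]
            raise ValueError(
                f"non-finite score(s) at gene index(es) {bad[:10].tolist()}"
            )
        if len(np.unique(gene_ids)) != n:
            raise ValueError("gene_ids must be unique")
        if len(self.study_names) != 2:
            raise ValueError("exactly two study names required")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "study_names", tuple(self.study_names))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ModelParams:
    """Mixture parameters theta = (pi0, pi1, pi2, mu1, mu2, s1, s2, rho1, rho2).

    Component 0 (non-DE) is fixed at mean 0, variance 1, correlation 0 and is
    not stored.  Invariants: pi on the simplex, mu1 > 0 > mu2, sigma > 0,
    0 < rho < 1.
    """

    pi: tuple[float, float, float]
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho1: float
    rho2: float

    def __post_init__(self) -> None:
        pi = tuple(float(p) for p in self.pi)
        if len(pi) != 3:
            raise ValueError("pi must have 3 components")
        if any(p < 0 or p > 1 for p in pi) or abs(sum(pi) - 1.0) > 1e-8:
            raise ValueError(f"pi must lie on the probability simplex, got {pi}")
        if not (self.mu1 > 0 > self.mu2):
            raise ValueError(f"need mu1 > 0 > mu2, got mu1={self.mu1}, mu2={self.mu2}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigmas must be positive")
        if not (0 < self.rho1 < 1 and 0 < self.rho2 < 1):
            raise ValueError("correlations must lie strictly in (0, 1)")
        object.__setattr__(self, "pi", pi)

    # Arrays over all three components (index 0 = fixed anchor component).
    @property
    def pis(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    @property
    def mus(self) -> np.ndarray:
        return np.array([MU0, self.mu1, self.mu2])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([SIGMA0, self.sigma1, self.sigma2])

    @property
    def rhos(self) -> np.ndarray:
        return np.array([RHO0, self.rho1, self.rho2])

    def to_dict(self) -> dict:
        return {
            "pi": list(self.pi),
            "mu1": self.mu1,
            "mu2": self.mu2,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
            "rho1": self.rho1,
            "rho2": self.rho2,
        }


@dataclass(frozen=True)
class PseudoObservations:
    """Rank-derived pseudo-uniform scores u and pseudo-latent values z.

    ``u[i, j] = rank(x[i, j]) / (n + 1)`` lies strictly inside (0, 1);
    ``z = G^{-1}(u)`` under the current parameter estimate.
    """

    u: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if u.shape != z.shape or u.ndim != 2 or u.shape[1] != 2:
            raise ValueError("u and z must both be (n, 2)")
        if np.any(u <= 0) or np.any(u >= 1):
            raise ValueError("pseudo-uniform scores must lie strictly in (0, 1)")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "z", z)


def empirical_cdf_transform(x: np.ndarray) -> np.ndarray:
    """Map scores to pseudo-uniform values rank/(n+1), average ranks for ties.

    The n+1 denominator keeps every value strictly inside (0, 1) so the
    latent quantile stays finite.  Exactly invariant under any strictly
    increasing transform of the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)):
        bad = np.where(~np.isfinite(x))[0]
        raise ValueError(f"non-finite score at gene index(es) {bad[:10].tolist()}")
    return stats.rankdata(x, method="average") / (x.size + 1)


def mixture_cdf(z, theta: ModelParams):
    """Latent marginal CDF G(z) = sum_k pi_k * Phi((z - mu_k) / sigma_k)."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z, dtype=float)
    for p, m, s in zip(theta.pis, theta.mus, theta.sigmas):
        if p > 0:
            out = out + p * stats.norm.cdf((z - m) / s)
    return out if out.ndim else float(out)


def mixture_pdf(z, theta: ModelParams):
    """Latent marginal density g(z), the derivative of :func:`mixture_cdf`."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z, dtype=float)
    for p, m, s in zip(theta.pis, theta.mus, theta.sigmas):
        if p > 0:
            out = out + p * stats.norm.pdf((z - m) / s) / s
    return out if out.ndim else float(out)


def mixture_quantile(u, theta: ModelParams):
    """Numerical inverse G^{-1}(u) by vectorized bisection.

    G is strictly increasing with closed form, so bisection on a bracket
    wide enough to cover all component tails converges unconditionally;
    iterations run to interval width 1e-12, well inside QUANTILE_TOL in u.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u_arr <= 0) or np.any(u_arr >= 1) or not np.all(np.isfinite(u_arr)):
        raise ValueError("u must lie strictly in (0, 1)")
    lo_init = float(np.min(theta.mus - 10.0 * theta.sigmas))
    hi_init = float(np.max(theta.mus + 10.0 * theta.sigmas))
    lo = np.full(u_arr.shape, lo_init)
    hi = np.full(u_arr.shape, hi_init)
    # Widen bracket in the (vanishingly unlikely) case of extreme u.
    while np.any(mixture_cdf(lo, theta) >= u_arr):
        lo -= 10.0
    while np.any(mixture_cdf(hi, theta) <= u_arr):
        hi += 10.0
    while np.max(hi - lo) > 1e-7:
        mid = 0.5 * (lo + hi)
        below = mixture_cdf(mid, theta) < u_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    z = 0.5 * (lo + hi)
    # Newton polish from inside a 1e-7 bracket (G smooth, monotone)
    for _ in range(3):
        step = (mixture_cdf(z, theta) - u_arr) / np.maximum(
            mixture_pdf(z, theta), 1e-300
        )
        z = np.clip(z - step, lo, hi)
    return z if np.ndim(u) else float(z[0])


def component_density(z1, z2, k: int, theta: ModelParams):
    """Bivariate normal density h_k at (z1, z2).

    Component k has mean (mu_k, mu_k), common variance sigma_k**2 and
    correlation rho_k; k=0 factorizes into independent standard normals.
    """
    if k not in (0, 1, 2):
        raise ValueError(f"component must be 0, 1 or 2, got {k}")
    m = theta.mus[k]
    s = theta.sigmas[k]
    r = theta.rhos[k]
    d1 = (np.asarray(z1, dtype=float) - m) / s
    d2 = (np.asarray(z2, dtype=float) - m) / s
    one_minus_r2 = 1.0 - r * r
    quad = (d1 * d1 - 2.0 * r * d1 * d2 + d2 * d2) / one_minus_r2
    out = np.exp(-0.5 * quad) / (2.0 * np.pi * s * s * np.sqrt(one_minus_r2))
    return out if out.ndim else float(out)


def mixture_density(z1, z2, theta: ModelParams):
    """Full mixture density sum_k pi_k h_k(z1, z2)."""
    out = np.zeros(np.broadcast(np.asarray(z1), np.asarray(z2)).shape)
    for k, p in enumerate(theta.pis):
        if p > 0:
            out = out + p * component_density(z1, z2, k, theta)
    return out if out.ndim else float(out)


def pseudo_observations(values: np.ndarray, theta: ModelParams) -> PseudoObservations:
    """Build pseudo-observations: u from column-wise ranks, z = G^{-1}(u)."""
    values = np.asarray(values, dtype=float)
    u = np.column_stack([empirical_cdf_transform(values[:, j]) for j in range(2)])
    z = np.column_stack([mixture_quantile(u[:, j], theta) for j in range(2)])
    return PseudoObservations(u=u, z=z)


def pseudo_log_likelihood(pseudo: PseudoObservations, theta: ModelParams) -> float:
    """Pseudo-log-likelihood: sum_i log sum_k pi_k h_k(z_{i1}, z_{i2}).

    Densities are floored at DENSITY_FLOOR before the log; floored genes are
    counted and reported through the module logger.
    """
    dens = mixture_density(pseudo.z[:, 0], pseudo.z[:, 1], theta)
    dens = np.atleast_1d(dens)
    n_floored = int(np.sum(dens < DENSITY_FLOOR))
    if n_floored:
        logger.warning("mixture density underflow at %d gene(s); floored", n_floored)
        dens = np.maximum(dens, DENSITY_FLOOR)
    return float(np.sum(np.log(dens)))
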