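"""Synthetic-data generators and evaluation machinery.

Three generators cover the benchmark conditions:

* :func:`simulate_from_model` — exact draws from the latent three-component
  bivariate-Gaussian model, with a choice of observed marginal (rank-based
  methods cannot tell them apart, which is itself a tested property);
* :func:`simulate_violation` — the model-misspecification study: every DE
  gene gets its *own* mean and correlation drawn from uniform ranges, so no
  single three-component model is exactly true; per-platform two-sided
  z-test p-values accompany the scores for the p-value combiners;
* :func:`simulate_cross_platform` — coupled RNA-seq counts (negative
  binomial, gamma-distributed per-gene overdispersion) and microarray
  log-intensities, joined per gene and replicate by a shared uniform
  quantile so both platforms report the same underlying expression draw.

Evaluation helpers compute calibration curves (estimated non-DE rate vs
empirical FDR) and ROC/AUC for ranking statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .copula import FoldChangeMatrix, ModelParams, mixture_cdf
from .inference import SelectionTable


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"g{i:05d}" for i in range(n)])


@dataclass(frozen=True)
class ViolationConfig:
    """Model-misspecification study: per-gene uniform means/correlations.

    Defaults give 5000 genes per dataset with 60% non-DE, up-gene means
    uniform on (0.58, 1.58), down-gene means uniform on (-1.58, -0.58)
    (mirroring the up range) and inter-study correlations uniform on
    (0.80, 0.88) for both DE components.  A down range straddling zero can
    be configured, but note that it changes the identity of the best-fitting
    mixture: with many "down" genes centered near or above zero the dominant
    pseudo-likelihood mode merges them with the up component and the
    posterior non-DE probability loses its calibration semantics (see the
    methods note).
    """

    n_genes: int = 5000
    pi: tuple[float, float, float] = (0.6, 0.2, 0.2)
    mu1_range: tuple[float, float] = (0.58, 1.58)
    mu2_range: tuple[float, float] = (-1.58, -0.58)
    rho_range: tuple[float, float] = (0.80, 0.88)
    n_datasets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.mu1_range, self.mu2_range, self.rho_range):
            if lo > hi:
                raise ValueError("ranges must be valid intervals (lo <= hi)")
        if abs(sum(self.pi) - 1.0) > 1e-8 or any(p < 0 for p in self.pi):
            raise ValueError("pi must lie on the probability simplex")
        if self.n_genes < 10 or self.n_datasets < 1:
            raise ValueError("n_genes >= 10 and n_datasets >= 1 required")


@dataclass(frozen=True)
class CrossPlatformConfig:
    """Coupled RNA-seq + microarray generator settings.

    Baseline NB means are log-normal (meanlog/sdlog on the natural-log
    scale); per-gene overdispersion phi (var = m + phi m^2) is gamma with
    the given shape and rate; DE genes shift the condition-2 mean by
    +/- ``logfc_magnitude`` on the log2 scale; microarray intensities are
    normal on the log2 scale with sd ``array_noise_sd`` around the log2
    mean.  The shared quantile couples the underlying expression draw of
    the two platforms; ``platform_noise_sd`` adds independent log2-scale
    measurement noise on the microarray side so the platforms are not
    rank-identical per gene.  ``array_noise_sd``, ``platform_noise_sd`` and
    the dispersion scale are the data-quality knobs.
    """

    n_genes: int = 10000
    prop_up: float = 0.1
    prop_down: float = 0.3
    n_reps: int = 3
    nb_mean_log_mu: float = 4.0
    nb_mean_log_sigma: float = 1.5
    nb_dispersion_shape: float = 2.0
    nb_dispersion_rate: float = 20.0
    array_noise_sd: float = 0.25
    platform_noise_sd: float = 0.15
    logfc_magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or not isinstance(
            self.n_reps, (int, np.integer)
        ):
            raise ValueError("n_genes and n_reps must be integers")
        if self.prop_up < 0 or self.prop_down < 0 or self.prop_up + self.prop_down > 1:
            raise ValueError("DE proportions must be in [0,1] and sum <= 1")
        for name in (
            "nb_mean_log_sigma",
            "nb_dispersion_shape",
            "nb_dispersion_rate",
            "array_noise_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _draw_bivariate(
    rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray, rho: np.ndarray
) -> np.ndarray:
    """Per-row bivariate normal with common mean/variance and correlation."""
    e1 = rng.standard_normal(mu.size)
    e2 = rng.standard_normal(mu.size)
    z1 = mu + sigma * e1
    z2 = mu + sigma * (rho * e1 + np.sqrt(1.0 - rho**2) * e2)
    return np.column_stack([z1, z2])


def simulate_from_model(
    theta: ModelParams, n: int, seed: int, marginal: str = "latent"
) -> tuple[FoldChangeMatrix, np.ndarray]:
    """Draw n genes exactly from the latent mixture model.

    Component labels come from ``theta.pi``; the latent pair from the
    component's bivariate normal; the observed score is F^{-1}(G(z)) for the
    chosen marginal F: ``latent`` (x = z), ``normal`` (standard normal) or
    ``lognormal``.  Returns the score matrix and the true labels.
    """
    if marginal not in ("latent", "normal", "lognormal"):
        raise ValueError(f"unknown marginal '{marginal}'")
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=theta.pis)
    z = _draw_bivariate(
        rng, theta.mus[labels], theta.sigmas[labels], theta.rhos[labels]
    )
    if marginal == "latent":
        x = z
    else:
        u = mixture_cdf(z, theta)
        x = stats.norm.ppf(u)
        if marginal == "lognormal":
            x = np.exp(x)
    data = FoldChangeMatrix(gene_ids=_gene_ids(n), values=x)
    return data, labels


def simulate_violation(
    config: ViolationConfig,
) -> list[tuple[FoldChangeMatrix, np.ndarray, np.ndarray]]:
    """Generate misspecified datasets with per-gene DE means/correlations.

    Each DE gene draws its own mean from the component's uniform range and
    its own correlation from ``rho_range`` (unit variance throughout);
    non-DE genes are independent standard normal pairs.  The scores double
    as z-statistics: the returned per-platform p-values are two-sided normal
    tail areas 2(1 - Phi(|x|)).
    """
    out = []
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_datasets):
        n = config.n_genes
        labels = rng.choice(3, size=n, p=np.asarray(config.pi))
        mu = np.zeros(n)
        rho = np.zeros(n)
        up = labels == 1
        down = labels == 2
        mu[up] = rng.uniform(*config.mu1_range, size=int(up.sum()))
        mu[down] = rng.uniform(*config.mu2_range, size=int(down.sum()))
        rho[up | down] = rng.uniform(*config.rho_range, size=int((up | down).sum()))
        x = _draw_bivariate(rng, mu, np.ones(n), rho)
        pvals = 2.0 * stats.norm.sf(np.abs(x))
        out.append((FoldChangeMatrix(gene_ids=_gene_ids(n), values=x), labels, pvals))
    return out


def simulate_cross_platform(
    config: CrossPlatformConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Coupled RNA-seq count and microarray intensity matrices.

    Per gene: a baseline mean, a gamma overdispersion, and a DE shift of the
    condition-2 mean.  Per gene x condition x replicate a single uniform
    quantile is drawn and pushed through both platforms' distributions — the
    NB quantile function for counts and a log2-scale normal quantile for
    intensities — so the two platforms measure the same underlying draw.

    Returns (counts, intensities, labels); matrices are genes x
    (2 * n_reps) with columns ``<cond>_rep<r>``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_genes)
    n_up = int(round(config.prop_up * n))
    n_down = int(round(config.prop_down * n))
    labels = np.zeros(n, dtype=int)
    perm = rng.permutation(n)
    labels[perm[:n_up]] = 1
    labels[perm[n_up : n_up + n_down]] = 2

    base_mean = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, size=n)
    phi = rng.gamma(
        config.nb_dispersion_shape, 1.0 / config.nb_dispersion_rate, size=n
    )
    shift = np.where(
        labels == 1, config.logfc_magnitude, np.where(labels == 2, -config.logfc_magnitude, 0.0)
    )
    means = {"cond1": base_mean, "cond2": base_mean * 2.0**shift}

    counts = {}
    intens = {}
    for cond, m in means.items():
        size = 1.0 / phi  # NB number-of-failures parameter
        p = size / (size + m)
        for rep in range(1, config.n_reps + 1):
            q = rng.uniform(size=n)
            col = f"{cond}_rep{rep}"
            counts[col] = stats.nbinom.ppf(q, size, p).astype(int)
            intens[col] = stats.norm.ppf(
                q, loc=np.log2(m), scale=config.array_noise_sd
            ) + config.platform_noise_sd * rng.standard_normal(n)
    ids = _gene_ids(n)
    return (
        pd.DataFrame(counts, index=ids),
        pd.DataFrame(intens, index=ids),
        labels,
    )


def fold_changes_from_matrices(
    counts: pd.DataFrame,
    intensities: pd.DataFrame,
    pseudocount: float = 0.5,
) -> FoldChangeMatrix:
    """Per-gene log2 fold changes from paired expression matrices.

    RNA-seq: mean log2(count + pseudocount) difference between conditions;
    microarray: mean log2-intensity difference.  Columns are matched on the
    ``cond1``/``cond2`` prefix.
    """
    def _lfc(frame: pd.DataFrame, log: bool) -> np.ndarray:
        c1 = frame.loc[:, [c.startswith("cond1") for c in frame.columns]]
        c2 = frame.loc[:, [c.startswith("cond2") for c in frame.columns]]
        if log:
            c1, c2 = np.log2(c1 + pseudocount), np.log2(c2 + pseudocount)
        return (c2.mean(axis=1) - c1.mean(axis=1)).to_numpy()

    return FoldChangeMatrix(
        gene_ids=counts.index.to_numpy(),
        values=np.column_stack([_lfc(counts, log=True), _lfc(intensities, log=False)]),
        study_names=("rnaseq", "microarray"),
    )


def evaluate_calibration(
    estimated_error: np.ndarray, labels: np.ndarray, selection: SelectionTable
) -> pd.DataFrame:
    """Pair the estimated non-DE rate with the empirical FDR at every rank.

    The empirical FDR at rank i is the fraction of truly non-DE genes
    (label 0) among the top-i genes in the selection's p0-ascending order.
    """
    labels = np.asarray(labels)
    order = selection.order
    n = order.size
    ranks = np.arange(1, n + 1)
    empirical = np.cumsum(labels[order] == 0) / ranks
    return pd.DataFrame(
        {
            "rank": ranks,
            "estimated_error": np.asarray(estimated_error, dtype=float),
            "empirical_fdr": empirical,
        }
    )


def evaluate_roc(score: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC for a DE ranking statistic (higher score = more DE).

    ``labels`` are binarized as DE (1 or 2) vs non-DE (0); tied scores are
    handled by the usual averaging over orderings.
    """
    y = (np.asarray(labels) != 0).astype(int)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; ROC undefined")
    score = np.asarray(score, dtype=float)
    fpr, tpr, _ = roc_curve(y, score)
    auc = float(roc_auc_score(y, score))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc
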