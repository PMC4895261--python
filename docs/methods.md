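# Methods

## Model

`copuladeg` combines per-gene differential-expression scores from two
studies through a three-component Gaussian copula mixture. Genes are
non-DE, up-regulated or down-regulated with proportions π = (π₀, π₁, π₂);
conditional on the component, a latent pair (z₁, z₂) is bivariate normal
with common mean μ_k, common variance σ_k² and inter-study correlation ρ_k.
The non-DE component is pinned at μ₀ = 0, σ₀² = 1, ρ₀ = 0: because only the
ranks of the observed scores enter the model, location and scale of the
latent axis are not identifiable and the null component provides the
anchor. The DE components are constrained to μ₁ > 0 > μ₂ (direction) and
0 < ρ_k < 1 (signals concordant across studies). Observed scores relate to
the latent scale only through x_{ij} = F_j⁻¹(G(z_{ij})) with G the latent
mixture CDF and F_j unknown study-specific marginals, so the fitted model,
the posteriors and the DEG selection are all exactly invariant under
strictly increasing transforms of either score column — the property that
makes cross-platform integration possible without normalisation.

Assumptions worth keeping in mind: scores are i.i.d. across genes within a
study; the same gene measures the same underlying process in both studies
(equal latent marginals across the pair); DE genes in the same direction
share one Gaussian component. Violations of the last assumption are the
subject of the violation benchmark below.

## Pseudo-observations and the likelihood

F_j is estimated by the empirical CDF rescaled to rank/(n+1) (average ranks
for ties), keeping every pseudo-uniform value strictly inside (0, 1) so the
latent quantile G⁻¹ stays finite. The pseudo-log-likelihood is
Σ_i log Σ_k π_k h_k(z_{i1}, z_{i2}) with z = G⁻¹(u); mixture densities are
floored at 1e−300 before the log (occurrences counted and logged). G⁻¹ is
computed by vectorized bisection to a bracket of width 1e−7 followed by
three Newton steps, giving |G(G⁻¹(u)) − u| ≤ 1e−9.

## Estimation

Fitting alternates two phases (an ECM on pseudo-data):

1. **pseudo-data refresh** — recompute z = G⁻¹(u; θ) under the current θ;
2. **inner EM** at fixed z — E-step: posterior responsibilities; M-step:
   responsibility-weighted Gaussian updates under the equal-mean,
   equal-variance bivariate structure (for which the weighted MLE has the
   closed form: mean of (z₁+z₂)/2, pooled variance over both coordinates,
   cross-moment over variance for ρ), followed by projection onto the
   constraint set (μ₁ ≥ 0.01, μ₂ ≤ −0.01, ρ ∈ [0.001, 0.999], σ ≥ 0.05,
   π ≥ 1e−6 renormalized). Component 1 is re-anchored as the high-mean
   component after every M-step so labels cannot switch between restarts.

Within an inner EM phase the pseudo-log-likelihood is non-decreasing (the
tests assert this at 1e−8 per step). Across refreshes it is **not** a joint
objective — empirically it drifts slightly downward while the parameters
converge geometrically to the fixed point — so convergence is declared on
parameter stability: max absolute change in any element of θ below
`param_tol` (default 5e−4, all parameters being O(1)) over one outer
iteration. `tol` (default 1e−5, relative) governs the inner EM, which runs
two orders of magnitude past the outer scale (0.01·tol) so each refresh
starts from an equilibrated EM fixed point; with a loose inner criterion
the outer iteration accomplishes little per refresh and can appear
converged far from the fixed point. Defaults: `max_iter` 200 outer
refreshes, `inner_max_iter` 300, `n_starts` 3 seed-jittered restarts
(base start π = (0.6, 0.2, 0.2), μ = ±2, σ = 1, ρ = 0.5) with the best
final pseudo-likelihood winning and ties going to the lowest start index.
A `shared_sigma` option constrains σ₁ = σ₂ (the symmetric reading of the
parameterisation); separate sigmas are the default since each DE component
has its own variance in the latent model.

The pseudo-likelihood surface can be multimodal in finite samples: when the
smallest DE component carries few genes (a few hundred), a mode that merges
it into the null occasionally attains the higher pseudo-likelihood. The
parameter-recovery tests therefore assert success over a majority of
independent draws (9/10 at n = 10 000) rather than for every draw. A column
with (nearly) constant values carries no rank information and is rejected
up front.

## Classification and DEG selection

Posterior component probabilities follow the usual mixture ratio; the hard
label is the argmax with exact ties resolved to the smaller component index
(conservative: prefers non-DE). Selection ranks genes by p₀ ascending
(ties broken by gene id for determinism) and computes the running mean of
sorted p₀ — the expected proportion of non-DE genes among the top-i calls.
The reported list is the longest prefix whose running mean stays below α;
i_max = 0 (empty list) is a valid outcome. Both the per-gene p₀ (a local
quantity) and the running mean (the set-level error rate actually
controlled) are reported, mirroring the local-idr / IDR distinction.

## Baselines

Fisher: −2 Σ log p referred to χ² with 4 df (two studies); zero p-values
clamped at 1e−300. Stouffer: z = Σ Φ⁻¹(1−p)/√2, combined p = 1 − Φ(z);
p clamped to [1e−15, 1−1e−15] because the probit diverges at the ends and
p = 0 otherwise collapses many genes onto one value. RankProd: product over
studies of rank/n. The one-tail product only flags one direction, while DE
genes sit in both tails of a fold-change list, so the statistic is
evaluated on ascending ranks (down tail) and descending ranks (up tail) and
the smaller product is reported per gene with its direction; exact ties go
to the down tail. RankProd is used as a ranking statistic only — no
permutation significance.

## Synthetic data

Three generators define the benchmark conditions.

**Exact-model draws** (`simulate_from_model`): labels from π, latent pairs
from the component Gaussians, observed scores through a chosen marginal
(latent/normal/lognormal — indistinguishable to the method, which is itself
a tested property). The recovery benchmark uses
θ* = (π = (0.6, 0.25, 0.15), μ₁ = 2.5, μ₂ = −2.0, σ = 1, ρ = 0.84) at
n = 10 000.

**Violation benchmark** (`simulate_violation`): each DE gene draws its own
mean and correlation — μ ~ unif(0.58, 1.58) for up, unif(−1.58, −0.58) for
down, ρ ~ unif(0.80, 0.88), unit variance — so no single three-component
model is exactly true; per-platform p-values are two-sided normal tails
2(1 − Φ(|x|)), the scores being unit-variance z-statistics by construction.
Defaults: 5000 genes, π = (0.6, 0.2, 0.2) (symmetric setting) or
(0.6, 0.1, 0.3) (asymmetric). On the down-mean range we deliberately use
(−1.58, −0.58), mirroring the up range rather than the variant that
straddles zero: with a large fraction of "down" genes centred at or above
zero there is no down-shifted cluster to find — the best-fitting mixture
then places all correlated genes in one wide component and re-purposes the
other as a second null (ρ at the lower boundary), and the posterior non-DE
probability loses its error-rate semantics. The straddling variant remains
available through `mu2_range` for stress-testing; expect mis-calibration
there, not because the optimizer fails but because the model class no
longer matches the generator's structure.

**Cross-platform generator** (`simulate_cross_platform`): per gene, a
baseline mean from a log-normal (meanlog 4.0, sdlog 1.5 — median ≈ 55
counts with a long right tail, typical of bulk RNA-seq), an overdispersion
φ from Gamma(shape 2, rate 20) (mean 0.1, var = m + φm²), and a DE shift of
±1 log2 unit of the condition-2 mean for 10% up / 30% down genes by
default. Per gene × condition × replicate one uniform quantile is drawn and
pushed through both the NB quantile function (counts) and a log2-scale
normal quantile with sd 0.25 (microarray), coupling the platforms;
independent microarray noise (`platform_noise_sd`, default 0.15 log2 units)
is added on top because with the quantile fully shared the intensity is a
deterministic monotone transform of the count and the platforms would be
rank-identical per gene. Caveat: even with that noise, the replicate-level
coupling correlates the fold-change noise of non-DE genes across platforms
(violating the model's ρ₀ = 0), so this generator exercises the IO path and
the qualitative pipeline rather than the calibration guarantees; the
violation benchmark is the quantitative testbed.

What passing tests on these generators do **not** show about real data:
real cross-platform studies carry probe-level artefacts, normalisation
residue and lab effects that none of the generators emulate; the
rank-based design is expected to absorb monotone distortions of that kind,
but nothing here validates behaviour under non-monotone ones.

## Evaluation machinery

Calibration pairs the estimated non-DE rate (running mean of sorted p₀)
with the empirical FDR (fraction of truly non-DE genes among the top-i) at
every rank; the benchmark statistic is the mean absolute gap over ranks
i ≥ 50 (below that the empirical FDR is dominated by small-count noise).
ROC/AUC uses the standard threshold sweep with tie averaging
(scikit-learn), scoring DE-vs-non-DE with 1 − p₀ for the copula method,
−RP for RankProd and −p for the combiners.

## Problem sizes and numerical choices

The shipped test suite fits n = 10 000 draws for recovery (10 seeds),
twenty 5000-gene datasets per violation setting, and smaller fixtures
elsewhere; the acceptance script uses 3 recovery seeds and 10 datasets per
setting — sizes chosen to estimate each quantity stably while keeping a
full run in the minutes range on one CPU. Tolerances: quantile inversion
1e−9 (in u); oracle-equivalence checks 1e−10; density-normalisation check
1e−3 on an 8σ grid; EM monotonicity 1e−8 per step. Degenerate inputs:
constant columns rejected; all-zero responsibility rows made uniform and
logged; components with responsibility mass below 1e−6·n frozen at their
previous parameters for that iteration.

## Known limitations

Two studies only; no standard errors or model selection on the number of
components; empirical marginals only (no parametric F_j); RankProd
significance by permutation is out of scope. The pseudo-likelihood ignores
the sampling noise of the empirical marginals, so parameter uncertainty is
understated at small n — selections remain rank-valid but α-control
inherits the posterior's finite-sample bias.
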