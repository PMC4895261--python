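"""Unit and property tests for the copula/mixture mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import dblquad

from copuladeg import (
    FoldChangeMatrix,
    ModelParams,
    PseudoObservations,
    component_density,
    empirical_cdf_transform,
    mixture_cdf,
    mixture_quantile,
    pseudo_log_likelihood,
)
from copuladeg.copula import mixture_density, mixture_pdf


class TestFoldChangeMatrix:
    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError, match=r"\(n, 2\)"):
            FoldChangeMatrix(gene_ids=["a"], values=np.zeros((1, 3)))

    def test_rejects_too_few_genes(self):
        with pytest.raises(ValueError, match="at least 10"):
            FoldChangeMatrix(
                gene_ids=[f"g{i}" for i in range(5)], values=np.zeros((5, 2))
            )

    def test_rejects_nonfinite_naming_index(self):
        values = np.zeros((12, 2))
        values[7, 1] = np.nan
        with pytest.raises(ValueError, match="7"):
            FoldChangeMatrix(gene_ids=[f"g{i}" for i in range(12)], values=values)

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="unique"):
            FoldChangeMatrix(gene_ids=["g0"] * 12, values=np.zeros((12, 2)))


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pi": (0.5, 0.5, 0.5)},  # off the simplex
            {"mu1": -1.0},  # mean ordering violated
            {"mu2": 0.5},
            {"sigma1": 0.0},
            {"rho1": 1.0},
            {"rho2": 0.0},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        base = dict(
            pi=(0.6, 0.2, 0.2), mu1=2.0, mu2=-2.0, sigma1=1.0, sigma2=1.0,
            rho1=0.5, rho2=0.5,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            ModelParams(**base)


class TestEmpiricalCdfTransform:
    def test_average_ranks_over_n_plus_one(self):
        np.testing.assert_allclose(
            empirical_cdf_transform(np.array([3.0, 1.0, 2.0])), [0.75, 0.25, 0.50]
        )

    def test_all_tied(self):
        np.testing.assert_allclose(
            empirical_cdf_transform(np.array([5.0, 5.0, 5.0])), [0.5, 0.5, 0.5]
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="index"):
            empirical_cdf_transform(np.array([1.0, np.inf, 2.0]))

    @settings(deadline=None)
    @given(
        st.lists(st.integers(-10**6, 10**6), min_size=2, max_size=40, unique=True)
    )
    def test_invariant_under_monotone_transform(self, xs):
        # integer-backed grid so exp() cannot collapse distinct values to ties
        x = np.array(xs, dtype=float) / 1e4
        np.testing.assert_array_equal(
            empirical_cdf_transform(x), empirical_cdf_transform(np.exp(x / 50.0))
        )
        assert np.all((empirical_cdf_transform(x) > 0))
        assert np.all((empirical_cdf_transform(x) < 1))


class TestMixtureCdf:
    def test_reduces_to_standard_normal(self):
        theta = ModelParams(
            pi=(1.0, 0.0, 0.0), mu1=2.0, mu2=-2.0, sigma1=1.0, sigma2=1.0,
            rho1=0.5, rho2=0.5,
        )
        assert mixture_cdf(0.0, theta) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_mixture_median_zero(self, theta_symmetric):
        assert mixture_cdf(0.0, theta_symmetric) == pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_value_against_direct_sum(self, theta_mixed):
        # independent evaluation: 0.5*Phi(0) + 0.3*Phi(-1) + 0.2*Phi(1)
        expected = 0.5 * 0.5 + 0.3 * stats.norm.cdf(-1) + 0.2 * stats.norm.cdf(1)
        assert expected == pytest.approx(0.46587, abs=5e-6)
        assert mixture_cdf(0.0, theta_mixed) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_with_correct_limits(self, theta_generic):
        grid = np.linspace(-6, 6, 400)  # strict within float resolution
        vals = mixture_cdf(grid, theta_generic)
        assert np.all(np.diff(vals) > 0)
        assert mixture_cdf(-40.0, theta_generic) < 1e-12
        assert mixture_cdf(40.0, theta_generic) > 1 - 1e-12


class TestMixtureQuantile:
    def test_standard_normal_median(self):
        theta = ModelParams(
            pi=(1.0, 0.0, 0.0), mu1=2.0, mu2=-2.0, sigma1=1.0, sigma2=1.0,
            rho1=0.5, rho2=0.5,
        )
        assert mixture_quantile(0.5, theta) == pytest.approx(0.0, abs=1e-8)

    def test_inverse_of_cdf_example(self, theta_mixed):
        u = mixture_cdf(0.0, theta_mixed)
        assert mixture_quantile(u, theta_mixed) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("z", [-3.0, 0.0, 3.0])
    def test_round_trip(self, theta_generic, z):
        assert mixture_quantile(
            mixture_cdf(z, theta_generic), theta_generic
        ) == pytest.approx(z, abs=1e-6)

    def test_forward_residual_within_tolerance(self, theta_generic):
        u = np.linspace(1e-6, 1 - 1e-6, 501)
        z = mixture_quantile(u, theta_generic)
        assert np.max(np.abs(mixture_cdf(z, theta_generic) - u)) < 1e-9
        assert np.all(np.diff(z) > 0)  # monotone in u

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.2, 1.3, np.nan])
    def test_rejects_out_of_range(self, theta_mixed, u):
        with pytest.raises(ValueError):
            mixture_quantile(u, theta_mixed)


class TestComponentDensity:
    def test_null_component_height_at_origin(self, theta_mixed):
        assert component_density(0.0, 0.0, 0, theta_mixed) == pytest.approx(
            1.0 / (2 * np.pi), rel=1e-12
        )

    def test_null_component_factorizes(self, theta_generic):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 50))
        np.testing.assert_allclose(
            component_density(a, b, 0, theta_generic),
            stats.norm.pdf(a) * stats.norm.pdf(b),
            rtol=1e-12,
        )

    def test_mode_height_with_correlation(self):
        theta = ModelParams(
            pi=(0.5, 0.3, 0.2), mu1=2.0, mu2=-1.0, sigma1=1.0, sigma2=1.0,
            rho1=0.8, rho2=0.5,
        )
        expected = 1.0 / (2 * np.pi * np.sqrt(1 - 0.64))
        assert expected == pytest.approx(0.26526, abs=5e-6)
        assert component_density(2.0, 2.0, 1, theta) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_scipy_bivariate_normal(self, theta_generic):
        rng = np.random.default_rng(1)
        pts = rng.normal(scale=2.0, size=(30, 2))
        for k in range(3):
            m = theta_generic.mus[k]
            s2 = theta_generic.sigmas[k] ** 2
            r = theta_generic.rhos[k]
            cov = [[s2, r * s2], [r * s2, s2]]
            ref = stats.multivariate_normal(mean=[m, m], cov=cov).pdf(pts)
            np.testing.assert_allclose(
                component_density(pts[:, 0], pts[:, 1], k, theta_generic),
                ref,
                rtol=1e-10,
            )

    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_integrates_to_one(self, theta_generic, k):
        m = theta_generic.mus[k]
        s = theta_generic.sigmas[k]
        lo, hi = m - 8 * s, m + 8 * s
        total, _ = dblquad(
            lambda z2, z1: component_density(z1, z2, k, theta_generic),
            lo, hi, lo, hi, epsabs=1e-6,
        )
        assert total == pytest.approx(1.0, abs=1e-3)


class TestPseudoLogLikelihood:
    def test_single_gene_standard_normal(self):
        theta = ModelParams(
            pi=(1.0, 0.0, 0.0), mu1=2.0, mu2=-2.0, sigma1=1.0, sigma2=1.0,
            rho1=0.5, rho2=0.5,
        )
        pseudo = PseudoObservations(u=np.full((1, 2), 0.5), z=np.zeros((1, 2)))
        assert pseudo_log_likelihood(pseudo, theta) == pytest.approx(
            np.log(1.0 / (2 * np.pi)), abs=1e-12
        )

    def test_additive_over_genes(self, theta_generic):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(8, 2))
        u = np.clip(stats.norm.cdf(z), 1e-6, 1 - 1e-6)
        whole = pseudo_log_likelihood(PseudoObservations(u=u, z=z), theta_generic)
        parts = sum(
            pseudo_log_likelihood(
                PseudoObservations(u=u[i : i + 1], z=z[i : i + 1]), theta_generic
            )
            for i in range(8)
        )
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_matches_brute_force_formula(self, theta_mixed):
        # direct per-gene evaluation of log sum_k pi_k h_k(z1, z2)
        z = np.array([[0.5, -0.3], [2.0, 1.5], [-1.0, -2.0]])
        u = stats.norm.cdf(z)
        expected = 0.0
        for z1, z2 in z:
            acc = 0.0
            for k in range(3):
                acc += theta_mixed.pis[k] * component_density(z1, z2, k, theta_mixed)
            expected += np.log(acc)
        got = pseudo_log_likelihood(PseudoObservations(u=u, z=z), theta_mixed)
        assert got == pytest.approx(expected, abs=1e-10)


def test_mixture_pdf_is_cdf_derivative(theta_generic):
    grid = np.linspace(-6, 6, 101)
    h = 1e-5
    numeric = (mixture_cdf(grid + h, theta_generic) - mixture_cdf(grid - h, theta_generic)) / (2 * h)
    np.testing.assert_allclose(mixture_pdf(grid, theta_generic), numeric, atol=1e-8)


def test_mixture_density_is_pi_weighted_sum(theta_generic):
    z1, z2 = 0.7, -0.4
    expected = sum(
        theta_generic.pis[k] * component_density(z1, z2, k, theta_generic)
        for k in range(3)
    )
    assert mixture_density(z1, z2, theta_generic) == pytest.approx(expected, rel=1e-12)
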