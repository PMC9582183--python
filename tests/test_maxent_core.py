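"""Moment constraints, the Newton ME solver, family mappings, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize as sp_optimize
from scipy import special, stats

import metaif as m
from metaif.maxent_core import _log_partition_stats, quadrature_nodes


GAMMA_BASIS = (m.basis_const(), m.basis_log(), m.basis_identity())


def gamma_constraints(alpha, beta):
    mu = np.array([1.0, special.digamma(alpha) + np.log(beta), alpha * beta])
    return m.MomentConstraintSet(GAMMA_BASIS, mu)


class TestComputeMoments:
    def test_constant_sample(self):
        cs = m.compute_moments(np.full(7, 3.0), GAMMA_BASIS)
        np.testing.assert_allclose(cs.targets, [1.0, np.log(3.0), 3.0])

    def test_two_point_log_mean(self):
        cs = m.compute_moments(np.array([1.0, np.e]),
                               (m.basis_const(), m.basis_log()))
        np.testing.assert_allclose(cs.targets, [1.0, 0.5])

    def test_gamma_draws_match_closed_form_moments(self, rng):
        x = rng.gamma(2.0, 0.5, 100_000)
        cs = m.compute_moments(x, GAMMA_BASIS)
        assert abs(cs.targets[2] - 1.0) < 0.01
        truth = special.digamma(2.0) + np.log(0.5)
        assert abs(cs.targets[1] - truth) < 0.02 * abs(truth) + 0.02

    def test_nonpositive_sample_with_log_basis_rejected(self):
        with pytest.raises(m.DomainError):
            m.compute_moments(np.array([1.0, 0.0]), GAMMA_BASIS)


class TestNewtonSolver:
    def test_mean_constraint_yields_exponential(self):
        cs = m.compute_moments(np.full(4, 2.0),
                               (m.basis_const(), m.basis_identity()))
        dens = m.solve_lambda_newton(cs, (1e-12, 80.0))
        assert abs(dens.lam.lambdas[1] - 0.5) < 1e-8

    def test_gamma_constraints_recover_multipliers(self):
        dens = m.solve_lambda_newton(gamma_constraints(2.0, 0.5), (1e-12, 50.0))
        np.testing.assert_allclose(dens.lam.lambdas[1:], [-1.0, 2.0], atol=1e-6)
        fam = m.lambda_to_family(dens.lam, dens.basis)
        assert fam.family == "erlang" or np.isclose(fam.alpha, 2.0, atol=1e-6)

    def test_moment_residuals_below_contract(self):
        dens = m.solve_lambda_newton(gamma_constraints(2.719, 0.237),
                                     (1e-12, 30.0))
        nodes, weights = dens.quadrature()
        p = m.density_eval(dens, nodes)
        g1 = float(weights @ (np.log(nodes) * p))
        g2 = float(weights @ (nodes * p))
        cs = gamma_constraints(2.719, 0.237)
        assert abs(g1 - cs.targets[1]) < 1e-8
        assert abs(g2 - cs.targets[2]) < 1e-8

    def test_jensen_infeasible_moment_pair_raises(self):
        """E[ln X] > ln E[X] violates Jensen's inequality, so no density on
        any support can satisfy the pair; the solver must report failure."""
        bad = m.MomentConstraintSet(GAMMA_BASIS, np.array([1.0, -0.446, 0.335]))
        with pytest.raises(m.ConvergenceError) as exc:
            m.solve_lambda_newton(bad, (1e-12, 10.0))
        assert exc.value.residual is not None

    def test_entropy_maximal_among_perturbed_reprojected_densities(self, rng):
        """The ME solution has the largest entropy among densities satisfying
        the same constraints, built by perturb-and-reproject on the grid."""
        cs = gamma_constraints(2.0, 0.8)
        dens = m.solve_lambda_newton(cs, (1e-9, 40.0))
        nodes, weights = dens.quadrature()
        p = m.density_eval(dens, nodes)
        h_me = float(-(weights @ (p * np.log(np.maximum(p, 1e-300)))))
        phi = np.stack([b(nodes) for b in cs.basis])

        def reproject(q):
            # rescale within the exponential span to restore the moments
            def resid(c):
                qq = q * np.exp(-c[0] - c[1] * phi[1] - c[2] * phi[2])
                return [weights @ qq - 1.0,
                        weights @ (qq * phi[1]) - cs.targets[1],
                        weights @ (qq * phi[2]) - cs.targets[2]]
            sol = sp_optimize.root(resid, np.zeros(3), tol=1e-12)
            return q * np.exp(-sol.x[0] - sol.x[1] * phi[1] - sol.x[2] * phi[2]), sol.success

        worse = 0
        for _ in range(200):
            bump = rng.normal(0, 0.3) * np.sin(rng.uniform(0.5, 3) * nodes
                                               + rng.uniform(0, np.pi))
            q, ok = reproject(p * np.exp(bump))
            if not ok:
                continue
            h = float(-(weights @ (q * np.log(np.maximum(q, 1e-300)))))
            assert h <= h_me + 1e-6
            worse += 1
        assert worse > 100  # most perturbations must actually reproject


class TestDensityEval:
    def test_exponential_value_at_origin(self):
        lam = m.LambdaVector(np.array([-np.log(2.0), 2.0]))
        dens = m.MaxEntDensity((1e-12, 60.0), lam,
                               (m.basis_const(), m.basis_identity()))
        assert abs(m.density_eval(dens, 1e-12) - 2.0) < 1e-9

    def test_normalization_and_outside_support(self):
        dens = m.solve_lambda_newton(gamma_constraints(2.0, 0.5), (1e-12, 50.0))
        nodes, weights = dens.quadrature()
        assert abs(weights @ m.density_eval(dens, nodes) - 1.0) < 1e-6
        assert m.density_eval(dens, 100.0) == 0.0

    def test_table_gamma_multipliers_reproduce_pdf(self):
        fam = m.ParametricFamily("gamma", 2.719, 0.237)
        lam = m.family_to_lambda(fam)
        dens = m.MaxEntDensity((1e-12, 50.0), lam, GAMMA_BASIS)
        x = np.linspace(0.05, 3.0, 200)
        np.testing.assert_allclose(m.density_eval(dens, x), fam.pdf(x),
                                   rtol=0, atol=1e-10)


class TestFamilyMappings:
    def test_weibull_shape_one_reduces_to_exponential(self):
        lam = m.family_to_lambda(m.ParametricFamily("weibull", 1.0, 2.0))
        np.testing.assert_allclose(lam.lambdas[1], 0.0, atol=1e-12)
        np.testing.assert_allclose(lam.lambdas[2], 0.5, atol=1e-12)

    def test_table_gamma_multipliers(self):
        lam = m.family_to_lambda(m.ParametricFamily("gamma", 2.719, 0.237))
        np.testing.assert_allclose(lam.lambdas[1], -1.719, atol=1e-12)
        np.testing.assert_allclose(lam.lambdas[2], 1 / 0.237, rtol=1e-12)

    def test_lambda_to_family_gamma_integer_shape_is_erlang(self):
        lam = m.LambdaVector(np.array([0.3, -1.0, 2.0]))
        fam = m.lambda_to_family(lam, GAMMA_BASIS)
        assert fam.family == "erlang"
        assert fam.alpha == 2.0 and np.isclose(fam.beta, 0.5)

    def test_table_weibull_round_trip(self):
        fam = m.ParametricFamily("weibull", 2.6, 1.738)
        back = m.lambda_to_family(m.family_to_lambda(fam),
                                  (m.basis_const(), m.basis_log(),
                                   m.basis_power(2.6)))
        assert np.isclose(back.alpha, 2.6) and np.isclose(back.beta, 1.738)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.2, 8.0), beta=st.floats(0.05, 10.0),
           fam_name=st.sampled_from(["gamma", "weibull"]))
    def test_round_trip_random_parameters(self, alpha, beta, fam_name):
        fam = m.ParametricFamily(fam_name, alpha, beta)
        basis = (m.basis_const(), m.basis_log(),
                 m.basis_power(alpha) if fam_name == "weibull"
                 else m.basis_identity())
        back = m.lambda_to_family(m.family_to_lambda(fam), basis)
        assert np.isclose(back.alpha, alpha, rtol=1e-9)
        assert np.isclose(back.beta, beta, rtol=1e-9)

    def test_erlang_non_integer_shape_rejected(self):
        with pytest.raises(m.DomainError):
            m.ParametricFamily("erlang", 2.5, 1.0)

    def test_unrecognized_basis_pattern(self):
        lam = m.LambdaVector(np.array([0.0, 1.0]))
        with pytest.raises(m.UnsupportedFamilyError):
            m.lambda_to_family(lam, (m.basis_const(), m.basis_xlogx()))

    def test_erlang_projection_preserves_mean(self):
        fam = m.ParametricFamily("gamma", 2.719, 0.237)
        erl = m.erlang_projection(fam)
        assert erl.alpha == 3.0
        np.testing.assert_allclose(erl.alpha * erl.beta, fam.alpha * fam.beta)


class TestDifferentialEntropy:
    def test_uniform_grid_density_is_zero(self):
        grid = np.linspace(0.0, 1.0, 2001)
        masses = np.full(grid.size, 1.0)
        gd = m.GridDensity.from_pdf(grid, masses)
        assert abs(m.differential_entropy(gd)) < 1e-9

    def test_exponential_closed_form(self):
        fam = m.ParametricFamily("exponential", 1.0, 0.7)
        assert abs(m.differential_entropy(fam) - (1 + np.log(0.7))) < 1e-10

    def test_gamma_quadrature_matches_closed_form(self):
        a, b = 2.719, 0.237
        fam = m.ParametricFamily("gamma", a, b)
        closed = a + np.log(b) + special.gammaln(a) + (1 - a) * special.digamma(a)
        assert abs(m.differential_entropy(fam) - closed) < 1e-8

    def test_non_normalized_density_rejected(self):
        lam = m.LambdaVector(np.array([1.0, 0.1]))  # wrong log-partition
        dens = m.MaxEntDensity((1e-6, 5.0), lam,
                               (m.basis_const(), m.basis_identity()))
        with pytest.raises(m.DomainError):
            m.differential_entropy(dens)


class TestWeibullBaselines:
    def test_empirical_cv_one_is_exponential_like(self):
        # {2 - sqrt(2), 2 + sqrt(2)} has sample sd == mean, so the
        # method-of-moments shape is exactly 1 and beta the sample mean
        x = np.array([2.0 - np.sqrt(2.0), 2.0 + np.sqrt(2.0)])
        fam = m.fit_weibull_empirical(x)
        assert np.isclose(fam.alpha, 1.0, atol=1e-10)
        assert np.isclose(fam.beta, np.mean(x), rtol=1e-10)

    def test_empirical_recovers_weibull_shape(self, rng):
        x = stats.weibull_min(2.0, scale=1.0).rvs(100_000, random_state=rng)
        fam = m.fit_weibull_empirical(x)
        assert abs(fam.alpha - 2.0) / 2.0 < 0.05

    def test_mle_recovers_shape_from_inverse_transform_draws(self, rng):
        u = rng.uniform(size=100_000)
        x = 1.0 * (-np.log(u)) ** (1 / 2.0)
        fam = m.fit_weibull_mle(x)
        assert abs(fam.alpha - 2.0) / 2.0 < 0.02
        assert abs(fam.beta - 1.0) < 0.02

    def test_mle_maximizes_likelihood_vs_grid(self, rng):
        x = stats.weibull_min(1.7, scale=0.8).rvs(50, random_state=rng)
        fam = m.fit_weibull_mle(x)
        ll_hat = np.sum(stats.weibull_min(fam.alpha, scale=fam.beta).logpdf(x))
        alphas = np.linspace(0.5, 4.0, 120)
        betas = np.linspace(0.2, 2.5, 120)
        best = -np.inf
        for a in alphas:
            ll = np.array([np.sum(stats.weibull_min(a, scale=b).logpdf(x))
                           for b in betas])
            best = max(best, ll.max())
        assert ll_hat >= best - 1e-6

    def test_degenerate_samples_rejected(self):
        with pytest.raises(m.DegenerateDataError):
            m.fit_weibull_mle(np.array([2.0, 2.0]))
        with pytest.raises(m.DegenerateDataError):
            m.fit_weibull_empirical(np.array([1.0, 1.0]))

    def test_modified_mle_equals_mle_on_empirical_table(self, rng):
        x = stats.weibull_min(2.0, scale=1.0).rvs(400, random_state=rng)
        values, counts = np.unique(x, return_counts=True)
        plain = m.fit_weibull_mle(x)
        tab = m.fit_weibull_modified_mle(values, counts / counts.sum())
        assert abs(tab.alpha - plain.alpha) < 1e-8
        assert abs(tab.beta - plain.beta) < 1e-8

    def test_modified_mle_on_histogram(self, rng):
        x = stats.weibull_min(2.0, scale=1.0).rvs(100_000, random_state=rng)
        counts, edges = np.histogram(x, bins=100)
        centers = 0.5 * (edges[:-1] + edges[1:])
        fam = m.fit_weibull_modified_mle(centers, counts / counts.sum())
        assert abs(fam.alpha - 2.0) / 2.0 < 0.05

    def test_modified_mle_degenerate_tables(self):
        with pytest.raises(m.DegenerateDataError):
            m.fit_weibull_modified_mle(np.array([0.0, 1.0]),
                                       np.array([1.0, 0.0]))
        with pytest.raises(m.DegenerateDataError):
            m.fit_weibull_modified_mle(np.array([0.0, 1.0]),
                                       np.array([0.5, 0.5]))
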