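"""Likelihood, ICAR prior, MCMC engine and grid-integration oracle."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

import telemap as tm
from telemap.bym_model import (
    GridSpec,
    grid_posterior_oracle,
    log_icar_prior,
    pairwise_difference_sum,
    tau_u_full_conditional,
    tau_v_full_conditional,
)
from telemap.geo_adjacency import AdjacencyMatrix, permute_adjacency


def make_panel(y, E, X=None, names=()):
    X = np.zeros((len(y), 0)) if X is None else np.asarray(X)
    return tm.AreaYearPanel(
        area_ids=[f"a{i}" for i in range(len(y))],
        y=np.asarray(y, dtype=np.int64),
        offset=np.asarray(E, dtype=float),
        X=X,
        covariate_names=tuple(names),
    )


class TestLogLikelihood:
    def test_zero_count_unit_exposure(self):
        panel = make_panel([0], [1])
        # -E exp(0) = -1
        assert tm.log_likelihood(panel, 0.0, [], [0.0], [0.0]) == pytest.approx(-1.0)

    def test_two_count_closed_form(self):
        panel = make_panel([2], [1])
        assert tm.log_likelihood(panel, 0.0, [], [0.0], [0.0]) == pytest.approx(
            -1.0 - math.log(2.0)
        )

    def test_matches_termwise_brute_force(self, rng):
        """Independent reimplementation: python-loop sum with lgamma."""
        n = 5
        y = rng.poisson(5, n)
        E = rng.uniform(1, 50, n)
        X = rng.standard_normal((n, 2))
        beta0, beta = -0.3, np.array([0.2, -0.1])
        u = rng.standard_normal(n) * 0.1
        v = rng.standard_normal(n) * 0.1
        panel = make_panel(y, E, X, ("x1", "x2"))
        expected = 0.0
        for i in range(n):
            eta = beta0 + X[i] @ beta + u[i] + v[i]
            expected += (y[i] * eta + y[i] * math.log(E[i]) - E[i] * math.exp(eta)
                         - math.lgamma(y[i] + 1.0))
        got = tm.log_likelihood(panel, beta0, beta, u, v)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_parameter_rejected(self):
        panel = make_panel([1], [1])
        with pytest.raises(ValueError):
            tm.log_likelihood(panel, np.nan, [], [0.0], [0.0])


class TestIcarPrior:
    def test_zero_field_leaves_only_log_tau_term(self, adjacency_3x3):
        val = log_icar_prior(np.zeros(9), 2.5, adjacency_3x3)
        assert val == pytest.approx((9 - 1) / 2 * math.log(2.5))

    def test_two_node_closed_form(self):
        adj = AdjacencyMatrix.from_pairs(2, [(0, 1)])
        # one pair, difference 2 -> -(1/2)*4 = -2; (n-c)/2 log 1 = 0
        assert log_icar_prior(np.array([1.0, -1.0]), 1.0, adj) == pytest.approx(-2.0)

    def test_pairwise_sum_matches_double_loop(self, adjacency_3x3, rng):
        u = rng.standard_normal(9)
        u -= u.mean()
        expected = 0.0
        done = set()
        for i, j in adjacency_3x3.pairs:
            assert (i, j) not in done
            done.add((i, j))
            expected += (u[i] - u[j]) ** 2
        assert pairwise_difference_sum(u, adjacency_3x3) == pytest.approx(expected)
        got = log_icar_prior(u, 3.0, adjacency_3x3)
        assert got == pytest.approx(4 * math.log(3.0) - 1.5 * expected)

    def test_constraint_violation_rejected(self, adjacency_3x3):
        with pytest.raises(ValueError, match="sum-to-zero"):
            log_icar_prior(np.ones(9), 1.0, adjacency_3x3)


class TestConjugateUpdates:
    def test_tau_u_full_conditional_hand_computed(self):
        adj = AdjacencyMatrix.from_pairs(3, [(0, 1), (1, 2)])
        u = np.array([0.5, 0.0, -0.5])
        priors = tm.Priors(tau_shape=1.0, tau_rate=0.0005)
        shape, rate = tau_u_full_conditional(u, adj, priors, n_components=1)
        # n - c = 2; pairwise sum = 0.25 + 0.25 = 0.5
        assert shape == pytest.approx(1.0 + 1.0)
        assert rate == pytest.approx(0.0005 + 0.25)

    def test_tau_v_full_conditional_hand_computed(self):
        priors = tm.Priors(tau_shape=2.0, tau_rate=1.0)
        shape, rate = tau_v_full_conditional(np.array([1.0, -2.0, 0.5]), priors)
        assert shape == pytest.approx(2.0 + 1.5)
        assert rate == pytest.approx(1.0 + (1 + 4 + 0.25) / 2)


class TestFitBymPoisson:
    def test_fixed_seed_bit_identical(self, small_panel_and_adjacency):
        panel, adjacency = small_panel_and_adjacency
        spec = tm.ModelSpec(("x1", "x2"), True, True)
        mcmc = tm.McmcConfig(n_iterations=600, n_burnin=200, seed=9)
        s1 = tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(), mcmc)
        s2 = tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(), mcmc)
        assert np.array_equal(s1.beta0, s2.beta0)
        assert np.array_equal(s1.beta, s2.beta)
        assert np.array_equal(s1.u, s2.u)
        assert np.array_equal(s1.v, s2.v)
        assert np.array_equal(s1.tau_u, s2.tau_u)
        assert np.array_equal(s1.log_likelihood, s2.log_likelihood)

    def test_u_draws_satisfy_sum_to_zero(self, small_samples):
        assert np.max(np.abs(small_samples.u.sum(axis=1))) < 1e-8

    def test_tau_draws_positive_and_nan_when_disabled(self, small_panel_and_adjacency):
        panel, adjacency = small_panel_and_adjacency
        spec = tm.ModelSpec(("x1",), include_structured=False,
                            include_unstructured=True)
        s = tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(),
                               tm.McmcConfig(n_iterations=400, n_burnin=100, seed=2))
        assert np.all(np.isnan(s.tau_u))
        assert np.all(s.tau_v > 0)
        assert np.all(s.u == 0)

    def test_draw_count_respects_thinning(self, small_panel_and_adjacency):
        panel, adjacency = small_panel_and_adjacency
        spec = tm.ModelSpec((), True, True)
        s = tm.fit_bym_poisson(
            panel, adjacency, spec, tm.Priors(),
            tm.McmcConfig(n_iterations=1000, n_burnin=400, thin=3, seed=0))
        assert s.n_draws == 200

    def test_area_set_mismatch_rejected(self, small_panel_and_adjacency):
        panel, _ = small_panel_and_adjacency
        wrong = AdjacencyMatrix.from_pairs(4, [(0, 1)])
        with pytest.raises(ValueError, match="areas"):
            tm.fit_bym_poisson(panel, wrong, tm.ModelSpec((), True, True))

    def test_all_zero_outcomes_warn_not_fail(self):
        panel = make_panel([0, 0, 0, 0], [10, 10, 10, 10])
        adj = AdjacencyMatrix.from_pairs(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.warns(UserWarning, match="zero"):
            s = tm.fit_bym_poisson(
                panel, adj, tm.ModelSpec((), True, True), tm.Priors(),
                tm.McmcConfig(n_iterations=300, n_burnin=100, seed=0))
        assert np.all(np.isfinite(s.beta0))

    def test_matches_glm_when_random_effects_disabled(self):
        """No random effects + vague priors: the posterior centre agrees
        with the maximum-likelihood Poisson GLM fit."""
        import statsmodels.api as sm

        lattice = tm.generate_grid_lattice(20, 20, seed=21)
        cfg = tm.SimulationConfig(seed=21, tau_u=1e12, tau_v=1e12)
        adjacency = tm.queen_adjacency(lattice)
        panel = tm.simulate_area_panel(lattice, cfg, ["x1", "x2"],
                                       adjacency=adjacency)
        spec = tm.ModelSpec(("x1", "x2"), include_structured=False,
                            include_unstructured=False)
        s = tm.fit_bym_poisson(
            panel, adjacency, spec, tm.Priors(beta_prec=1e-8),
            tm.McmcConfig(n_iterations=12_000, n_burnin=3_000, seed=1))
        glm = sm.GLM(panel.y, sm.add_constant(panel.X),
                     family=sm.families.Poisson(),
                     offset=np.log(panel.offset)).fit()
        assert s.beta0.mean() == pytest.approx(glm.params[0], abs=0.01)
        assert np.allclose(s.beta.mean(axis=0), glm.params[1:], atol=0.01)

    def test_exchangeability_under_relabeling(self):
        """Permuting area order (panel + adjacency together) leaves scalar
        posterior summaries unchanged up to Monte-Carlo error."""
        lattice = tm.generate_grid_lattice(10, 10, seed=13)
        cfg = tm.SimulationConfig(n_rows=10, n_cols=10, seed=13)
        adjacency = tm.queen_adjacency(lattice)
        panel = tm.simulate_area_panel(lattice, cfg, ["x1", "x2"],
                                       adjacency=adjacency)
        perm = np.random.default_rng(2).permutation(100)
        inv = np.argsort(perm)
        panel_p = tm.AreaYearPanel(
            area_ids=[panel.area_ids[i] for i in inv],
            y=panel.y[inv], offset=panel.offset[inv], X=panel.X[inv],
            covariate_names=panel.covariate_names)
        adj_p = permute_adjacency(adjacency, perm.tolist())
        spec = tm.ModelSpec(("x1", "x2"), True, True)
        mcmc = tm.McmcConfig(n_iterations=15_000, n_burnin=5_000, seed=3)
        s1 = tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(), mcmc)
        s2 = tm.fit_bym_poisson(panel_p, adj_p, spec, tm.Priors(), mcmc)
        assert np.allclose(s1.beta.mean(axis=0), s2.beta.mean(axis=0), atol=0.04)
        assert s1.beta0.mean() == pytest.approx(s2.beta0.mean(), abs=0.05)


class TestGridOracle:
    def test_single_area_matches_1d_quadrature(self):
        """Poisson-lognormal posterior for one area: the grid oracle agrees
        with adaptive 1-D quadrature to 1e-4."""
        panel = make_panel([3], [1])
        adj = AdjacencyMatrix(1, ())
        spec = tm.ModelSpec((), include_structured=False,
                            include_unstructured=False)
        priors = tm.Priors(beta_prec=1.0)
        grid = GridSpec(axes={"beta0": (-6.0, 5.0, 2001)})
        oracle = grid_posterior_oracle(panel, adj, spec, priors, grid)

        def unnorm(b0):
            return np.exp(3 * b0 - np.exp(b0) - 0.5 * b0 ** 2)

        z, _ = integrate.quad(unnorm, -10, 8)
        m, _ = integrate.quad(lambda b: b * unnorm(b), -10, 8)
        assert oracle.means["beta0"] == pytest.approx(m / z, abs=1e-4)

    def test_symmetric_two_area_panel_centres_u_at_zero(self):
        panel = make_panel([5, 5], [50, 50])
        adj = AdjacencyMatrix.from_pairs(2, [(0, 1)])
        spec = tm.ModelSpec((), include_structured=True,
                            include_unstructured=False)
        priors = tm.Priors(beta_prec=0.01, tau_shape=2.0, tau_rate=1.0)
        grid = GridSpec(axes={
            "beta0": (-4.6, -0.4, 85),
            "w0": (-2.0, 2.0, 81),
            "tau_u": (0.0005, 60.0, 121),
        })
        oracle = grid_posterior_oracle(panel, adj, spec, priors, grid)
        assert oracle.u_mean[0] == pytest.approx(0.0, abs=1e-10)
        assert oracle.u_mean[1] == pytest.approx(0.0, abs=1e-10)

    def test_grid_refinement_self_consistency(self):
        panel = make_panel([4, 7], [40, 60])
        adj = AdjacencyMatrix.from_pairs(2, [(0, 1)])
        spec = tm.ModelSpec((), include_structured=True,
                            include_unstructured=False)
        priors = tm.Priors(beta_prec=0.01, tau_shape=2.0, tau_rate=1.0)

        def run(npts):
            grid = GridSpec(axes={
                "beta0": (-4.5, -0.9, npts),
                "w0": (-2.2, 2.2, npts),
                "tau_u": (0.0005, 60.0, npts + 40),
            })
            return grid_posterior_oracle(panel, adj, spec, priors, grid)

        coarse, fine = run(61), run(122)
        assert abs(coarse.means["beta0"] - fine.means["beta0"]) < 1e-3
        assert abs(coarse.means["w0"] - fine.means["w0"]) < 1e-3

    def test_too_many_parameters_rejected(self):
        panel = make_panel([1, 2, 3], [10, 10, 10])
        adj = AdjacencyMatrix.from_pairs(3, [(0, 1), (1, 2)])
        spec = tm.ModelSpec((), include_structured=True,
                            include_unstructured=True)  # 3 + v's + taus > 4
        with pytest.raises(ValueError, match="at most 4"):
            grid_posterior_oracle(
                panel, adj, spec, tm.Priors(),
                GridSpec(axes={}))

    def test_truncating_grid_warns(self):
        panel = make_panel([3], [1])
        adj = AdjacencyMatrix(1, ())
        spec = tm.ModelSpec((), False, False)
        grid = GridSpec(axes={"beta0": (0.5, 2.0, 101)})  # posterior mode ~1.1, cut off
        with pytest.warns(UserWarning, match="boundary"):
            grid_posterior_oracle(panel, adj, spec, tm.Priors(beta_prec=1.0), grid)
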