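"""Solver contracts: proximal operators, penalty, KKT, paths, reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costdrivers import sgl

from _oracles import lasso_cd_oracle, sgl_objective, sgl_prox_gradient_oracle
from conftest import design_from_matrix, random_grouped_instance


class TestProximalOperators:
    def test_soft_threshold_examples(self):
        assert sgl.soft_threshold(np.array([0.5]), 1.0) == pytest.approx([0.0])
        assert np.allclose(sgl.soft_threshold(np.array([2.0, -2.0]), 0.5), [1.5, -1.5])
        z = np.array([0.3, -1.2, 0.0])
        assert np.array_equal(sgl.soft_threshold(z, 0.0), z)
        with pytest.raises(ValueError):
            sgl.soft_threshold(z, -0.1)

    def test_group_prox_examples(self):
        assert np.allclose(sgl.group_prox(np.zeros(3), 5.0), 0.0)
        assert np.allclose(sgl.group_prox(np.array([3.0, 4.0]), 2.5), [1.5, 2.0])
        assert np.allclose(sgl.group_prox(np.array([3.0, 4.0]), 6.0), 0.0)
        with pytest.raises(ValueError):
            sgl.group_prox(np.ones(2), -1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6),
           st.floats(0, 10))
    def test_prox_operators_shrink(self, zs, t):
        z = np.array(zs)
        st_out = sgl.soft_threshold(z, t)
        gp_out = sgl.group_prox(z, t)
        assert np.all(np.abs(st_out) <= np.abs(z) + 1e-12)
        assert np.linalg.norm(gp_out) <= np.linalg.norm(z) + 1e-12


class TestPenaltyValue:
    def test_limits_and_printed_optimum_arithmetic(self):
        groups = {"g": np.array([0, 1])}
        b = np.array([3.0, 4.0])
        assert sgl.penalty_value(np.zeros(2), groups, sgl.PenaltyConfig(1.0, 0.5)) == 0.0
        assert sgl.penalty_value(b, groups, sgl.PenaltyConfig(1.0, 0.0)) == pytest.approx(5.0)
        assert sgl.penalty_value(b, groups, sgl.PenaltyConfig(1.0, 1.0)) == pytest.approx(7.0)
        # mixed penalty at a strong-grouping setting:
        # 0.646 * (0.85 * 5 + 0.15 * 7) = 0.646 * 5.3
        val = sgl.penalty_value(b, groups, sgl.PenaltyConfig(0.646, 0.15))
        assert val == pytest.approx(0.646 * 5.3, abs=1e-12)

    def test_malformed_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            sgl.penalty_value(np.ones(3), {"g": np.array([0, 1])},
                              sgl.PenaltyConfig(1.0, 0.5))


class TestFitReductions:
    def test_lambda_zero_matches_normal_equations(self, rng):
        design, y = random_grouped_instance(rng)
        fit = sgl.fit(design, y, sgl.PenaltyConfig(0.0, 0.5), tol=1e-10)
        yc = y - y.mean()
        oracle = np.linalg.solve(design.matrix.T @ design.matrix,
                                 design.matrix.T @ yc)
        assert np.allclose(fit.beta, oracle, rtol=1e-6, atol=1e-8)

    def test_lambda_at_or_above_lambda_max_gives_zero(self, rng):
        for alpha in (0.0, 0.15, 1.0):
            design, y = random_grouped_instance(rng)
            lmax = sgl.lambda_max(design, y, alpha)
            for lam in (lmax, 1.01 * lmax):
                fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, alpha), tol=1e-10)
                assert np.all(fit.beta == 0.0)
                assert sgl.kkt_check(fit, design, y) <= 1e-10

    def test_alpha_one_matches_independent_lasso_cd(self, rng):
        design, y = random_grouped_instance(rng, n_rows=60)
        X = design.matrix
        yc = y - y.mean()
        lam = 0.3 * sgl.lambda_max(design, y, 1.0)
        fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, 1.0), tol=1e-12)
        oracle = lasso_cd_oracle(X, yc, lam)
        groups = [np.asarray(i) for i in design.groups.values()]
        f_mine = sgl_objective(X, yc, fit.beta, groups, lam, 1.0)
        f_orc = sgl_objective(X, yc, oracle, groups, lam, 1.0)
        assert abs(f_mine - f_orc) <= 1e-8
        assert np.allclose(fit.beta, oracle, atol=1e-6)

    def test_scaling_covariance(self, rng):
        design, y = random_grouped_instance(rng)
        lam = 0.2 * sgl.lambda_max(design, y, 0.15)
        f1 = sgl.fit(design, y, sgl.PenaltyConfig(lam, 0.15), tol=1e-11)
        c = 7.5
        f2 = sgl.fit(design, c * y, sgl.PenaltyConfig(c * lam, 0.15), tol=1e-11)
        assert np.allclose(f2.beta, c * f1.beta, rtol=1e-6, atol=1e-9)


class TestObjectiveAndKKT:
    def test_objective_never_increases_across_sweeps(self, rng):
        design, y = random_grouped_instance(rng, n_rows=80)
        lam = 0.1 * sgl.lambda_max(design, y, 0.15)
        fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, 0.15), tol=1e-10)
        diffs = np.diff(fit.objective_path)
        assert np.all(diffs <= 1e-10 * max(1.0, abs(fit.objective_path[0])))

    def test_converged_fit_satisfies_kkt(self, rng):
        design, y = random_grouped_instance(rng)
        lam = 0.2 * sgl.lambda_max(design, y, 0.15)
        fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, 0.15), tol=1e-9)
        assert fit.converged
        assert sgl.kkt_check(fit, design, y) <= 1e-4

    def test_perturbed_solution_violates_kkt(self, rng):
        design, y = random_grouped_instance(rng)
        lam = 0.2 * sgl.lambda_max(design, y, 0.15)
        fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, 0.15), tol=1e-9)
        active = np.flatnonzero(fit.beta)
        assert len(active)
        sd = float((y - y.mean()).std(ddof=0))
        fit.beta[active[0]] += 0.1 * sd  # 0.1 on the unit-outcome scale
        assert sgl.kkt_check(fit, design, y) > 1e-3

    def test_nonfinite_inputs_rejected(self, rng):
        design, y = random_grouped_instance(rng)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            sgl.fit(design, y, sgl.PenaltyConfig(0.1, 0.5))


class TestLambdaMax:
    def test_closed_forms(self, rng):
        X = rng.standard_normal((50, 1))
        X -= X.mean(); X /= X.std(ddof=0)
        y = rng.standard_normal(50)
        d = design_from_matrix(X, [1], standardized=True)
        yc = y - y.mean()
        c = float(X[:, 0] @ yc / 50)
        assert sgl.lambda_max(d, y, 1.0) == pytest.approx(abs(c))
        d3, y3 = random_grouped_instance(rng, max_groups=2, min_groups=2)
        norms = [np.linalg.norm(d3.matrix[:, i].T @ (y3 - y3.mean()) / len(y3))
                 for i in d3.groups.values()]
        assert sgl.lambda_max(d3, y3, 0.0) == pytest.approx(max(norms))

    def test_bracketing_against_the_fitter(self, rng):
        design, y = random_grouped_instance(rng, min_groups=3, max_groups=3)
        lmax = sgl.lambda_max(design, y, 0.15)
        hi = sgl.fit(design, y, sgl.PenaltyConfig(1.001 * lmax, 0.15), tol=1e-10)
        lo = sgl.fit(design, y, sgl.PenaltyConfig(0.999 * lmax, 0.15), tol=1e-10)
        assert np.all(hi.beta == 0.0)
        assert np.any(lo.beta != 0.0)

    def test_constant_outcome_rejected(self, rng):
        design, _ = random_grouped_instance(rng)
        with pytest.raises(ValueError, match="constant"):
            sgl.lambda_max(design, np.ones(design.matrix.shape[0]), 0.5)


class TestPath:
    def test_single_point_above_lambda_max_is_null(self, rng):
        design, y = random_grouped_instance(rng)
        lmax = sgl.lambda_max(design, y, 0.15)
        fits = sgl.fit_path(design, y, 0.15, [1.01 * lmax])
        assert np.all(fits[0].beta == 0.0)

    def test_support_monotone_and_endpoints(self, rng):
        design, y = random_grouped_instance(rng, n_rows=100)
        lmax = sgl.lambda_max(design, y, 0.15)
        grid = np.geomspace(lmax * 1.05, lmax * 1e-4, 25)
        fits = sgl.fit_path(design, y, 0.15, grid, tol=1e-9)
        counts = [len(f.active_groups) for f in fits]
        assert counts == sorted(counts)  # non-decreasing as lambda falls
        assert counts[0] == 0
        yc = y - y.mean()
        ols = np.linalg.solve(design.matrix.T @ design.matrix,
                              design.matrix.T @ yc)
        assert np.allclose(fits[-1].beta, ols, rtol=1e-2, atol=1e-3)

    def test_empty_and_unsorted_grids_rejected(self, rng):
        design, y = random_grouped_instance(rng)
        with pytest.raises(ValueError, match="empty"):
            sgl.fit_path(design, y, 0.5, [])
        with pytest.raises(ValueError, match="decreasing"):
            sgl.fit_path(design, y, 0.5, [0.1, 0.5])


def test_oracle_equivalence_small_grid(rng):
    """Blockwise solver vs the independent full-vector proximal oracle."""
    for _ in range(5):
        design, y = random_grouped_instance(rng)
        yc = y - y.mean()
        groups = [np.asarray(i) for i in design.groups.values()]
        for lam, alpha in [(0.1, 0.15), (0.1, 1.0), (1.0, 0.0), (1.0, 0.5)]:
            fit = sgl.fit(design, y, sgl.PenaltyConfig(lam, alpha), tol=1e-12)
            b_orc = sgl_prox_gradient_oracle(design.matrix, yc, groups, lam, alpha)
            f_mine = sgl_objective(design.matrix, yc, fit.beta, groups, lam, alpha)
            f_orc = sgl_objective(design.matrix, yc, b_orc, groups, lam, alpha)
            assert abs(f_mine - f_orc) <= 1e-8
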