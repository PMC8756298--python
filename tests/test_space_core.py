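import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacelog import (
    CoordinateState,
    PenaltySpec,
    SpaceFit,
    active_shooting,
    beta_to_rho,
    compute_partial_residual,
    fit_space,
    lambda_max,
    log_penalty_derivative,
    objective_value,
    soft_threshold_update,
    update_sigma,
    update_weights,
)

from _oracles import grid_minimize_coordinate, prox_grad_space, space_objective
from conftest import random_gaussian_matrix


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,V,thr,expected",
        [
            (0.5, 1.0, 0.6, 0.0),
            (0.5, 1.0, 0.2, 0.3),
            (-0.5, 2.0, 0.4, -0.3),
            (0.0, 1.0, 0.1, 0.0),
        ],
    )
    def test_examples(self, z, V, thr, expected):
        got = soft_threshold_update(CoordinateState(z=z, V=V, threshold=thr))
        assert got == pytest.approx(expected)

    @settings(deadline=None, max_examples=60)
    @given(
        z=st.floats(-2, 2),
        V=st.floats(0.1, 10),
        thr=st.floats(0, 5),
    )
    def test_shrinks_and_matches_grid_minimum(self, z, V, thr):
        got = soft_threshold_update(CoordinateState(z=z, V=V, threshold=thr))
        assert abs(got) <= abs(z) + 1e-12
        brute = grid_minimize_coordinate(z, V, thr, n_points=4001)
        assert abs(got - brute) <= max(2 * abs(z) / 4000, 1e-12)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            CoordinateState(z=1.0, V=0.0, threshold=0.1)


class TestLogPenaltyDerivative:
    def test_examples(self):
        assert log_penalty_derivative(0.5, 1.0, 0.5) == pytest.approx(1.0)
        assert log_penalty_derivative(0.0, 2.0, 0.1) == pytest.approx(20.0)

    def test_decreasing_in_rho_and_vanishing(self):
        vals = [log_penalty_derivative(r, 1.0, 0.1) for r in (0, 0.5, 2.0, 100.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            log_penalty_derivative(0.1, 1.0, 0.0)


class TestBetaToRho:
    @pytest.mark.parametrize(
        "bij,bji,expected",
        [(0.2, 0.8, 0.4), (0.0, 0.5, 0.0), (-0.3, -0.3, -0.3)],
    )
    def test_examples(self, bij, bji, expected):
        assert beta_to_rho(bij, bji) == pytest.approx(expected)

    def test_sign_conflict_returns_zero(self):
        assert beta_to_rho(0.3, -0.2) == 0.0


class TestPartialResidual:
    def test_zero_rho_gives_scaled_correlation(self, rng):
        n, m = 500, 4
        Y = rng.standard_normal((n, m))
        Y = (Y - Y.mean(0)) / Y.std(0)
        state = compute_partial_residual(
            Y, np.zeros((m, m)), np.ones(m), 0, 1
        )
        r = np.corrcoef((Y - Y.mean(0)).T)[0, 1]
        # with d=1, w=1: z = 2<Y_0,Y_1>/(|Y_0|^2+|Y_1|^2) ~= correlation
        assert state.z == pytest.approx(r, abs=1e-6)

    def test_constant_column_rejected(self, rng):
        Y = rng.standard_normal((50, 3))
        Y[:, 2] = 1.0
        with pytest.raises(ValueError):
            compute_partial_residual(Y, np.zeros((3, 3)), np.ones(3), 0, 1)

    def test_recovers_truth_on_single_edge_data(self):
        prec = np.array([[1.0, -0.4], [-0.4, 1.0]])
        from spacelog import precision_to_partial_correlation, sample_expression

        true_rho = precision_to_partial_correlation(prec)[0, 1]
        Y = sample_expression(prec, 10**4, seed=5).to_numpy()
        d = np.diag(prec)
        state = compute_partial_residual(Y, np.zeros((2, 2)), d, 0, 1)
        assert state.z == pytest.approx(true_rho, abs=0.03)


def _fixed_sigma_setup(Y):
    n, m = Y.shape
    Yc = Y - Y.mean(0)
    d0 = n / np.einsum("ij,ij->j", Yc, Yc)
    return Yc, d0, np.ones(m)


class TestActiveShooting:
    def test_empty_model_above_lambda_max_in_one_sweep(self, rng):
        Y = random_gaussian_matrix(rng, 60, 6)
        lam = lambda_max(Y) * 1.0001
        fit = fit_space(Y, PenaltySpec("lasso", lam))
        assert np.count_nonzero(fit.rho) == 0

    def test_matches_proximal_gradient_oracle(self, rng):
        Y = random_gaussian_matrix(rng, 50, 4)
        Yc, d0, w = _fixed_sigma_setup(Y)
        lam = 0.2 * lambda_max(Yc)
        fit = fit_space(Yc, PenaltySpec("lasso", lam), n_sigma_updates=1, tol=1e-10)
        pen = np.full((4, 4), 2 * lam)
        oracle_rho = prox_grad_space(Yc, d0, w, pen)
        f_impl = space_objective(Yc, fit.rho, d0, w, pen)
        f_oracle = space_objective(Yc, oracle_rho, d0, w, pen)
        assert f_impl <= f_oracle * (1 + 1e-4) + 1e-10

    def test_oracle_solution_is_fixed_point(self, rng):
        Y = random_gaussian_matrix(rng, 50, 4)
        Yc, d0, w = _fixed_sigma_setup(Y)
        lam = 0.2 * lambda_max(Yc)
        pen = np.full((4, 4), 2 * lam)
        oracle_rho = prox_grad_space(Yc, d0, w, pen)
        init = SpaceFit(
            rho=oracle_rho, sigma_inv_diag=d0, weights=w,
            penalty=PenaltySpec("lasso", lam),
        )
        refit = active_shooting(Yc, pen, w, init, tol=1e-8)
        assert np.max(np.abs(refit.rho - oracle_rho)) < 1e-5


class TestFitSpace:
    def test_rho_exactly_symmetric_zero_diagonal(self, rng):
        Y = random_gaussian_matrix(rng, 80, 8)
        fit = fit_space(Y, PenaltySpec("lasso", 0.1 * lambda_max(Y)))
        assert np.array_equal(fit.rho, fit.rho.T)
        assert np.all(np.diag(fit.rho) == 0)
        assert np.all(np.abs(fit.rho) < 1)
        assert np.all(fit.sigma_inv_diag > 0)

    def test_log_with_huge_tau_matches_lasso(self, rng):
        Y = random_gaussian_matrix(rng, 60, 6)
        lam0 = 0.15 * lambda_max(Y)
        tau = 1e6
        lasso = fit_space(Y, PenaltySpec("lasso", lam0), n_sigma_updates=1, tol=1e-9)
        log = fit_space(
            Y, PenaltySpec("log", lam0 * tau, tau), n_sigma_updates=1, tol=1e-9
        )
        np.testing.assert_allclose(log.rho, lasso.rho, atol=1e-4)

    def test_lla_objective_non_increasing(self, rng):
        for _ in range(5):
            Y = random_gaussian_matrix(rng, 50, 6)
            lam = 0.1 * lambda_max(Y)
            fit = fit_space(Y, PenaltySpec("log", lam, 0.01), n_lla=5)
            trace = fit.objective_trace
            assert all(
                b <= a + 1e-9 * max(1.0, abs(a)) for a, b in zip(trace, trace[1:])
            )

    def test_sparsity_non_increasing_in_lambda(self, rng):
        Y = random_gaussian_matrix(rng, 60, 8)
        lmax = lambda_max(Y)
        sizes = []
        for lam in np.geomspace(lmax, 0.01 * lmax, 12):
            fit = fit_space(Y, PenaltySpec("lasso", lam), n_sigma_updates=1)
            sizes.append(len(fit.edges()))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_warm_start_equals_cold_start(self, rng):
        Y = random_gaussian_matrix(rng, 60, 6)
        lmax = lambda_max(Y)
        warm = None
        for lam in np.geomspace(lmax, 0.05 * lmax, 8):
            cold = fit_space(Y, PenaltySpec("lasso", lam), tol=1e-9)
            warm_fit = fit_space(
                Y, PenaltySpec("lasso", lam), tol=1e-9, rho_init=warm
            )
            np.testing.assert_allclose(warm_fit.rho, cold.rho, atol=1e-6)
            warm = warm_fit.rho

    def test_rejects_bad_input(self, rng):
        with pytest.raises(ValueError):
            fit_space(np.ones((10, 1)), PenaltySpec("lasso", 1.0))
        Y = rng.standard_normal((10, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_space(Y, PenaltySpec("lasso", 1.0))


class TestSigmaAndWeights:
    def test_sigma_with_zero_rho_is_inverse_variance(self, rng):
        Y = rng.standard_normal((2000, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        d = update_sigma(Y, np.zeros((4, 4)))
        Yc = Y - Y.mean(0)
        np.testing.assert_allclose(d, 1 / (Yc**2).mean(0), rtol=1e-10)

    def test_sigma_floor_on_perfect_fit(self):
        # gene 1 = exact multiple of gene 0: residual variance collapses
        rng = np.random.default_rng(0)
        y0 = rng.standard_normal(100)
        Y = np.column_stack([y0, 2 * y0])
        rho = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = np.array([1.0, 0.25])  # makes sqrt(d1/d0)*2 reproduce Y0 exactly
        out = update_sigma(Y, rho, d)
        assert np.all(np.isfinite(out)) and np.all(out > 0)

    def test_sigma_consistency_on_true_model(self):
        from spacelog import graph_to_precision, simulate_ba_graph, sample_expression
        from spacelog import precision_to_partial_correlation

        g = simulate_ba_graph(6, 1, seed=2)
        prec = graph_to_precision(g, seed=2)
        Y = sample_expression(prec, 10**4, seed=3).to_numpy()
        rho = precision_to_partial_correlation(prec)
        d_hat = update_sigma(Y, rho, np.diag(prec))
        np.testing.assert_allclose(d_hat, np.diag(prec), rtol=0.05)

    def test_weight_schemes(self):
        d = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        rho = np.zeros((6, 6))
        np.testing.assert_array_equal(update_weights("uniform", d, rho), np.ones(6))
        np.testing.assert_array_equal(update_weights("residual", d, rho), d)
        np.testing.assert_array_equal(update_weights("degree", d, rho), np.ones(6))
        # star: gene 0 connected to all others
        rho[0, 1:] = rho[1:, 0] = 0.2
        w = update_weights("degree", d, rho)
        assert w[0] == 5 and np.all(w[1:] == 1)


class TestObjectiveValue:
    def test_zero_rho_lasso(self, rng):
        Y = rng.standard_normal((40, 5))
        Yc = Y - Y.mean(0)
        m = 5
        fit = SpaceFit(
            rho=np.zeros((m, m)),
            sigma_inv_diag=np.ones(m),
            weights=np.ones(m),
            penalty=PenaltySpec("lasso", 3.0),
        )
        assert objective_value(Y, fit) == pytest.approx(0.5 * np.sum(Yc**2))

    def test_zero_rho_log_penalty_constant(self, rng):
        Y = rng.standard_normal((40, 5))
        Yc = Y - Y.mean(0)
        m, lam, tau = 5, 2.0, 0.1
        fit = SpaceFit(
            rho=np.zeros((m, m)),
            sigma_inv_diag=np.ones(m),
            weights=np.ones(m),
            penalty=PenaltySpec("log", lam, tau),
        )
        expected = 0.5 * np.sum(Yc**2) + lam * m * (m - 1) * np.log(tau)
        assert objective_value(Y, fit) == pytest.approx(expected)
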