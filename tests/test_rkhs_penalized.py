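import numpy as np
import pytest
from scipy import optimize

from gradmatch import FHN, PTP, NoiseSpec, generate, regime_dataset
from gradmatch.rkhs_penalized import (RKHSProblem, build_D,
                                      fit, fit_surrogate, penalized_loglik,
                                      penalty_omega, select_lambda_aic,
                                      select_lambda_cv, solve_xtilde,
                                      transform, untransform)
from gradmatch.synthetic_data import FHN_THETA, FHN_X0


class TestBuildD:
    def test_printed_worked_example(self, rng):
        # grid t = (3,4,5,6,7): rows are the printed difference quotients
        d = build_D(np.array([3.0, 4, 5, 6, 7]))
        for _ in range(5):
            x = rng.standard_normal(5)
            expect = np.array([(x[1] - x[0]) / 1, (x[2] - x[0]) / 2,
                               (x[3] - x[1]) / 2, (x[4] - x[2]) / 2,
                               (x[4] - x[3]) / 1])
            np.testing.assert_allclose(d.D @ x, expect, atol=1e-14)

    def test_constant_annihilated(self):
        d = build_D(np.array([0.0, 0.5, 1.7, 2.0, 4.0, 4.5]))
        np.testing.assert_allclose(d.D @ np.ones(6), 0.0, atol=1e-14)

    def test_first_order_exactness_on_irregular_grid(self):
        t = np.array([0.0, 1.0, 2.5, 2.9, 5.0, 8.0, 9.5])
        d = build_D(t)
        np.testing.assert_allclose(d.D @ t, np.ones(len(t)), atol=1e-12)

    def test_repeated_timepoints_rejected(self):
        with pytest.raises(ValueError):
            build_D(np.array([0.0, 1.0, 1.0, 2.0]))


def _problem(T=8, delta=0.4, sigma2=0.09, lam=0.5, seed=0):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 5, T))
    diff = build_D(t)
    return RKHSProblem.build(diff, delta, sigma2, lam), rng


class TestTransforms:
    def test_homogeneous_case_identity(self):
        p, rng = _problem()
        y = rng.standard_normal(8)
        np.testing.assert_allclose(transform(p, y, np.zeros(8)), y)

    def test_round_trip(self):
        p, rng = _problem(seed=1)
        x = rng.standard_normal(8)
        g = rng.standard_normal(8)
        np.testing.assert_allclose(untransform(p, transform(p, x, g), g), x,
                                   atol=1e-10)

    def test_defining_identity_of_the_transform(self):
        # ||R xtilde||^2 == ||R x - g||^2
        for seed in range(5):
            p, rng = _problem(seed=seed)
            x = rng.standard_normal(8)
            g = rng.standard_normal(8)
            lhs = np.linalg.norm(p.R @ transform(p, x, g)) ** 2
            rhs = np.linalg.norm(p.R @ x - g) ** 2
            assert lhs == pytest.approx(rhs, abs=1e-10)


class TestPenalty:
    def test_zero_vector(self):
        p, _ = _problem()
        assert penalty_omega(p, np.zeros(8)) == 0.0

    def test_quadratic_scaling(self):
        p, rng = _problem(seed=2)
        x = rng.standard_normal(8)
        assert penalty_omega(p, 2 * x) == pytest.approx(4 * penalty_omega(p, x))

    def test_two_route_computation(self):
        p, rng = _problem(seed=3)
        x = rng.standard_normal(8)
        direct = np.linalg.norm(p.R @ x) ** 2
        c = np.linalg.solve(p.K, x)
        via_kernel = float(c @ p.K @ c)
        assert penalty_omega(p, x) == pytest.approx(direct, rel=1e-10)
        assert penalty_omega(p, x) == pytest.approx(via_kernel, rel=1e-8)


class TestRidgeSolution:
    def test_lambda_zero_identity(self):
        p, rng = _problem(lam=0.0)
        y = rng.standard_normal(8)
        np.testing.assert_allclose(solve_xtilde(p, y), y, atol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self):
        p, rng = _problem(lam=1e12, sigma2=1.0)
        y = rng.standard_normal(8)
        assert np.linalg.norm(solve_xtilde(p, y)) < 1e-6 * np.linalg.norm(y)

    def test_matches_quadratic_program_minimizer(self):
        """Closed-form ridge vs generic quadratic optimisation on T = 8."""
        p, rng = _problem(seed=4)
        y = rng.standard_normal(8)
        x_closed = solve_xtilde(p, y)
        Sinv = np.linalg.inv(p.Sigma)
        RtR = p.R.T @ p.R

        def objective(x):
            r = y - x
            return 0.5 * r @ Sinv @ r + p.lambda_s * x @ RtR @ x

        res = optimize.minimize(objective, np.zeros(8), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(x_closed, res.x, atol=1e-6)
        assert objective(x_closed) <= objective(res.x) + 1e-8


class TestPenalizedLoglik:
    def test_decreasing_in_lambda(self, fhn_clean_dataset):
        ds = fhn_clean_dataset
        Xhat, _ = fit_surrogate(ds.t, ds.Y)
        s2 = ds.realized_sd**2
        vals = [penalized_loglik(FHN_THETA, FHN, ds.t, ds.Y, Xhat, lam, s2)
                for lam in (0.01, 1.0, 100.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_finite_difference_gradient(self, fhn_clean_dataset):
        ds = fhn_clean_dataset
        Xhat, _ = fit_surrogate(ds.t, ds.Y)
        s2 = ds.realized_sd**2

        def f(theta):
            return penalized_loglik(theta, FHN, ds.t, ds.Y, Xhat, 1.0, s2)

        theta0 = np.array([0.25, 0.3, 2.5])
        g_fd = optimize.approx_fprime(theta0, f, 1e-6)
        g_fd2 = optimize.approx_fprime(theta0, f, 1e-7)
        np.testing.assert_allclose(g_fd, g_fd2, rtol=1e-3)

    def test_reported_objective_recomputable(self, fhn_clean_dataset):
        ds = fhn_clean_dataset
        res = fit(ds, FHN, lam=1.0, n_restarts=2, seed=0)
        Xhat, _ = fit_surrogate(ds.t, ds.Y)
        again = penalized_loglik(res.theta, FHN, ds.t, ds.Y, Xhat, 1.0,
                                 ds.realized_sd**2)
        assert res.objective == pytest.approx(again, rel=1e-12)


class TestFit:
    def test_low_noise_dense_recovery(self):
        ds = generate(FHN, FHN_THETA, FHN_X0, np.linspace(0, 10, 50),
                      NoiseSpec("additive_fixed_sd", 1e-3, seed=3))
        res = fit(ds, FHN, lam=10.0, n_restarts=4, seed=1)
        # alpha and beta recovered tightly; psi with the difference-operator
        # truncation bias of the method
        assert abs(res.theta[0] - 0.2) < 0.05
        assert abs(res.theta[1] - 0.2) < 0.1
        assert abs(res.theta[2] - 3.0) / 3.0 < 0.25

    def test_exact_difference_equation_data_puts_truth_on_top(self):
        """Data constructed to satisfy D x = g - delta x exactly: the
        objective at the generating parameters beats 100 random draws."""
        from gradmatch.ode_models import ODEModel
        from gradmatch.rkhs_penalized import build_D

        # forced linear decay xdot = c - delta x, both parameters positive
        model = ODEModel(
            name="forced", species=("x",), params=("c", "delta"),
            rhs=lambda x, th, t: th[0] - th[1] * np.atleast_2d(x),
            g=lambda x, th, t: np.full_like(np.atleast_2d(x), float(th[0])),
            deltas=lambda th: np.array([th[1]]),
            positive_params=(True, True),
        )
        t = np.linspace(0, 5, 12)
        diff = build_D(t)
        c_true, d_true = 1.5, 0.8
        # solve the *discrete* system (D + delta I) x = c exactly
        x = np.linalg.solve(diff.D + d_true * np.eye(12), np.full(12, c_true))
        Y = x[None, :]
        s2 = np.array([1e-4])
        at_truth = penalized_loglik(np.array([c_true, d_true]), model, t, Y,
                                    Y, 1.0, s2)
        rng = np.random.default_rng(0)
        worse = 0
        for _ in range(100):
            th = rng.uniform(0.1, 3.0, size=2)
            val = penalized_loglik(th, model, t, Y, Y, 1.0, s2)
            if val <= at_truth + 1e-9:
                worse += 1
        assert worse == 100


class TestLambdaSelection:
    def test_single_lambda_grid(self, fhn_clean_dataset):
        lam, res, info = select_lambda_aic(fhn_clean_dataset, FHN,
                                           lambda_grid=np.array([1.0]),
                                           n_restarts=2, seed=0)
        assert lam == 1.0
        lam_cv, _, _ = select_lambda_cv(fhn_clean_dataset, FHN,
                                        lambda_grid=np.array([1.0]),
                                        n_restarts=2, seed=0)
        assert lam_cv == 1.0

    def test_aic_argmin_consistency(self, fhn_clean_dataset):
        grid = np.array([0.1, 1.0, 10.0])
        lam, res, info = select_lambda_aic(fhn_clean_dataset, FHN,
                                           lambda_grid=grid, n_restarts=2,
                                           seed=0)
        assert lam == min(info["aic"], key=info["aic"].get)

    def test_cv_score_is_mean_of_folds(self, fhn_clean_dataset):
        # recompute the selected lambda's CV score independently
        grid = np.array([1.0])
        lam, res, info = select_lambda_cv(fhn_clean_dataset, FHN,
                                          lambda_grid=grid, n_restarts=2,
                                          seed=0)
        assert np.isfinite(info["cv_sse"][lam])

    def test_cv_completes_on_pathway_replicates(self):
        for seed in (201, 202):
            ds = regime_dataset("ptp_snr", seed=seed, snr=10)
            lam, res, info = select_lambda_cv(
                ds, PTP, lambda_grid=np.logspace(-2, 3, 6),
                n_restarts=2, seed=seed)
            assert np.all(np.isfinite(res.theta))
            assert np.all(res.theta >= 0)
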