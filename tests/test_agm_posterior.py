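import numpy as np
import pytest
from scipy import stats

from gradmatch import KernelSpec
from gradmatch.agm_posterior import (ChiSquarePrior, GammaPrior,
                                     InverseGammaPrior, LogNormalPrior,
                                     NormalPrior, default_priors,
                                     log_data_likelihood)
from gradmatch.gp_interpolation import deriv_conditional, kernel_derivative_blocks
from gradmatch.ode_models import ODEModel

LOG2PI = np.log(2 * np.pi)


class TestPriors:
    @pytest.mark.parametrize("prior,ref", [
        (NormalPrior(0.0, 0.4), stats.norm(0, 0.4)),
        (GammaPrior(4.0, 0.5), stats.gamma(4.0, scale=0.5)),
        (ChiSquarePrior(2.0), stats.chi2(2)),
        (InverseGammaPrior(2.0, 1.0), stats.invgamma(2.0, scale=1.0)),
        (LogNormalPrior(0.0, 2.0), stats.lognorm(2.0)),
    ])
    def test_logpdf_matches_scipy(self, prior, ref):
        for x in (0.05, 0.5, 1.7, 4.0):
            assert prior.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-10)

    def test_off_support(self):
        assert GammaPrior(4, 0.5).logpdf(-1.0) == -np.inf
        assert ChiSquarePrior(2).logpdf(0.0) == -np.inf

    def test_fhn_prior_set(self):
        ps = default_priors("fhn")
        assert ps.log_theta(np.array([0.0, 0.0, 1.0])) > -np.inf
        assert ps.log_theta(np.array([0.0, 0.0, -1.0])) == -np.inf

    def test_sampling_matches_density(self, rng):
        ps = default_priors("ptp")
        draws = np.array([ps.sample_theta(rng) for _ in range(4000)])
        # each marginal is Gamma(4, 0.5): check mean/var roughly
        assert np.allclose(draws.mean(axis=0), 2.0, atol=0.15)
        assert np.allclose(draws.var(axis=0), 1.0, atol=0.25)


class TestDataLikelihood:
    def test_zero_residual(self):
        X = np.ones((2, 7))
        sigma2 = np.array([0.25, 0.16])
        expect = -0.5 * 7 * (np.log(sigma2) + LOG2PI).sum()
        assert log_data_likelihood(X, X, sigma2) == pytest.approx(expect)

    def test_single_point_value(self):
        got = log_data_likelihood(np.array([[1.0]]), np.array([[0.0]]),
                                  np.array([1.0]))
        assert got == pytest.approx(-0.5 * LOG2PI - 0.5)

    def test_matches_scipy_normal(self, rng):
        Y = rng.standard_normal((3, 9))
        X = rng.standard_normal((3, 9))
        sigma2 = np.array([0.3, 1.0, 2.5])
        ref = sum(stats.norm(X[s], np.sqrt(sigma2[s])).logpdf(Y[s]).sum()
                  for s in range(3))
        assert log_data_likelihood(Y, X, sigma2) == pytest.approx(ref)

    def test_monotone_in_residual(self):
        X = np.zeros((1, 5))
        s2 = np.array([1.0])
        vals = [log_data_likelihood(X + c, X, s2) for c in (0.0, 0.5, 1.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            log_data_likelihood(np.ones((1, 2)), np.ones((1, 2)),
                                np.array([-1.0]))


def _linear_decay_model():
    return ODEModel(
        name="lin", species=("x",), params=("theta",),
        rhs=lambda x, th, t: -th[0] * np.atleast_2d(x),
        g=lambda x, th, t: np.zeros_like(np.atleast_2d(x)),
        deltas=lambda th: np.array([th[0]]),
        positive_params=(True,),
    )


class TestMarginalAgainstQuadrature:
    """Closed-form derivative marginalisation vs numerical integration.

    On a 3-timepoint, 1-species linear-decay system, the closed form
    N(f | mu, A + gamma I) must agree (up to a theta-independent constant)
    with brute-force quadrature of N(xdot|mu,A) N(xdot|f,gamma I) over xdot.
    """

    def test_theta_differences_match(self):
        t = np.array([0.0, 0.6, 1.3])
        x = np.array([1.0, 0.6, 0.3])
        spec = KernelSpec("rbf", (1.0, 0.8))
        blocks = kernel_derivative_blocks(spec, t, phi=float(x.mean()))
        cond = deriv_conditional(blocks, x)
        gamma = 0.2

        grid_1d = np.linspace(-7, 5, 161)
        G = np.stack(np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij"),
                     axis=-1).reshape(-1, 3)
        dv = (grid_1d[1] - grid_1d[0]) ** 3
        dens_gp = stats.multivariate_normal(cond.mu, cond.A + 1e-9 * np.eye(3)
                                            ).pdf(G)

        def closed_form(theta):
            f = -theta * x
            r = f - cond.mu
            B = cond.A + gamma * np.eye(3)
            return float(-0.5 * r @ np.linalg.solve(B, r)
                         - 0.5 * np.linalg.slogdet(2 * np.pi * B)[1])

        def quadrature(theta):
            f = -theta * x
            dens_ode = stats.multivariate_normal(f, gamma * np.eye(3)).pdf(G)
            return float(np.log(np.sum(dens_gp * dens_ode) * dv))

        thetas = [0.3, 0.8, 1.5, 2.5]
        cf = np.array([closed_form(th) for th in thetas])
        qd = np.array([quadrature(th) for th in thetas])
        # compare differences across theta (any constant offset drops out)
        np.testing.assert_allclose(cf - cf[0], qd - qd[0], atol=1e-4)

    def test_zero_mismatch_when_f_equals_mu(self):
        # residual term vanishes; only the normaliser remains
        t = np.linspace(0, 2, 4)
        spec = KernelSpec("rbf", (1.0, 1.0))
        blocks = kernel_derivative_blocks(spec, t, phi=0.0)
        x = np.zeros(4)
        cond = deriv_conditional(blocks, x)
        np.testing.assert_allclose(cond.mu, 0.0, atol=1e-12)

    def test_large_gamma_flattens_theta_dependence(self):
        t = np.array([0.0, 0.6, 1.3])
        x = np.array([1.0, 0.6, 0.3])
        spec = KernelSpec("rbf", (1.0, 0.8))
        blocks = kernel_derivative_blocks(spec, t, phi=float(x.mean()))
        cond = deriv_conditional(blocks, x)

        def mismatch(theta, gamma):
            f = -theta * x
            r = f - cond.mu
            B = cond.A + gamma * np.eye(3)
            return float(-0.5 * r @ np.linalg.solve(B, r))

        spread_small = np.ptp([mismatch(th, 0.1) for th in (0.3, 1.0, 3.0)])
        spread_large = np.ptp([mismatch(th, 1e6) for th in (0.3, 1.0, 3.0)])
        assert spread_large < 1e-4 * spread_small


class TestLogJoint:
    def _setup(self):
        from gradmatch import FHN, regime_dataset
        from gradmatch.gp_interpolation import (KernelSpec, deriv_conditional,
                                                kernel_derivative_blocks)
        ds = regime_dataset("fhn_cs_20", seed=3)
        specs = [KernelSpec("rbf", (1.5, 0.5)), KernelSpec("rbf", (0.6, 1.5))]
        blocks = [kernel_derivative_blocks(specs[s], ds.t,
                                           phi=float(ds.Y[s].mean()))
                  for s in range(2)]
        X = ds.Y.copy()
        conds = [deriv_conditional(blocks[s], X[s]) for s in range(2)]
        return ds, FHN, blocks, conds, X, specs

    def test_off_support_theta_is_minus_inf(self):
        from gradmatch.agm_posterior import default_priors, log_joint
        ds, model, blocks, conds, X, specs = self._setup()
        val = log_joint(ds.Y, X, np.array([0.0, 0.0, -1.0]), model, blocks,
                        conds, gamma=0.1, sigma2=ds.realized_sd**2,
                        priors=default_priors("fhn"))
        assert val == -np.inf

    def test_equals_sum_of_components(self):
        from gradmatch.agm_posterior import (default_priors, log_joint,
                                             log_data_likelihood,
                                             log_px_marginal)
        ds, model, blocks, conds, X, specs = self._setup()
        priors = default_priors("fhn")
        theta = np.array([0.2, 0.2, 3.0])
        sigma2 = ds.realized_sd**2
        hp = [h for s in specs for h in s.hyperparams]
        total = log_joint(ds.Y, X, theta, model, blocks, conds, gamma=0.1,
                          sigma2=sigma2, priors=priors, eta_values=hp)
        parts = (priors.log_theta(theta)
                 + sum(priors.eta.logpdf(h) for h in hp)
                 + log_data_likelihood(ds.Y, X, sigma2)
                 + log_px_marginal(X, theta, model, blocks, conds, 0.1))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_mismatch_zero_when_f_equals_mu(self):
        # force f == mu by replacing the model gradient with the GP mean
        from gradmatch.agm_posterior import log_mismatch_term
        from gradmatch.ode_models import ODEModel
        ds, model, blocks, conds, X, specs = self._setup()
        mu_all = np.array([c.mu for c in conds])
        fake = ODEModel(name="fake", species=model.species,
                        params=model.params,
                        rhs=lambda x, th, t: mu_all,
                        g=lambda x, th, t: mu_all,
                        deltas=lambda th: np.zeros(2),
                        positive_params=model.positive_params)
        theta = np.array([0.2, 0.2, 3.0])
        with_resid = log_mismatch_term(X, theta, model, conds, 0.1)
        no_resid = log_mismatch_term(X, theta, fake, conds, 0.1)
        assert no_resid > with_resid  # quadratic term contributes 0
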