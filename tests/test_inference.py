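"""Evidence estimation, BIC order selection, heritability, diagnostics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from jointfm import (
    bic_grid,
    geweke_z,
    harmonic_mean_evidence,
    heritability_and_ve,
    mpsrf,
    thermodynamic_integrate,
)
from jointfm.inference import _spectral_var_at_zero
from jointfm.simulate import SimulationDesign, simulate_null_population, simulate_population


class TestThermodynamicIntegration:
    def test_flat_likelihood_gives_unit_evidence(self):
        ladder = np.linspace(0.01, 1, 10)
        logz, se = thermodynamic_integrate(ladder, np.zeros(10))
        assert logz == pytest.approx(0.0, abs=1e-12)

    def test_conjugate_normal_mean_toy(self, rng):
        # y_i ~ N(mu, s0^2), mu ~ N(0, tau^2): evidence in closed form, and
        # the tempered posteriors are conjugate so each rung is sampled iid
        from helpers import normal_mean_ti
        n, s0, tau = 20, 1.0, 2.0
        y = rng.normal(0.7, s0, size=n)
        exact = multivariate_normal.logpdf(
            y, np.zeros(n), s0 ** 2 * np.eye(n) + tau ** 2 * np.ones((n, n)))
        logz, se = normal_mean_ti(y, s0, tau, J=32, S=4000, rng=rng)
        # tolerance: 3 Monte-Carlo SE plus trapezoid discretization slack
        assert logz == pytest.approx(exact, abs=3 * se + 0.1)

    def test_refining_ladder_is_self_consistent(self, rng):
        from helpers import normal_mean_ti
        n, s0, tau = 12, 1.0, 1.5
        y = rng.normal(0.3, s0, size=n)
        a, _ = normal_mean_ti(y, s0, tau, J=16, S=4000, rng=rng)
        b, _ = normal_mean_ti(y, s0, tau, J=32, S=4000, rng=rng)
        assert abs(a - b) < 0.15

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            thermodynamic_integrate([0.5], [1.0])
        with pytest.raises(ValueError):
            thermodynamic_integrate([0.5, 0.5], [1.0, 1.0])

    def test_harmonic_mean_on_conjugate_toy(self, rng):
        # the harmonic mean is biased up, but should land within a few nats
        # on a 1-parameter toy
        n, s0, tau = 20, 1.0, 2.0
        y = rng.normal(0.7, s0, size=n)
        exact = multivariate_normal.logpdf(
            y, np.zeros(n), s0 ** 2 * np.eye(n) + tau ** 2 * np.ones((n, n)))
        prec = n / s0 ** 2 + 1 / tau ** 2
        mu_post = y.sum() / s0 ** 2 / prec
        draws = rng.normal(mu_post, 1 / np.sqrt(prec), size=20000)
        ll = np.array([np.sum(norm.logpdf(y, m, s0)) for m in draws])
        est = harmonic_mean_evidence(ll)
        assert exact - 0.5 < est < exact + 3.0


@pytest.fixture(scope="module")
def null_data():
    return simulate_null_population(SimulationDesign(n_progeny=60), seed=5)


class TestBicGrid:
    def test_nesting_never_lowers_likelihood(self, null_data):
        sel = bic_grid(null_data.y, null_data.time_grid,
                       orders=[(2, 2, 2, 2), (3, 2, 2, 2), (2, 2, 3, 2),
                               (2, 2, 2, 3)])
        base = sel.loglik[0]
        assert np.all(sel.loglik[1:] >= base - 1e-3)

    def test_single_candidate_selected(self, null_data):
        sel = bic_grid(null_data.y, null_data.time_grid, orders=[(2, 2, 2, 2)])
        assert sel.selected == (2, 2, 2, 2)

    def test_ranking_invariant_to_affine_rescaling(self, null_data):
        orders = [(2, 2, 2, 2), (3, 2, 2, 2), (2, 2, 3, 2)]
        a = bic_grid(null_data.y, null_data.time_grid, orders=orders)
        b = bic_grid(2.0 * null_data.y + 3.0, null_data.time_grid,
                     orders=orders)
        assert np.array_equal(np.argsort(a.bic), np.argsort(b.bic))


class TestHeritability:
    def _chain_stub(self, beta):
        from jointfm.mcmc import Chain
        return Chain(samples={"beta": np.asarray(beta)[None]}, acceptance={},
                     seed=0, burn_in=0, thin=1, iterations=1)

    def test_no_effect_gives_zero_ve(self, rng):
        y = rng.standard_normal((30, 4))
        chain = self._chain_stub([[1.0, 0.5], [1.0, 0.5]])
        q1 = rng.uniform(size=30)
        h2, ve = heritability_and_ve(y, q1, chain, np.arange(1.0, 5.0))
        assert ve == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_genotype_means_give_unit_h2(self):
        from jointfm.longitudinal import design_matrix
        t = np.arange(1.0, 5.0)
        beta = np.array([[0.0, 1.0], [1.0, -0.5]])
        q1 = np.array([1.0] * 10 + [0.0] * 10)
        X = design_matrix(t, 1)
        y = np.where(q1[:, None] > 0.5, (X @ beta[0])[None, :],
                     (X @ beta[1])[None, :])
        h2, ve = heritability_and_ve(y, q1, self._chain_stub(beta), t)
        assert h2 == pytest.approx(1.0)
        assert 0 < ve <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability_and_ve(np.ones((5, 3)), np.zeros(5),
                                self._chain_stub(np.zeros((2, 2))),
                                np.arange(1.0, 4.0))

    def test_generator_variance_partition_recovered(self):
        # on nearly noise-free data the genetic share approaches 1 and the
        # per-QTL share matches the analytic two-class decomposition
        from jointfm.longitudinal import design_matrix
        d = SimulationDesign(n_progeny=4000, sigma2=1e-12,
                             eta=(-18.0, 0.0, 0.0))
        ds = simulate_population(d, seed=9)
        X = design_matrix(ds.time_grid, 2)
        beta = np.array([d.beta1, d.beta2])
        q1 = (ds.Q_true == 1).astype(float)
        h2, ve = heritability_and_ve(ds.y, q1, self._chain_stub(beta),
                                     ds.time_grid)
        u = beta @ X.T
        p1 = q1.mean()
        ubar = p1 * u[0] + (1 - p1) * u[1]
        var_g = p1 * (u[0] - ubar) ** 2 + (1 - p1) * (u[1] - ubar) ** 2
        expected = np.mean(var_g) / np.mean(ds.y.var(axis=0, ddof=1))
        assert h2 == pytest.approx(1.0, abs=0.01)
        assert ve == pytest.approx(expected, rel=0.02)


@pytest.fixture(scope="module")
def tiny_fit():
    from jointfm import ModelSpec, run_chain
    from conftest import tiny_design
    ds = simulate_population(tiny_design(n=15), seed=31)
    spec = ModelSpec(K=2, quad_points=16)
    chain = run_chain(ds.to_joint_data(), spec, iterations=700,
                      burn_in=250, seed=32)
    return ds, spec, chain


class TestJointModelEvidence:
    """Estimator plumbing on a small simulated population."""

    def test_savage_dickey_and_power_posterior_agree_in_direction(self, tiny_fit):
        from jointfm import bayes_factor
        ds, spec, _ = tiny_fit
        data = ds.to_joint_data()
        sd = bayes_factor(data, spec, seed=33, iterations=900, burn_in=300)
        assert sd.estimator == "savage_dickey"
        assert np.isfinite(sd.log_bf)
        pp = bayes_factor(data, spec, seed=33, estimator="power_posterior",
                          n_temps=4, iterations=400, burn_in=150)
        assert pp.estimator == "power_posterior"
        assert np.isfinite(pp.log_bf)
        # strong QTL effect: both estimators find evidence against the null
        assert sd.log_bf < 0 and pp.log_bf < 0

    def test_harmonic_mean_path(self, tiny_fit):
        from jointfm import log_marginal_likelihood
        ds, spec, chain = tiny_fit
        est, se = log_marginal_likelihood(ds.to_joint_data(), spec,
                                          method="harmonic_mean", chain=chain)
        assert np.isfinite(est)
        assert est <= chain.samples["loglik"].max()

    def test_unknown_method_rejected(self, tiny_fit):
        from jointfm import log_marginal_likelihood
        ds, spec, _ = tiny_fit
        with pytest.raises(ValueError):
            log_marginal_likelihood(ds.to_joint_data(), spec, method="nope")

    def test_posterior_predictive_bf(self, tiny_fit):
        from jointfm import posterior_predictive_bf
        ds, spec, chain = tiny_fit
        data = ds.to_joint_data()
        empty = posterior_predictive_bf(chain, data, 0, spec)
        assert empty.bfs.size == 0 and np.isnan(empty.mean_bf)
        res = posterior_predictive_bf(chain, data, 2, spec, seed=44,
                                      iterations=500, burn_in=200)
        assert res.bfs.size + res.n_failed == 2
        assert np.all(np.isfinite(res.bfs))


class TestGeweke:
    def test_iid_chain_small_z(self, rng):
        zs = [geweke_z(rng.standard_normal(2000))[0] for _ in range(20)]
        assert np.mean(np.abs(zs)) < 2.0
        assert np.max(np.abs(zs)) < 4.5

    def test_mean_shift_detected(self, rng):
        x = rng.standard_normal(2000)
        x[:200] += 5.0
        z, p = geweke_z(x)
        assert abs(z) > 5
        assert p < 1e-6

    def test_identical_segments_zero(self, rng):
        half = rng.standard_normal(500)
        z, p = geweke_z(np.concatenate([half, half]), frac_a=0.5, frac_b=0.5)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.ones(1000))


class TestMPSRF:
    def test_identical_chains_near_one(self, rng):
        x = rng.standard_normal((500, 3))
        assert mpsrf([x, x.copy()]) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_large(self, rng):
        a = rng.standard_normal((500, 2))
        b = rng.standard_normal((500, 2)) + 10.0
        assert mpsrf([a, b]) > 10

    def test_well_mixed_chains_below_threshold(self, rng):
        chains = [rng.standard_normal((2000, 3)) for _ in range(5)]
        assert mpsrf(chains) < 1.1

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            mpsrf([rng.standard_normal((10, 2))])


def test_spectral_variance_matches_iid_variance(rng):
    est = np.mean([_spectral_var_at_zero(rng.standard_normal(20000))
                   for _ in range(10)])
    assert est == pytest.approx(1.0, rel=0.1)
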