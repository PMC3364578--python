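"""Sampler correctness: block full conditionals, conjugate updates, and a
joint validation by Geweke's successive-conditional simulator test."""

import numpy as np
import pytest
from scipy.stats import invgamma

from jointfm import ModelSpec, Sampler, run_chain
from jointfm.inference import _spectral_var_at_zero
from jointfm.mcmc import _cov_chol
from jointfm.simulate import simulate_population

from conftest import tiny_design


def _grid_moments(grid, logdens):
    logdens = np.asarray(logdens, float)
    w = np.exp(logdens - logdens.max())
    w /= w.sum()
    mean = float(np.sum(w * grid))
    var = float(np.sum(w * (grid - mean) ** 2))
    return mean, var


def _chain_tol(x, var_target):
    """3 standard errors of the chain mean, floored by the target spread."""
    se = np.sqrt(max(_spectral_var_at_zero(np.asarray(x)), 1e-12) / len(x))
    return 3 * max(se, np.sqrt(var_target) * 0.02)


class TestBlockFullConditionals:
    def test_gamma_block_matches_grid_conditional(self, tiny_sampler):
        smp = tiny_sampler
        smp._scales["gamma"] = 0.3
        lo, hi = smp.priors.gamma_bounds
        grid = np.linspace(lo + 1e-6, hi - 1e-6, 400)
        logdens = [smp._event_terms(smp.Mq, smp.Ms, g, smp.state.lam0)[0].sum()
                   for g in grid]
        mean, var = _grid_moments(grid, logdens)
        draws = np.empty(8000)
        for k in range(draws.size):
            smp.update_gamma()
            draws[k] = smp.state.gamma
        assert abs(draws[2000:].mean() - mean) < _chain_tol(draws[2000:], var)

    def test_Dstar_block_matches_grid_conditional(self, tiny_sampler):
        smp = tiny_sampler
        Dm = smp.data.lmap.length_cM
        grid = np.linspace(0.01, Dm - 0.01, 500)
        Q = smp.state.Q
        with np.errstate(divide="ignore"):
            logdens = [np.log(smp.ws.omega(d)[np.arange(smp.data.n), Q - 1]).sum()
                       for d in grid]
        mean, var = _grid_moments(grid, logdens)
        draws = np.empty(8000)
        for k in range(draws.size):
            smp.update_Dstar()
            draws[k] = smp.state.Dstar
        assert abs(draws[2000:].mean() - mean) < _chain_tol(draws[2000:], var)

    def test_lambda0_gibbs_piecewise_exponential(self, tiny_sampler):
        smp = tiny_sampler
        smp.state.gamma = 0.0
        smp._refresh_all()
        d_k, E_k = smp._counts_exposures()
        # gamma = 0: exposure is total time at risk per interval (exactly)
        s = smp.data.s
        knots = smp.ws.knots
        expected_E = [np.sum(np.maximum(np.minimum(s, knots[k + 1]) - knots[k], 0))
                      for k in range(smp.ws.K)]
        assert np.allclose(E_k, expected_E, rtol=1e-10)
        a, b = smp.priors.lambda0_gamma
        draws = np.empty((4000, smp.ws.K))
        for i in range(draws.shape[0]):
            smp.update_lambda0()
            draws[i] = smp.state.lam0
        post_mean = (a + d_k) / (b + E_k)
        post_sd = np.sqrt(a + d_k) / (b + E_k)
        assert np.allclose(draws.mean(axis=0), post_mean,
                           atol=3 * post_sd / np.sqrt(1000))

    def test_lambda0_prior_recovered_without_data_weight(self, tiny_sampler):
        smp = tiny_sampler
        smp.temp = 0.0   # tempered out: conditional reduces to the prior
        a, b = smp.priors.lambda0_gamma
        draws = np.empty((20000, smp.ws.K))
        for i in range(draws.shape[0]):
            smp.update_lambda0()
            draws[i] = smp.state.lam0
        assert draws.mean() == pytest.approx(a / b, rel=0.1)

    def test_sigma2_gibbs_conjugacy(self, tiny_sampler):
        smp = tiny_sampler
        a1, a2 = smp.priors.sigma2_ig
        shape = a1 + 0.5 * smp.state.theta.size
        rate = a2 + 0.5 * np.sum(smp.state.theta ** 2)
        draws = np.empty(6000)
        for i in range(draws.size):
            smp.update_sigma2()
            draws[i] = smp.state.sigma2
        dist = invgamma(shape, scale=rate)
        assert draws.mean() == pytest.approx(dist.mean(),
                                             abs=4 * dist.std() / np.sqrt(1000))
        assert draws.std() == pytest.approx(dist.std(), rel=0.25)

    def test_theta_block_prior_limit(self, tiny_sampler):
        # flat likelihood (huge residual variance, gamma = 0): the theta
        # conditional collapses to its MVN(0, sigma2 I) prior
        smp = tiny_sampler
        smp.state.gamma = 0.0
        smp.state.cov_a = np.array([20.0, 0.0, 0.0])
        smp.state.sigma2 = 0.04
        smp._refresh_all()
        smp._scales["theta"] = 0.3
        pooled = []
        for k in range(6000):
            smp.update_theta()
            if k >= 1000 and k % 5 == 0:
                pooled.append(smp.state.theta.copy())
        pooled = np.concatenate([p.ravel() for p in pooled])
        assert pooled.mean() == pytest.approx(0.0, abs=0.02)
        assert pooled.var() == pytest.approx(0.04, rel=0.15)

    def test_Q_block_matches_two_cell_bayes(self, tiny_sampler):
        smp = tiny_sampler
        l1, l2 = smp._both_genotype_logliks()
        lp = np.log(smp.omega) + np.stack([l1, l2], axis=1)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        p1 = p[:, 0] / p.sum(axis=1)
        count = np.zeros(smp.data.n)
        reps = 4000
        for _ in range(reps):
            smp.update_Q()
            count += (smp.state.Q == 1)
        se = np.sqrt(np.maximum(p1 * (1 - p1), 1e-6) / reps)
        assert np.all(np.abs(count / reps - p1) < 4 * se + 0.01)

    @pytest.mark.parametrize("which", ["eta", "delta"])
    def test_cov_block_matches_grid_conditional(self, which):
        ds = simulate_population(tiny_design(n=10), seed=11)
        spec = ModelSpec(order_g=0, order_h=0, K=2, quad_points=16)
        smp = Sampler(ds.to_joint_data(), spec, seed=5)
        smp._scales[which] = 0.3
        prior_var = smp.priors.eta_var if which == "eta" else smp.priors.delta_var
        from jointfm.longitudinal import mvn_loglik_chol

        def cond_logdens(grid):
            out = []
            for v in grid:
                a = np.array([v]) if which == "eta" else smp.state.cov_a
                b = smp.state.cov_b if which == "eta" else np.array([v])
                L = _cov_chol(spec, ds.time_grid, a, b)
                out.append(mvn_loglik_chol(smp.resid, L).sum()
                           - 0.5 * v * v / prior_var)
            return out

        cur = (smp.state.cov_a if which == "eta" else smp.state.cov_b)[0]
        coarse = np.linspace(cur - 8.0, cur + 8.0, 400)
        c_mean, c_var = _grid_moments(coarse, cond_logdens(coarse))
        grid = np.linspace(c_mean - 6 * np.sqrt(c_var),
                           c_mean + 6 * np.sqrt(c_var), 400)
        mean, var = _grid_moments(grid, cond_logdens(grid))
        draws = np.empty(8000)
        for k in range(draws.size):
            getattr(smp, f"update_{which}")()
            draws[k] = (smp.state.cov_a if which == "eta" else smp.state.cov_b)[0]
        assert abs(draws[2000:].mean() - mean) < _chain_tol(draws[2000:], var)

    def test_zero_variance_proposal_keeps_state(self, tiny_sampler):
        smp = tiny_sampler
        for name in ("beta", "eta", "delta", "gamma"):
            smp._scales[name] = 0.0
        before = smp.state.copy()
        smp.update_beta()
        smp.update_eta()
        smp.update_delta()
        smp.update_gamma()
        assert np.allclose(smp.state.beta, before.beta)
        assert np.allclose(smp.state.cov_a, before.cov_a)
        assert np.allclose(smp.state.cov_b, before.cov_b)
        assert smp.state.gamma == before.gamma
        # a propose-equals-current move is always accepted
        assert smp.accept["gamma"][0] == smp.accept["gamma"][1]


class TestLogPosterior:
    def test_gamma_outside_support(self, tiny_sampler):
        tiny_sampler.state.gamma = 0.5
        assert tiny_sampler.log_posterior() == -np.inf

    def test_componentwise_recomputation(self, tiny_sampler):
        smp = tiny_sampler
        st, pr = smp.state, smp.priors
        expected = smp.complete_data_loglik()
        expected += pr.log_beta(st.beta[0]) + pr.log_beta(st.beta[1])
        expected += pr.log_sigma2(st.sigma2) + pr.log_gamma_link(st.gamma)
        expected += pr.log_lambda0(st.lam0)
        expected += pr.log_cov_a(st.cov_a) + pr.log_cov_b(st.cov_b)
        expected += -np.log(smp.data.lmap.length_cM)
        m1 = st.theta.shape[1]
        expected += np.sum(
            -0.5 * np.sum(st.theta ** 2, axis=1) / st.sigma2
            - 0.5 * m1 * np.log(2 * np.pi * st.sigma2))
        expected += np.sum(np.log(
            smp.omega[np.arange(smp.data.n), st.Q - 1]))
        assert smp.log_posterior() == pytest.approx(expected)

    def test_mixture_form_uses_logsumexp(self, tiny_sampler):
        from scipy.special import logsumexp
        smp = tiny_sampler
        l1, l2 = smp._both_genotype_logliks()
        mix = np.sum(logsumexp(np.stack([l1, l2], axis=1),
                               b=smp.omega, axis=1))
        cond = smp.log_posterior(mixture=False)
        qterm = (smp.complete_data_loglik()
                 + np.sum(np.log(smp.omega[np.arange(smp.data.n),
                                           smp.state.Q - 1])))
        assert smp.log_posterior(mixture=True) == pytest.approx(
            cond - qterm + mix)


class TestChainDriver:
    def test_zero_kept_iterations(self, tiny_sampler):
        ds = simulate_population(tiny_design(), seed=7)
        ch = run_chain(ds.to_joint_data(), ModelSpec(K=2, quad_points=16),
                       iterations=10, burn_in=10, seed=1)
        assert len(ch) == 0

    def test_seed_determinism(self):
        ds = simulate_population(tiny_design(), seed=7)
        kwargs = dict(iterations=120, burn_in=40, seed=9)
        spec = ModelSpec(K=2, quad_points=16)
        a = run_chain(ds.to_joint_data(), spec, **kwargs)
        b = run_chain(ds.to_joint_data(), spec, **kwargs)
        for k in a.samples:
            assert np.array_equal(a.samples[k], b.samples[k])

    def test_recorded_length_contract(self):
        ds = simulate_population(tiny_design(), seed=7)
        ch = run_chain(ds.to_joint_data(), ModelSpec(K=2, quad_points=16),
                       iterations=100, burn_in=20, thin=4, seed=2)
        assert len(ch) == 20

    def test_adaptation_reaches_target_band(self):
        ds = simulate_population(tiny_design(n=30), seed=3)
        ch = run_chain(ds.to_joint_data(), ModelSpec(K=2, quad_points=16),
                       iterations=4000, burn_in=2500, seed=4)
        for block in ("eta", "delta", "gamma"):
            assert 0.15 < ch.acceptance[block] < 0.55


# ---------------------------------------------------------------------------
# Geweke successive-conditional validation of the whole sampler


def test_geweke_successive_conditional_agreement():
    """Means of parameter functionals agree between iid prior-predictive
    draws and the successive-conditional chain (sampler + data refresh)."""
    from helpers import run_geweke_check
    names, zs = run_geweke_check(n_subjects=20, N=4000, M=4000, seed=77)
    for name, z in zip(names, zs):
        assert z < 3.5, f"{name}: |z| = {z:.2f}"
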