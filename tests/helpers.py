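"""Shared test harnesses: Geweke joint-sampler check and the conjugate-toy
thermodynamic-integration oracle."""

import numpy as np
from scipy.stats import norm

from jointfm import JointData, ModelSpec, Priors, ProposalSettings, Sampler
from jointfm.inference import _spectral_var_at_zero, thermodynamic_integrate
from jointfm.longitudinal import design_matrix
from jointfm.mcmc import _cov_chol, draw_state_from_prior
from jointfm.simulate import SimulationDesign, sample_event_times, simulate_population

# Tight, proper priors for the Geweke test: the successive-conditional
# simulator must revisit the prior-predictive distribution, so the priors
# are narrowed to keep simulated data numerically sane while remaining a
# valid model configuration.
GEWEKE_SPEC = ModelSpec(order_r=1, order_m=1, order_g=0, order_h=0, K=2,
                        quad_points=16, knots=np.array([0.0, 2.0, 4.0]))
GEWEKE_PRIORS = Priors(beta_var=0.09, sigma2_ig=(6.0, 0.05),
                       gamma_bounds=(-0.8, -0.2), lambda0_gamma=(60.0, 12.0),
                       eta_var=0.09, delta_var=0.04)

GEWEKE_STAT_NAMES = ["beta10", "beta11", "beta21", "gamma", "sigma2",
                     "Dstar", "lam0"]


def geweke_stats(state):
    return np.array([state.beta[0, 0], state.beta[0, 1], state.beta[1, 1],
                     state.gamma, state.sigma2, state.Dstar,
                     float(np.mean(state.lam0))])


def simulate_given_state(state, base: JointData, rng):
    """Draw (y, s) from the likelihood at the given parameter/latent state."""
    grid = base.time_grid
    Xr = design_matrix(grid, GEWEKE_SPEC.order_r)
    Xm = design_matrix(grid, GEWEKE_SPEC.order_m)
    L = _cov_chol(GEWEKE_SPEC, grid, state.cov_a, state.cov_b)
    mean = state.beta[state.Q - 1] @ Xr.T + state.theta @ Xm.T
    y = mean + rng.standard_normal(mean.shape) @ L.T
    coefs = state.beta[state.Q - 1] + state.theta
    s = sample_event_times(state.gamma, state.lam0, GEWEKE_SPEC.knots, coefs,
                           rng, quad_points=GEWEKE_SPEC.quad_points,
                           on_overflow="truncate")
    return JointData(y=y, time_grid=grid, s=s, lmap=base.lmap,
                     markers=base.markers)


def run_geweke_check(n_subjects=20, N=4000, M=4000, seed=77):
    """Compare prior-predictive draws against the successive-conditional
    chain; returns (names, |mean difference| / SE) per statistic."""
    base = simulate_population(
        SimulationDesign(n_progeny=n_subjects, n_markers=3,
                         group_length_cM=20.0, qtl_cM=7.0, T=4, K=2,
                         quad_points=16), seed=21)
    data0 = base.to_joint_data()
    rng = np.random.default_rng(seed)

    mc = np.empty((N, len(GEWEKE_STAT_NAMES)))
    for i in range(N):
        st = draw_state_from_prior(data0, GEWEKE_SPEC, GEWEKE_PRIORS, rng)
        mc[i] = geweke_stats(st)

    settings = ProposalSettings(beta_scale=0.1, theta_scale=0.1,
                                eta_scale=0.15, delta_scale=0.1,
                                gamma_scale=0.1, psi_cM=6.0)
    sc = np.empty((M, len(GEWEKE_STAT_NAMES)))
    state = draw_state_from_prior(data0, GEWEKE_SPEC, GEWEKE_PRIORS, rng)
    data = simulate_given_state(state, data0, rng)
    for i in range(M):
        smp = Sampler(data, GEWEKE_SPEC, GEWEKE_PRIORS, settings,
                      seed=10_000 + i, init_state=state)
        smp.step(adapt=False)
        state = smp.state
        data = simulate_given_state(state, data0, rng)
        sc[i] = geweke_stats(state)

    zs = []
    for j in range(len(GEWEKE_STAT_NAMES)):
        se = np.sqrt(mc[:, j].var() / N
                     + max(_spectral_var_at_zero(sc[:, j]), 0.0) / M)
        zs.append(abs(mc[:, j].mean() - sc[:, j].mean()) / se)
    return GEWEKE_STAT_NAMES, np.array(zs)


def normal_mean_ti(y, s0, tau, J, S, rng):
    """Power-posterior estimate of log evidence for the conjugate normal-mean
    model (iid sampling at each rung); returns (log_Z, se)."""
    n = len(y)
    ladder = ((1.0 + np.arange(J)) / J) ** 5
    means, ses = [], []
    for t in ladder:
        prec = t * n / s0 ** 2 + 1 / tau ** 2
        mu_t = t * y.sum() / s0 ** 2 / prec
        draws = rng.normal(mu_t, 1 / np.sqrt(prec), size=S)
        ll = np.array([np.sum(norm.logpdf(y, m, s0)) for m in draws])
        means.append(ll.mean())
        ses.append(ll.std(ddof=1) / np.sqrt(S))
    return thermodynamic_integrate(ladder, means, ses)
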